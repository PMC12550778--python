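"""Sequential network container and the seeded mini-batch training loop.

The loss is categorical cross-entropy over softmax logits, with an optional
L2 penalty and global gradient-norm clipping — the training recipe both
classifier branches share.
"""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Dropout, Layer
from .optim import make_optimizer

__all__ = ["Sequential", "train_network", "softmax_logits_to_probs"]


def softmax_logits_to_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential:
    """A plain stack of layers ending in an n-class logit layer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.built = False

    def build(self, in_shape: tuple, seed: int):
        rng = np.random.default_rng(seed)
        shape = in_shape
        for layer in self.layers:
            shape = layer.build(rng, shape)
            if isinstance(layer, Dropout):
                # dedicated child stream so dropout draws are reproducible
                layer.rng = np.random.default_rng(rng.integers(2**31))
        self.out_shape = shape
        self.built = True
        return self

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax_logits_to_probs(self.forward(x[i : i + batch_size])))
        return np.concatenate(outs, axis=0).astype(np.float64)

    # -- parameter bookkeeping ------------------------------------------------
    def named_params(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield (li, name), p, layer.grads.get(name)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{li}.{name}": p.copy() for (li, name), p, _ in self.named_params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for (li, name), p, _ in self.named_params():
            p[...] = weights[f"{li}.{name}"]


def _ce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and d(loss)/d(logits) for integer labels."""
    probs = softmax_logits_to_probs(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), y] + eps))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n, probs


def _clip_global_norm(grads: list[np.ndarray], max_norm: float) -> None:
    if max_norm is None or max_norm <= 0:
        return
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale


def train_network(
    net: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    *,
    epochs: int,
    batch_size: int,
    optimizer: str,
    learning_rate: float,
    l2_lambda: float = 0.0,
    grad_clip: float = 1.0,
    seed: int = 0,
    augment_fn=None,
    early_stopping_patience: int | None = None,
) -> list[dict]:
    """Seeded SGD-style training; returns per-epoch history records.

    ``augment_fn(image, rng) -> image`` is applied per training sample per
    epoch (the validation stream is never augmented).  With
    ``early_stopping_patience`` set, training stops once validation loss has
    not improved for that many consecutive epochs.
    """
    opt = make_optimizer(optimizer, learning_rate)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    best_val, stale = np.inf, 0
    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            xb = x_train[idx]
            if augment_fn is not None:
                xb = np.stack([augment_fn(img, rng) for img in xb])
            yb = y_train[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits, probs = _ce_loss_and_grad(logits, yb)
            if l2_lambda:
                loss += l2_lambda * sum(
                    float((p * p).sum()) for _, p, _ in net.named_params()
                )
            net.backward(dlogits.astype(DTYPE))
            triples = [(k, p, g) for k, p, g in net.named_params() if g is not None]
            if l2_lambda:
                for _, p, g in triples:
                    g += (2.0 * l2_lambda) * p
            _clip_global_norm([g for _, _, g in triples], grad_clip)
            opt.step(triples)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == yb).sum())
        rec = {
            "epoch": epoch + 1,
            "train_loss": float(np.sum(losses) / len(order)),
            "train_acc": correct / len(order),
        }
        if x_val is not None and len(x_val):
            val_logits = net.forward(x_val)
            val_loss, _, val_probs = _ce_loss_and_grad(val_logits, y_val)
            rec["val_loss"] = float(val_loss)
            rec["val_acc"] = float((val_probs.argmax(axis=1) == y_val).mean())
        history.append(rec)
        if early_stopping_patience and "val_loss" in rec:
            if rec["val_loss"] < best_val - 1e-9:
                best_val, stale = rec["val_loss"], 0
            else:
                stale += 1
                if stale >= early_stopping_patience:
                    break
    return history
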