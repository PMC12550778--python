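"""The two classifier branches as sklearn-style estimators.

* :class:`LVMClassifier` — a convolutional stack (conv -> ReLU -> max-pool)
  optionally followed by patch embedding + sinusoidal position codes +
  multi-head self-attention, then a three-layer fully-connected head with
  dropout and a softmax output ("large vision model" branch: fine-grained
  spatial features).
* :class:`InternImageClassifier` — a stem convolution, stacked
  inception-style multi-scale blocks, one dynamic-convolution stage whose
  kernel is an input-conditioned mixture of base kernels, global average
  pooling and a dense softmax head (multi-scale semantic-feature branch).
  ``feature_extractor`` accepts an external pretrained embedding function
  for users who have one; by default the surrogate backbone is trained
  from scratch.

Both train with categorical cross-entropy, L2 penalty, gradient-norm
clipping and a seeded mini-batch loop; inputs are standardized with
statistics fitted on the training data only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import layers as L
from .nn.network import Sequential, train_network
from .preprocess import AugmentationConfig, NormalizationStats, fit_normalization, random_augment
from .synth import LabeledDataset

__all__ = [
    "LVMConfig",
    "InternConfig",
    "TrainConfig",
    "LVMClassifier",
    "InternImageClassifier",
    "train_classifier",
    "lvm_forward",
    "internimage_forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LVMConfig:
    conv_specs: tuple = ((8, 3, "relu"), (16, 3, "relu"))
    pool_size: int = 2
    use_attention: bool = False
    patch_size: int = 4
    embed_dim: int = 32
    n_heads: int = 4
    fc_sizes: tuple = (64, 32)
    dropout_rate: float = 0.3
    l2_lambda: float = 0.0005
    n_classes: int = 3

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads {self.n_heads}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass(frozen=True)
class InternConfig:
    stem_filters: int = 8
    inception_specs: tuple = ((4, 8, 2, 2), (6, 12, 4, 4))
    dynamic_filters: int = 16
    n_base_kernels: int = 4
    head_width: int = 32
    n_classes: int = 3

    def __post_init__(self):
        if self.n_base_kernels < 1:
            raise ValueError("n_base_kernels must be >= 1")
        for spec in self.inception_specs:
            if len(spec) != 4 or any(w < 1 for w in spec):
                raise ValueError(f"inception spec must be 4 widths >= 1, got {spec}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    optimizer: str = "Adam"
    epochs: int = 50
    grad_clip: float = 1.0
    seed: int = 0
    early_stopping_patience: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")


def _build_lvm(config: LVMConfig) -> Sequential:
    stack: list[L.Layer] = []
    for filters, k, act in config.conv_specs:
        stack.append(L.Conv2D(filters, k, activation=act))
        stack.append(L.MaxPool2D(config.pool_size))
    if config.use_attention:
        stack.append(L.PatchEmbed(config.patch_size, config.embed_dim))
        stack.append(L.MultiHeadSelfAttention(config.n_heads))
        stack.append(L.FlattenSeq())
    else:
        stack.append(L.Flatten())
    for width in config.fc_sizes:
        stack.append(L.Dense(width, activation="relu"))
        if config.dropout_rate:
            stack.append(L.Dropout(config.dropout_rate))
    stack.append(L.Dense(config.n_classes, activation=None))
    return Sequential(stack)


def _build_intern(config: InternConfig) -> Sequential:
    stack: list[L.Layer] = [L.Conv2D(config.stem_filters, 3), L.MaxPool2D(2)]
    for i, spec in enumerate(config.inception_specs):
        stack.append(L.InceptionBlock(tuple(spec)))
        if i < len(config.inception_specs) - 1:
            stack.append(L.MaxPool2D(2))
    stack.append(
        L.DynamicConv2D(config.dynamic_filters, 3, n_base_kernels=config.n_base_kernels)
    )
    stack.append(L.GlobalAvgPool())
    stack.append(L.Dense(config.head_width, activation="relu"))
    stack.append(L.Dense(config.n_classes, activation=None))
    return Sequential(stack)


class _BranchClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the two branches."""

    def __init__(self, config=None, train_config=None, augmentation=None,
                 standardize_inputs=True):
        self.config = config
        self.train_config = train_config
        self.augmentation = augmentation
        self.standardize_inputs = standardize_inputs

    # subclasses set these
    _default_config: type
    _builder = None
    kind = "branch"

    def _resolved(self):
        cfg = self.config if self.config is not None else self._default_config()
        tc = self.train_config if self.train_config is not None else TrainConfig()
        return cfg, tc

    @staticmethod
    def _check_images(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(f"X must be (N, H, W, C), got shape {X.shape}")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        cfg, tc = self._resolved()
        X = self._check_images(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("training split is empty")
        if X_val is not None and len(X_val) == 0:
            raise ValueError("validation split is empty")
        if self.standardize_inputs:
            self.norm_stats_ = fit_normalization(X)
            X = (X - self.norm_stats_.mu) / self.norm_stats_.sigma
            if X_val is not None:
                X_val = (self._check_images(X_val) - self.norm_stats_.mu) / self.norm_stats_.sigma
        else:
            self.norm_stats_ = None
            if X_val is not None:
                X_val = self._check_images(X_val)
        self.classes_ = np.arange(cfg.n_classes)
        self.input_shape_ = X.shape[1:]
        net = type(self)._builder(cfg)
        net.build(self.input_shape_, seed=tc.seed)
        aug = self.augmentation
        augment_fn = None
        if aug is not None and not aug.is_identity:
            augment_fn = lambda img, rng: random_augment(img, aug, rng)
        self.history_ = train_network(
            net,
            X.astype(np.float32),
            y,
            None if X_val is None else X_val.astype(np.float32),
            None if y_val is None else np.asarray(y_val, dtype=np.int64),
            epochs=tc.epochs,
            batch_size=tc.batch_size,
            optimizer=tc.optimizer,
            learning_rate=tc.learning_rate,
            l2_lambda=getattr(cfg, "l2_lambda", 0.0),
            grad_clip=tc.grad_clip,
            seed=tc.seed + 1,
            augment_fn=augment_fn,
            early_stopping_patience=tc.early_stopping_patience,
        )
        self.net_ = net
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_images(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match fitted shape {self.input_shape_}"
            )
        if self.norm_stats_ is not None:
            X = (X - self.norm_stats_.mu) / self.norm_stats_.sigma
        return self.net_.predict_proba(X.astype(np.float32))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


class LVMClassifier(_BranchClassifier):
    """Conv/pool (+ optional attention) branch with a 3-layer dense head."""

    _default_config = LVMConfig
    _builder = staticmethod(_build_lvm)
    kind = "lvm"


class InternImageClassifier(_BranchClassifier):
    """Inception-style multi-scale branch with a dynamic-convolution stage.

    ``feature_extractor``: optional callable mapping (N, H, W, C)
    standardized images to (N, D) embeddings (e.g. a pretrained backbone);
    when given, it replaces the surrogate feature stack and only the dense
    head is trained.
    """

    _default_config = InternConfig
    _builder = staticmethod(_build_intern)
    kind = "intern"

    def __init__(self, config=None, train_config=None, augmentation=None,
                 standardize_inputs=True, feature_extractor=None):
        super().__init__(config, train_config, augmentation, standardize_inputs)
        self.feature_extractor = feature_extractor

    def fit(self, X, y, X_val=None, y_val=None):
        if self.feature_extractor is None:
            return super().fit(X, y, X_val, y_val)
        # external pretrained embedding: train the dense head only
        cfg, tc = self._resolved()
        X = self._check_images(X)
        y = np.asarray(y, dtype=np.int64)
        if self.standardize_inputs:
            self.norm_stats_ = fit_normalization(X)
            X = (X - self.norm_stats_.mu) / self.norm_stats_.sigma
        else:
            self.norm_stats_ = None
        self.classes_ = np.arange(cfg.n_classes)
        self.input_shape_ = X.shape[1:]
        emb = np.asarray(self.feature_extractor(X), dtype=np.float32)
        emb_val = y_val_arr = None
        if X_val is not None:
            Xv = self._check_images(X_val)
            if self.norm_stats_ is not None:
                Xv = (Xv - self.norm_stats_.mu) / self.norm_stats_.sigma
            emb_val = np.asarray(self.feature_extractor(Xv), dtype=np.float32)
            y_val_arr = np.asarray(y_val, dtype=np.int64)
        net = Sequential(
            [L.Dense(cfg.head_width, activation="relu"),
             L.Dense(cfg.n_classes, activation=None)]
        )
        net.build((emb.shape[1],), seed=tc.seed)
        self.history_ = train_network(
            net, emb, y, emb_val, y_val_arr,
            epochs=tc.epochs, batch_size=tc.batch_size, optimizer=tc.optimizer,
            learning_rate=tc.learning_rate, grad_clip=tc.grad_clip, seed=tc.seed + 1,
        )
        self.net_ = net
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.feature_extractor is None:
            return super().predict_proba(X)
        X = self._check_images(X)
        if self.norm_stats_ is not None:
            X = (X - self.norm_stats_.mu) / self.norm_stats_.sigma
        emb = np.asarray(self.feature_extractor(X), dtype=np.float32)
        return self.net_.predict_proba(emb)


def train_classifier(
    model_config,
    train_set: LabeledDataset,
    val_set: LabeledDataset | None,
    train_config: TrainConfig,
    aug: AugmentationConfig | None = None,
):
    """Fit the branch matching ``model_config`` on LabeledDataset splits."""
    if isinstance(model_config, LVMConfig):
        est = LVMClassifier(model_config, train_config, aug)
    elif isinstance(model_config, InternConfig):
        est = InternImageClassifier(model_config, train_config, aug)
    else:
        raise TypeError(f"unsupported model config type {type(model_config).__name__}")
    if len(train_set) == 0:
        raise ValueError("training split is empty")
    xv = yv = None
    if val_set is not None:
        if len(val_set) == 0:
            raise ValueError("validation split is empty")
        xv, yv = val_set.images, val_set.labels
    return est.fit(train_set.images, train_set.labels, xv, yv)


def _single_forward(est: _BranchClassifier, image: np.ndarray) -> np.ndarray:
    probs = est.predict_proba(np.asarray(image)[None])
    return probs[0]


def lvm_forward(image: np.ndarray, model: LVMClassifier) -> np.ndarray:
    """Class-probability 3-vector for one image from the LVM branch."""
    return _single_forward(model, image)


def internimage_forward(image: np.ndarray, model: InternImageClassifier) -> np.ndarray:
    """Class-probability 3-vector for one image from the inception branch."""
    return _single_forward(model, image)


CHECKPOINT_VERSION = 1


def save_checkpoint(est: _BranchClassifier, path: str | Path) -> Path:
    """Versioned .npz archive of weights + configs + fitted metadata."""
    path = Path(path)
    cfg, tc = est._resolved()
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": est.kind,
        "config": asdict(cfg),
        "train_config": asdict(tc),
        "input_shape": list(est.input_shape_),
        "norm_stats": None
        if est.norm_stats_ is None
        else {"mu": est.norm_stats_.mu, "sigma": est.norm_stats_.sigma},
        "history": est.history_,
    }
    weights = est.net_.get_weights()
    np.savez(path, __meta__=json.dumps(meta, sort_keys=True), **weights)
    return path


def _config_from_dict(kind: str, d: dict):
    def tup(x):
        return tuple(tuple(v) if isinstance(v, list) else v for v in x)

    if kind == "lvm":
        d = dict(d, conv_specs=tup(d["conv_specs"]), fc_sizes=tuple(d["fc_sizes"]))
        return LVMConfig(**d)
    d = dict(d, inception_specs=tup(d["inception_specs"]))
    return InternConfig(**d)


def load_checkpoint(path: str | Path) -> _BranchClassifier:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        weights = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    kind = meta["kind"]
    cfg = _config_from_dict(kind, meta["config"])
    tc = TrainConfig(**meta["train_config"])
    cls = LVMClassifier if kind == "lvm" else InternImageClassifier
    est = cls(cfg, tc)
    est.classes_ = np.arange(cfg.n_classes)
    est.input_shape_ = tuple(meta["input_shape"])
    ns = meta["norm_stats"]
    est.norm_stats_ = None if ns is None else NormalizationStats(ns["mu"], ns["sigma"])
    est.history_ = meta["history"]
    net = cls._builder(cfg)
    net.build(est.input_shape_, seed=tc.seed)
    net.set_weights(weights)
    est.net_ = net
    return est
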