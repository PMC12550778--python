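"""Trainable layers with hand-written backward passes.

Small, CPU-oriented implementations; every layer exposes

* ``build(rng, in_shape) -> out_shape`` — allocate parameters,
* ``forward(x, train) -> out`` — caching what backward needs,
* ``backward(dout) -> dx`` — filling ``grads`` (same keys as ``params``).

Arrays are float32 internally for speed; the stateless float64 kernels in
:mod:`sharkfuse.nn.functional` are the reference arithmetic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import functional as F

DTYPE = np.float32


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, rng: np.random.Generator, in_shape: tuple) -> tuple:
        return in_shape

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2D(Layer):
    """Same-padded stride-1 cross-correlation + bias + optional ReLU."""

    def __init__(self, filters: int, kernel_size: int = 3, activation: str = "relu"):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.filters, self.k, self.activation = filters, kernel_size, activation

    def build(self, rng, in_shape):
        h, w, c = in_shape
        self.in_shape = in_shape
        fan_in = self.k * self.k * c
        self.params = {
            "W": _he(rng, (self.k, self.k, c, self.filters), fan_in),
            "b": np.zeros(self.filters, dtype=DTYPE),
        }
        return (h, w, self.filters)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k, f = self.k, self.filters
        self._cols = F.im2col(x, k, k)
        pre = (self._cols @ self.params["W"].reshape(-1, f)).reshape(n, h, w, f)
        pre += self.params["b"]
        self._x_shape = x.shape
        if self.activation == "relu":
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        return pre

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        n, h, w, f = dout.shape
        k = self.k
        dflat = dout.reshape(n, h * w, f)
        self.grads["W"] = np.einsum("npc,npf->cf", self._cols, dflat).reshape(
            self.params["W"].shape
        )
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dcols = dflat @ self.params["W"].reshape(-1, f).T
        return F.col2im(dcols, self._x_shape, k, k)


class MaxPool2D(Layer):
    """Non-overlapping max-pool; spatial dims must divide the window."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def build(self, rng, in_shape):
        h, w, c = in_shape
        if h % self.size or w % self.size:
            raise ValueError(f"pool size {self.size} must divide spatial dims {h}x{w}")
        return (h // self.size, w // self.size, c)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        m = self.size
        xr = (
            x.reshape(n, h // m, m, w // m, m, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // m, w // m, c, m * m)
        )
        self._argmax = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._x_shape
        m = self.size
        dxr = np.zeros((n, h // m, w // m, c, m * m), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(n, h // m, w // m, c, m, m)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class Flatten(Layer):
    def build(self, rng, in_shape):
        self._in = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], *self._in)


class GlobalAvgPool(Layer):
    """Mean over spatial dims: (N, H, W, C) -> (N, C) feature embedding."""

    def build(self, rng, in_shape):
        self._in = in_shape
        return (in_shape[-1],)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._x_shape
        return np.broadcast_to(dout[:, None, None, :], self._x_shape) / (h * w)


class Dense(Layer):
    def __init__(self, width: int, activation: str | None = "relu"):
        super().__init__()
        self.width, self.activation = width, activation

    def build(self, rng, in_shape):
        (d,) = in_shape
        self.params = {"W": _he(rng, (d, self.width), d), "b": np.zeros(self.width, DTYPE)}
        return (self.width,)

    def forward(self, x, train=False):
        self._x = x
        pre = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        return pre

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def build(self, rng, in_shape):
        return in_shape

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class PatchEmbed(Layer):
    """Cut a feature map into p x p patches, project to d, add position code."""

    def __init__(self, patch_size: int, embed_dim: int):
        super().__init__()
        self.p, self.d = patch_size, embed_dim

    def build(self, rng, in_shape):
        h, w, c = in_shape
        if h % self.p or w % self.p:
            raise ValueError(f"patch size {self.p} must divide spatial dims {h}x{w}")
        self._grid = (h // self.p, w // self.p)
        self.n_patches = self._grid[0] * self._grid[1]
        dim_in = self.p * self.p * c
        self.params = {"W": _he(rng, (dim_in, self.d), dim_in), "b": np.zeros(self.d, DTYPE)}
        self._pe = F.positional_encoding(self.n_patches, self.d).astype(DTYPE)
        self._in = in_shape
        return (self.n_patches, self.d)

    def _patchify(self, x):
        n, h, w, c = x.shape
        p = self.p
        return (
            x.reshape(n, h // p, p, w // p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, self.n_patches, p * p * c)
        )

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._patches = self._patchify(x)
        return self._patches @ self.params["W"] + self.params["b"] + self._pe

    def backward(self, dout):
        self.grads["W"] = np.einsum("npi,npd->id", self._patches, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dpatch = dout @ self.params["W"].T
        n, h, w, c = self._x_shape
        p = self.p
        return (
            dpatch.reshape(n, h // p, w // p, p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )


class MultiHeadSelfAttention(Layer):
    """One multi-head self-attention block over a patch sequence (N, n, d)."""

    def __init__(self, n_heads: int):
        super().__init__()
        self.h = n_heads

    def build(self, rng, in_shape):
        n_patches, d = in_shape
        if d % self.h:
            raise ValueError(f"embed dim {d} not divisible by n_heads {self.h}")
        self.d, self.dh = d, d // self.h
        self.params = {k: _he(rng, (d, d), d) for k in ("Wq", "Wk", "Wv", "Wo")}
        return in_shape

    def _split(self, x):  # (N, n, d) -> (N, h, n, dh)
        n, np_, _ = x.shape
        return x.reshape(n, np_, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (N, h, n, dh) -> (N, n, d)
        n, _, np_, _ = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, np_, self.d)

    def forward(self, x, train=False):
        self._x = x
        p = self.params
        self._Q = self._split(x @ p["Wq"])
        self._K = self._split(x @ p["Wk"])
        self._V = self._split(x @ p["Wv"])
        scores = self._Q @ self._K.swapaxes(-1, -2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        self._A = e / e.sum(axis=-1, keepdims=True)
        self._heads = self._merge(self._A @ self._V)
        return self._heads @ p["Wo"]

    def backward(self, dout):
        p = self.params
        self.grads["Wo"] = np.einsum("bnd,bne->de", self._heads, dout)
        dheads = self._split(dout @ p["Wo"].T)
        dA = dheads @ self._V.swapaxes(-1, -2)
        dV = self._A.swapaxes(-1, -2) @ dheads
        dS = self._A * (dA - (dA * self._A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.dh)
        dQ = dS @ self._K
        dK = dS.swapaxes(-1, -2) @ self._Q
        dx = np.zeros_like(self._x)
        for name, dproj in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            dmerged = self._merge(dproj)
            self.grads[name] = np.einsum("bni,bnj->ij", self._x, dmerged)
            dx += dmerged @ p[name].T
        return dx


class FlattenSeq(Layer):
    """(N, n, d) patch sequence -> (N, n*d)."""

    def build(self, rng, in_shape):
        self._in = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], *self._in)


class InceptionBlock(Layer):
    """Parallel 1x1 / 3x3 / 5x5 / pool-project branches, channel-concatenated."""

    def __init__(self, widths: tuple[int, int, int, int]):
        super().__init__()
        if any(w < 1 for w in widths):
            raise ValueError("all inception branch widths must be >= 1")
        self.widths = tuple(widths)

    def build(self, rng, in_shape):
        h, w, c = in_shape
        w1, w3, w5, wp = self.widths
        self.params = {
            "W1": _he(rng, (1, 1, c, w1), c),
            "b1": np.zeros(w1, DTYPE),
            "W3": _he(rng, (3, 3, c, w3), 9 * c),
            "b3": np.zeros(w3, DTYPE),
            "W5": _he(rng, (5, 5, c, w5), 25 * c),
            "b5": np.zeros(w5, DTYPE),
            "Wp": _he(rng, (1, 1, c, wp), c),
            "bp": np.zeros(wp, DTYPE),
        }
        return (h, w, sum(self.widths))

    @staticmethod
    def _branch_fwd(x, W, b, cache):
        k = W.shape[0]
        cols = F.im2col(x, k, k)
        n, h, w, _ = x.shape
        pre = (cols @ W.reshape(-1, W.shape[-1])).reshape(n, h, w, -1) + b
        mask = pre > 0
        cache.append((cols, mask, k))
        return np.where(mask, pre, 0.0)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._cache = []
        n, h, w, c = x.shape
        outs = [
            self._branch_fwd(x, self.params["W1"], self.params["b1"], self._cache),
            self._branch_fwd(x, self.params["W3"], self.params["b3"], self._cache),
            self._branch_fwd(x, self.params["W5"], self.params["b5"], self._cache),
        ]
        # 3x3 stride-1 max-pool branch
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        v = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        flat = v.reshape(n, h, w, c, 9)
        self._pool_idx = flat.argmax(axis=-1)
        pooled = np.take_along_axis(flat, self._pool_idx[..., None], axis=-1)[..., 0]
        outs.append(self._branch_fwd(pooled, self.params["Wp"], self.params["bp"], self._cache))
        return np.concatenate(outs, axis=-1)

    def _branch_bwd(self, dout, name, cache_entry):
        cols, mask, k = cache_entry
        dout = dout * mask
        n, h, w, f = dout.shape
        dflat = dout.reshape(n, h * w, f)
        self.grads["W" + name] = np.einsum("npc,npf->cf", cols, dflat).reshape(
            self.params["W" + name].shape
        )
        self.grads["b" + name] = dout.sum(axis=(0, 1, 2))
        dcols = dflat @ self.params["W" + name].reshape(-1, f).T
        return F.col2im(dcols, self._x_shape, k, k)

    def backward(self, dout):
        w1, w3, w5, wp = self.widths
        d1, d3, d5, dp = np.split(dout, np.cumsum([w1, w3, w5]), axis=-1)
        dx = self._branch_bwd(d1, "1", self._cache[0])
        dx += self._branch_bwd(d3, "3", self._cache[1])
        dx += self._branch_bwd(d5, "5", self._cache[2])
        dpooled = self._branch_bwd(dp, "p", self._cache[3])
        # scatter pool-branch gradient through the stride-1 max locations
        n, h, w, c = self._x_shape
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dout.dtype)
        for o in range(9):
            a, b = divmod(o, 3)
            m = self._pool_idx == o
            dxp[:, a : a + h, b : b + w, :] += np.where(m, dpooled, 0.0)
        dx += dxp[:, 1 : 1 + h, 1 : 1 + w, :]
        return dx


class DynamicConv2D(Layer):
    """Input-conditioned convex mixture of K base kernels.

    The gate is global-average-pool -> dense(K) -> softmax; the effective
    per-sample kernel is the gated sum of the base kernels.
    """

    def __init__(self, filters: int, kernel_size: int = 3, n_base_kernels: int = 4):
        super().__init__()
        if n_base_kernels < 1:
            raise ValueError("n_base_kernels must be >= 1")
        self.filters, self.k, self.K = filters, kernel_size, n_base_kernels

    def build(self, rng, in_shape):
        h, w, c = in_shape
        fan_in = self.k * self.k * c
        self.params = {
            "Wb": _he(rng, (self.K, self.k, self.k, c, self.filters), fan_in),
            "b": np.zeros(self.filters, DTYPE),
            "Wg": _he(rng, (c, self.K), c),
            "bg": np.zeros(self.K, DTYPE),
        }
        self._c = c
        return (h, w, self.filters)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k, K, f = self.k, self.K, self.filters
        self._x_shape = x.shape
        self._s = x.mean(axis=(1, 2))  # (N, C) pooled descriptor
        logits = self._s @ self.params["Wg"] + self.params["bg"]
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        self._g = e / e.sum(axis=-1, keepdims=True)  # (N, K) simplex gate
        self._wb_flat = self.params["Wb"].reshape(K, k * k * c, f)
        self._w_eff = np.einsum("nk,kcf->ncf", self._g, self._wb_flat)
        self._cols = F.im2col(x, k, k)
        pre = np.einsum("npc,ncf->npf", self._cols, self._w_eff).reshape(n, h, w, f)
        pre += self.params["b"]
        self._mask = pre > 0
        return np.where(self._mask, pre, 0.0)

    def backward(self, dout):
        n, h, w, c = self._x_shape
        k, K, f = self.k, self.K, self.filters
        dout = dout * self._mask
        dflat = dout.reshape(n, h * w, f)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dW_eff = np.einsum("npc,npf->ncf", self._cols, dflat)
        dcols = np.einsum("npf,ncf->npc", dflat, self._w_eff)
        dx = F.col2im(dcols, self._x_shape, k, k)
        self.grads["Wb"] = np.einsum("nk,ncf->kcf", self._g, dW_eff).reshape(
            self.params["Wb"].shape
        )
        dg = np.einsum("ncf,kcf->nk", dW_eff, self._wb_flat)
        dlogits = self._g * (dg - (dg * self._g).sum(axis=-1, keepdims=True))
        self.grads["Wg"] = self._s.T @ dlogits
        self.grads["bg"] = dlogits.sum(axis=0)
        ds = dlogits @ self.params["Wg"].T  # (N, C)
        dx += np.broadcast_to(ds[:, None, None, :], self._x_shape) / (h * w)
        return dx
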