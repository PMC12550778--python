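"""Stateless numerical kernels for the two classifier branches.

These are the forward-pass primitives of the hybrid classifier: plain
cross-correlation and max-pooling, softmax, scaled-dot-product and
multi-head self-attention, sinusoidal positional encoding, the
inception-style multi-branch block, and input-conditioned (dynamic)
convolution.  The trainable layer objects in :mod:`sharkfuse.nn.layers`
route their forward passes through the same arithmetic; keeping the
kernels separate makes them directly checkable against brute-force
oracles.

Conventions: feature maps are ``(H, W, C)`` (or batched ``(N, H, W, C)``),
convolution kernels are ``(kh, kw, C_in, C_out)``, convolutions are
cross-correlations with same-padding and stride 1.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_forward",
    "maxpool",
    "softmax",
    "scaled_dot_attention",
    "multi_head_attention",
    "positional_encoding",
    "inception_block",
    "dynamic_conv",
    "im2col",
    "col2im",
    "relu",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _identity(x: np.ndarray) -> np.ndarray:
    return x


def im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Unfold same-padded ``(N, H, W, C)`` into ``(N, H*W, kh*kw*C)`` patches.

    Column ordering is (kh, kw, C) row-major, matching kernels reshaped from
    ``(kh, kw, C, F)`` to ``(kh*kw*C, F)``.
    """
    n, h, w, c = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N, H, W, C, kh, kw)
    return v.transpose(0, 1, 2, 4, 5, 3).reshape(n, h * w, kh * kw * c)


def col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back to the input."""
    n, h, w, c = x_shape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, kh, kw, c)
    for a in range(kh):
        for b in range(kw):
            dxp[:, a : a + h, b : b + w, :] += d[:, :, :, a, b, :]
    return dxp[:, ph : ph + h, pw : pw + w, :]


def _as_batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected a (H, W, C) or (N, H, W, C) array, got shape {x.shape}")


def conv_forward(
    feature_map: np.ndarray,
    kernel: np.ndarray,
    bias: np.ndarray | float = 0.0,
    activation=relu,
) -> np.ndarray:
    """Same-padded, stride-1 cross-correlation, then bias and activation.

    ``kernel`` has shape ``(kh, kw, C_in, C_out)`` with odd spatial size.
    ``activation=None`` applies no nonlinearity.
    """
    x, squeeze = _as_batched(feature_map)
    if kernel.ndim != 4:
        raise ValueError("kernel must be 4-D (kh, kw, C_in, C_out)")
    kh, kw, cin, cout = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel spatial size must be odd for same-padding")
    if x.shape[-1] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]} channels, kernel expects {cin}"
        )
    n, h, w, _ = x.shape
    cols = im2col(x, kh, kw)
    out = cols @ kernel.reshape(kh * kw * cin, cout)
    out = out.reshape(n, h, w, cout) + np.asarray(bias)
    if activation is not None:
        out = activation(out)
    return out[0] if squeeze else out


def maxpool(feature_map: np.ndarray, window: tuple, stride: tuple | None = None) -> np.ndarray:
    """Per-channel max over non-overlapping windows (stride defaults to window).

    Spatial dims not divisible by the window are padded with ``-inf`` so every
    input pixel belongs to exactly one window.
    """
    x, squeeze = _as_batched(feature_map)
    m, nn_ = (window, window) if np.isscalar(window) else window
    if stride is not None and tuple(stride) != (m, nn_):
        raise ValueError("only stride == window (non-overlapping pooling) is supported")
    n, h, w, c = x.shape
    ho, wo = -(-h // m), -(-w // nn_)
    if (h % m) or (w % nn_):
        x = np.pad(
            x,
            ((0, 0), (0, ho * m - h), (0, wo * nn_ - w), (0, 0)),
            constant_values=-np.inf,
        )
    out = x.reshape(n, ho, m, wo, nn_, c).max(axis=(2, 4))
    return out[0] if squeeze else out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: exp(z - max z) normalized along ``axis``."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """softmax(Q Kᵀ / √d_k) V with row-wise softmax.

    ``Q`` is (n_q, d_k), ``K`` is (n_k, d_k), ``V`` is (n_k, d_v); leading
    batch/head axes are broadcast through.
    """
    Q, K, V = np.asarray(Q, float), np.asarray(K, float), np.asarray(V, float)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"query/key width mismatch: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(f"key/value length mismatch: {K.shape[-2]} vs {V.shape[-2]}")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(Q.shape[-1])
    return softmax(scores, axis=-1) @ V


def multi_head_attention(
    S: np.ndarray,
    n_heads: int,
    W_Q: np.ndarray,
    W_K: np.ndarray,
    W_V: np.ndarray,
    W_O: np.ndarray,
) -> np.ndarray:
    """Multi-head self-attention over a patch sequence ``S`` of shape (n, d).

    The d-dimensional projections are split into ``n_heads`` slices of width
    d/h, attended independently, concatenated and projected by ``W_O``.
    """
    S = np.asarray(S, float)
    n, d = S.shape
    if d % n_heads:
        raise ValueError(f"embed dim {d} not divisible by n_heads {n_heads}")
    dh = d // n_heads
    Q, K, V = S @ W_Q, S @ W_K, S @ W_V

    def split(x):  # (n, d) -> (h, n, dh)
        return x.reshape(n, n_heads, dh).transpose(1, 0, 2)

    heads = scaled_dot_attention(split(Q), split(K), split(V))  # (h, n, dh)
    concat = heads.transpose(1, 0, 2).reshape(n, d)
    return concat @ W_O


def positional_encoding(n_positions: int, d: int) -> np.ndarray:
    """Sinusoidal position code: PE[p, 2i]=sin(p/10000^(2i/d)), PE[p, 2i+1]=cos(...)."""
    if d % 2:
        raise ValueError(f"embedding dimension must be even, got {d}")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d)
    pe = np.empty((n_positions, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def inception_block(
    feature_map: np.ndarray,
    w1: np.ndarray,
    b1,
    w3: np.ndarray,
    b3,
    w5: np.ndarray,
    b5,
    wp: np.ndarray,
    bp,
) -> np.ndarray:
    """Inception-style multi-scale block.

    Four parallel branches on the same input — 1x1 conv, 3x3 conv, 5x5 conv,
    and 3x3 stride-1 max-pool followed by a 1x1 projection — each ReLU, all
    same spatial size, concatenated along channels.
    """
    x, squeeze = _as_batched(feature_map)
    f1 = conv_forward(x, w1, b1)
    f3 = conv_forward(x, w3, b3)
    f5 = conv_forward(x, w5, b5)
    pooled = _maxpool_3x3_stride1(x)
    fp = conv_forward(pooled, wp, bp)
    out = np.concatenate([f1, f3, f5, fp], axis=-1)
    return out[0] if squeeze else out


def _maxpool_3x3_stride1(x: np.ndarray) -> np.ndarray:
    """3x3 max-pool at stride 1 with same-padding (-inf edges)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
    v = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    return v.max(axis=(4, 5))


def dynamic_conv(
    feature_map: np.ndarray,
    base_kernels: np.ndarray,
    gate_weights: np.ndarray,
    bias: np.ndarray | float = 0.0,
    activation=relu,
    atol: float = 1e-6,
) -> np.ndarray:
    """Convolution with an input-conditioned convex mixture of base kernels.

    ``base_kernels`` is (K, kh, kw, C_in, C_out); ``gate_weights`` is a
    K-vector (one image) or (N, K) on the probability simplex — typically
    produced by a global-average-pool -> dense -> softmax gate.  The
    effective kernel is W = Σ_k g_k · W_base[k], then a standard same-padded
    convolution is applied.
    """
    x, squeeze = _as_batched(feature_map)
    wb = np.asarray(base_kernels, float)
    if wb.ndim != 5:
        raise ValueError("base_kernels must be 5-D (K, kh, kw, C_in, C_out)")
    g = np.atleast_2d(np.asarray(gate_weights, float))
    if g.shape[-1] != wb.shape[0]:
        raise ValueError(f"gate length {g.shape[-1]} != number of base kernels {wb.shape[0]}")
    if np.any(g < -atol) or np.any(np.abs(g.sum(axis=-1) - 1.0) > atol):
        raise ValueError("gate weights must be nonnegative and sum to 1 (simplex)")
    if g.shape[0] == 1 and x.shape[0] > 1:
        g = np.repeat(g, x.shape[0], axis=0)
    k_, kh, kw, cin, cout = wb.shape
    n, h, w, _ = x.shape
    w_eff = np.einsum("nk,kcf->ncf", g, wb.reshape(k_, kh * kw * cin, cout))
    cols = im2col(x, kh, kw)
    out = np.einsum("npc,ncf->npf", cols, w_eff).reshape(n, h, w, cout) + np.asarray(bias)
    if activation is not None:
        out = activation(out)
    return out[0] if squeeze else out
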