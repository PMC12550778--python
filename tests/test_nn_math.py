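"""Oracle checks for the network math kernels.

Each forward primitive is compared against an independent brute-force
implementation (explicit loops / hand-evaluated values), and the layer
backward passes are verified against central finite differences.
"""

import numpy as np
import pytest

from sharkfuse.nn import functional as F
from sharkfuse.nn import layers as L


def conv_loops(x, kernel, bias):
    """Quadruple-loop same-padded cross-correlation oracle."""
    h, w, cin = x.shape
    kh, kw, _, cout = kernel.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((h, w, cout))
    for i in range(h):
        for j in range(w):
            for f in range(cout):
                acc = 0.0
                for a in range(kh):
                    for b in range(kw):
                        for c in range(cin):
                            acc += kernel[a, b, c, f] * xp[i + a, j + b, c]
                out[i, j, f] = acc + bias[f]
    return np.maximum(out, 0.0)


class TestConvForward:
    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(6, 6, 2))
        k = rng.normal(size=(3, 3, 2, 4))
        b = rng.normal(size=4)
        np.testing.assert_allclose(F.conv_forward(x, k, b), conv_loops(x, k, b), atol=1e-9)

    def test_identity_kernel(self, rng):
        x = rng.random((5, 5, 1))  # nonnegative, so ReLU is a no-op
        k = np.zeros((3, 3, 1, 1))
        k[1, 1, 0, 0] = 1.0
        np.testing.assert_allclose(F.conv_forward(x, k, 0.0), x, atol=1e-12)

    def test_zero_kernel_and_scalar_case(self):
        x = np.full((4, 4, 2), 3.0)
        assert np.all(F.conv_forward(x, np.zeros((3, 3, 2, 1)), 0.0) == 0)
        out = F.conv_forward(np.array([[[5.0]]]), np.array([[[[2.0]]]]), np.array([1.0]))
        assert out.item() == pytest.approx(11.0)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channel"):
            F.conv_forward(rng.normal(size=(4, 4, 3)), rng.normal(size=(3, 3, 2, 1)))


class TestMaxpool:
    def test_hand_cases(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert F.maxpool(x, (2, 2)).item() == 4.0
        const = np.full((4, 6, 2), 2.5)
        assert np.all(F.maxpool(const, (2, 2)) == 2.5)

    def test_global_window_is_per_channel_max(self, rng):
        x = rng.normal(size=(4, 4, 3))
        np.testing.assert_allclose(
            F.maxpool(x, (4, 4))[0, 0], x.max(axis=(0, 1)), atol=1e-12
        )


class TestSoftmax:
    def test_symmetry_and_forced_values(self):
        np.testing.assert_allclose(F.softmax([0.0, 0.0, 0.0]), np.full(3, 1 / 3), atol=1e-12)
        np.testing.assert_allclose(
            F.softmax([0.0, np.log(2), np.log(3)]), [1 / 6, 1 / 3, 1 / 2], atol=1e-12
        )

    def test_shift_invariance_and_normalization(self, rng):
        z = rng.normal(size=(10, 5)) * 10
        np.testing.assert_allclose(F.softmax(z), F.softmax(z + 123.456), atol=1e-12)
        np.testing.assert_allclose(F.softmax(z).sum(axis=-1), 1.0, atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            F.softmax([np.inf, 0.0])


def attention_loops(Q, K, V):
    """Per-row explicit softmax-weighted-sum oracle."""
    out = np.zeros((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        scores = np.array([Q[i] @ K[j] for j in range(K.shape[0])]) / np.sqrt(Q.shape[1])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        out[i] = sum(w[j] * V[j] for j in range(V.shape[0]))
    return out


class TestAttention:
    def test_matches_row_oracle(self, rng):
        Q, K, V = rng.normal(size=(3, 4, 3))
        np.testing.assert_allclose(
            F.scaled_dot_attention(Q, K, V), attention_loops(Q, K, V), atol=1e-9
        )

    def test_zero_queries_average_values(self, rng):
        K, V = rng.normal(size=(2, 5, 3))
        out = F.scaled_dot_attention(np.zeros((4, 3)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)), atol=1e-12)

    def test_singleton_key(self, rng):
        out = F.scaled_dot_attention(rng.normal(size=(3, 2)), np.ones((1, 2)), np.array([[7.0]]))
        np.testing.assert_allclose(out, 7.0, atol=1e-12)

    def test_hand_evaluated_2x1_case(self):
        q = k = v = np.array([[1.0], [0.0]])
        out = F.scaled_dot_attention(q, k, v)
        e = np.e
        assert out[0, 0] == pytest.approx(e / (e + 1), abs=1e-4)  # ~0.7311
        assert out[1, 0] == pytest.approx(0.5)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            F.scaled_dot_attention(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)),
                                   rng.normal(size=(2, 4)))


class TestMultiHead:
    def test_single_head_identity_output_collapses(self, rng):
        S = rng.normal(size=(5, 4))
        eye = np.eye(4)
        out = F.multi_head_attention(S, 1, eye, eye, eye, eye)
        np.testing.assert_allclose(out, F.scaled_dot_attention(S, S, S), atol=1e-12)

    def test_zero_projections_and_shape(self, rng):
        S = rng.normal(size=(6, 8))
        z = np.zeros((8, 8))
        assert np.all(F.multi_head_attention(S, 2, z, z, z, z) == 0)
        w = rng.normal(size=(4, 8, 8))
        out = F.multi_head_attention(S, 4, w[0], w[1], w[2], w[3])
        assert out.shape == S.shape

    def test_divisibility_enforced(self, rng):
        S = rng.normal(size=(4, 6))
        w = np.eye(6)
        with pytest.raises(ValueError, match="divisible"):
            F.multi_head_attention(S, 4, w, w, w, w)


class TestPositionalEncoding:
    def test_position_zero_and_range(self):
        pe = F.positional_encoding(8, 6)
        assert np.all(pe[0, 0::2] == 0.0)
        assert np.all(pe[0, 1::2] == 1.0)
        assert np.all(np.abs(pe) <= 1.0)

    def test_direct_evaluation(self):
        assert F.positional_encoding(2, 2)[1, 0] == pytest.approx(np.sin(1.0))

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError, match="even"):
            F.positional_encoding(4, 3)


class TestInceptionBlock:
    @staticmethod
    def _weights(rng, cin, widths, zero=False):
        mk = (lambda s: np.zeros(s)) if zero else (lambda s: rng.normal(size=s))
        w1, w3, w5, wp = widths
        return dict(
            w1=mk((1, 1, cin, w1)), b1=np.zeros(w1),
            w3=mk((3, 3, cin, w3)), b3=np.zeros(w3),
            w5=mk((5, 5, cin, w5)), b5=np.zeros(w5),
            wp=mk((1, 1, cin, wp)), bp=np.zeros(wp),
        )

    def test_channel_concat_and_spatial_preserved(self, rng):
        x = rng.normal(size=(8, 8, 3))
        out = F.inception_block(x, **self._weights(rng, 3, (8, 16, 4, 4)))
        assert out.shape == (8, 8, 32)

    def test_zero_weights_zero_output(self, rng):
        x = rng.normal(size=(6, 6, 2))
        out = F.inception_block(x, **self._weights(rng, 2, (2, 2, 2, 2), zero=True))
        assert np.all(out == 0)


class TestDynamicConv:
    def test_one_hot_gate_selects_kernel(self, rng):
        x = rng.normal(size=(6, 6, 2))
        wb = rng.normal(size=(3, 3, 3, 2, 4))
        for k in range(3):
            g = np.zeros(3)
            g[k] = 1.0
            np.testing.assert_allclose(
                F.dynamic_conv(x, wb, g), F.conv_forward(x, wb[k]), atol=1e-9
            )

    def test_identical_kernels_ignore_gate(self, rng):
        x = rng.normal(size=(5, 5, 1))
        base = rng.normal(size=(3, 3, 1, 2))
        wb = np.stack([base] * 4)
        g = rng.dirichlet(np.ones(4))
        np.testing.assert_allclose(
            F.dynamic_conv(x, wb, g), F.conv_forward(x, base), atol=1e-9
        )

    def test_single_kernel_and_simplex_validation(self, rng):
        x = rng.normal(size=(4, 4, 1))
        wb = rng.normal(size=(1, 3, 3, 1, 2))
        np.testing.assert_allclose(
            F.dynamic_conv(x, wb, [1.0]), F.conv_forward(x, wb[0]), atol=1e-12
        )
        with pytest.raises(ValueError, match="simplex"):
            F.dynamic_conv(x, wb, [0.5])


# ---- gradient checks for the trainable layers --------------------------------


def _num_grad(f, x, eps=1e-5):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


LAYER_CASES = [
    (lambda: L.Conv2D(2, 3), (5, 5, 2)),
    (lambda: L.MaxPool2D(2), (4, 4, 2)),
    (lambda: L.Dense(3), (6,)),
    (lambda: L.GlobalAvgPool(), (3, 3, 2)),
    (lambda: L.PatchEmbed(2, 4), (4, 4, 1)),
    (lambda: L.MultiHeadSelfAttention(2), (3, 4)),
    (lambda: L.InceptionBlock((2, 2, 1, 1)), (5, 5, 2)),
    (lambda: L.DynamicConv2D(2, 3, 3), (4, 4, 2)),
]


@pytest.mark.parametrize("make_layer,in_shape", LAYER_CASES,
                         ids=[c[0]().__class__.__name__ for c in LAYER_CASES])
def test_layer_backward_matches_finite_differences(make_layer, in_shape, rng):
    """Analytic input and parameter gradients agree with central differences."""
    layer = make_layer()
    layer.build(np.random.default_rng(0), in_shape)
    # float64 parameters for accurate finite differences
    for k in layer.params:
        layer.params[k] = layer.params[k].astype(np.float64)
    x = rng.normal(size=(2, *in_shape))
    w = rng.normal(size=(2, *layer.forward(x).shape[1:]))  # random loss projection

    def loss():
        return float((layer.forward(x) * w).sum())

    loss()
    dx = layer.backward(w.copy())
    np.testing.assert_allclose(dx, _num_grad(loss, x), atol=1e-6, rtol=1e-4)
    for name, p in layer.params.items():
        np.testing.assert_allclose(
            layer.grads[name], _num_grad(loss, p), atol=1e-6, rtol=1e-4,
            err_msg=f"param {name}",
        )
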