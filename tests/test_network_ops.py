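"""The network building blocks against independent scalar oracles."""

import numpy as np
import pytest

from mhcbind import _autodiff as ad
from mhcbind._autodiff import Tensor
from mhcbind.network import (
    CBAMParams,
    LSTMCellParams,
    cbam_apply,
    cbam_channel_attention,
    cbam_spatial_attention,
    conv1d_forward,
    conv2d_forward,
    lstm_step,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------
# scalar oracles: direct elementwise evaluation of the defining formulas
# ---------------------------------------------------------------------

def oracle_conv1d(X, W, b):
    m = len(W)
    out = []
    for i in range(len(X) - m + 1):
        acc = 0.0
        for j in range(m):
            acc += float(np.sum(np.atleast_1d(W[j]) * np.atleast_1d(X[i + j])))
        out.append(acc + b)
    return np.array(out)


def oracle_conv2d(x, w, b):
    K, L = w.shape
    H, W_ = x.shape
    out = np.zeros((H - K + 1, W_ - L + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            acc = 0.0
            for k in range(K):
                for l in range(L):
                    acc += w[k, l] * x[i + k, j + l]
            out[i, j] = acc + b
    return out


def oracle_lstm(x, h, C, p):
    hx = np.concatenate([h, x])
    f = sigmoid(p.W_f @ hx + p.b_f)
    i = sigmoid(p.W_i @ hx + p.b_i)
    o = sigmoid(p.W_o @ hx + p.b_o)
    ct = np.tanh(p.W_c @ hx + p.b_c)
    Cn = f * C + i * ct
    return f, i, o, ct, Cn, o * np.tanh(Cn)


def random_cbam_params(rng, C, ks=3, reduction=1):
    cr = max(C // reduction, 1)
    return CBAMParams(
        mlp_w1=rng.normal(size=(C, cr)), mlp_b1=rng.normal(size=cr),
        mlp_w2=rng.normal(size=(cr, C)), mlp_b2=rng.normal(size=C),
        spatial_w=rng.normal(size=(2, ks, ks)), spatial_b=float(rng.normal()),
    )


def oracle_cbam(F, p):
    C, H, W = F.shape
    # channel attention
    def mlp(s):
        return np.maximum(s @ p.mlp_w1 + p.mlp_b1, 0.0) @ p.mlp_w2 + p.mlp_b2

    mc = sigmoid(mlp(F.mean(axis=(1, 2))) + mlp(F.max(axis=(1, 2))))
    f1 = mc[:, None, None] * F
    # spatial attention
    pooled = np.stack([f1.mean(axis=0), f1.max(axis=0)])
    ks = p.spatial_w.shape[1]
    pad = ks // 2
    padded = np.pad(pooled, ((0, 0), (pad, pad), (pad, pad)))
    ms = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            ms[i, j] = np.sum(p.spatial_w * padded[:, i : i + ks, j : j + ks])
    return sigmoid(ms + p.spatial_b)[None] * f1


# ---------------------------------------------------------------------
# 1D convolution
# ---------------------------------------------------------------------

class TestConv1d:
    def test_hand_example(self):
        assert conv1d_forward([1, 2, 3], [1, 1]).tolist() == [3.0, 5.0]

    def test_identity_kernel(self):
        x = np.array([3.0, -1.0, 4.0])
        assert np.array_equal(conv1d_forward(x, [1.0]), x)

    def test_zero_input_relu(self):
        out = conv1d_forward([0, 0, 0], [2.5, -1.0],
                             activation=lambda z: np.maximum(z, 0))
        assert np.all(out == 0.0)

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv1d_forward([1.0], [1.0, 1.0])

    def test_matches_scalar_oracle_randomly(self):
        rng = np.random.default_rng(1)
        for _ in range(120):
            L = rng.integers(2, 9)
            m = rng.integers(1, L + 1)
            C = rng.integers(1, 4)
            X = rng.normal(size=(L, C))
            W = rng.normal(size=(m, C))
            b = float(rng.normal())
            np.testing.assert_allclose(
                conv1d_forward(X, W, b), oracle_conv1d(X, W, b), atol=1e-6)

    def test_graph_conv_matches_reference(self, float64_graph):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 7, 2))
        w = rng.normal(size=(4, 3, 2))
        b = rng.normal(size=4)
        out = ad.conv1d(Tensor(x), Tensor(w), Tensor(b)).data
        for bi in range(3):
            for f in range(4):
                np.testing.assert_allclose(
                    out[bi, :, f], oracle_conv1d(x[bi], w[f], b[f]), atol=1e-9)


# ---------------------------------------------------------------------
# 2D convolution
# ---------------------------------------------------------------------

class TestConv2d:
    def test_all_ones_2x2(self):
        out = conv2d_forward(np.ones((2, 2)), np.ones((2, 2)))
        assert out.shape == (1, 1) and out[0, 0] == 4.0

    def test_delta_kernel_shifts(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 5))
        w = np.zeros((2, 2)); w[1, 0] = 1.0
        np.testing.assert_allclose(conv2d_forward(x, w), x[1:5, 0:4])

    def test_zero_input_gives_activated_bias(self):
        out = conv2d_forward(np.zeros((3, 3)), np.ones((2, 2)), b=-1.5,
                             activation=np.tanh)
        np.testing.assert_allclose(out, np.tanh(-1.5) * np.ones((2, 2)))

    def test_kernel_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            conv2d_forward(np.ones((2, 2)), np.ones((3, 3)))

    def test_matches_scalar_oracle_randomly(self):
        rng = np.random.default_rng(4)
        for _ in range(120):
            H, W_ = rng.integers(2, 7, size=2)
            K = rng.integers(1, H + 1)
            L = rng.integers(1, W_ + 1)
            x = rng.normal(size=(H, W_))
            w = rng.normal(size=(K, L))
            b = float(rng.normal())
            np.testing.assert_allclose(
                conv2d_forward(x, w, b), oracle_conv2d(x, w, b), atol=1e-6)

    def test_graph_conv_matches_reference(self, float64_graph):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 3, 6, 5))
        w = rng.normal(size=(4, 3, 2, 3))
        b = rng.normal(size=4)
        out = ad.conv2d(Tensor(x), Tensor(w), Tensor(b)).data
        for bi in range(2):
            for f in range(4):
                expect = sum(oracle_conv2d(x[bi, c], w[f, c], 0.0)
                             for c in range(3)) + b[f]
                np.testing.assert_allclose(out[bi, f], expect, atol=1e-9)


# ---------------------------------------------------------------------
# LSTM cell
# ---------------------------------------------------------------------

def lstm_params(rng, H, X):
    size = (H, H + X)
    return LSTMCellParams(
        W_f=rng.normal(size=size), W_i=rng.normal(size=size),
        W_o=rng.normal(size=size), W_c=rng.normal(size=size),
        b_f=rng.normal(size=H), b_i=rng.normal(size=H),
        b_o=rng.normal(size=H), b_c=rng.normal(size=H),
    )


class TestLSTMStep:
    def test_all_zero_parameters(self):
        H, X = 3, 2
        p = LSTMCellParams(*(np.zeros((H, H + X)),) * 4, *(np.zeros(H),) * 4)
        s = lstm_step(np.zeros(X), np.zeros(H), np.zeros(H), p)
        np.testing.assert_allclose(s.f_t, 0.5)
        np.testing.assert_allclose(s.i_t, 0.5)
        np.testing.assert_allclose(s.o_t, 0.5)
        np.testing.assert_allclose(s.c_tilde, 0.0)
        np.testing.assert_allclose(s.C_t, 0.0)
        np.testing.assert_allclose(s.h_t, 0.0)

    def test_saturated_forget_gate_preserves_cell_state(self):
        # b_f -> +inf, input path off: C_t ~= C_prev
        H, X = 2, 2
        p = LSTMCellParams(
            W_f=np.zeros((H, H + X)), W_i=np.zeros((H, H + X)),
            W_o=np.zeros((H, H + X)), W_c=np.zeros((H, H + X)),
            b_f=np.full(H, 100.0), b_i=np.full(H, -100.0),
            b_o=np.zeros(H), b_c=np.zeros(H),
        )
        C_prev = np.array([0.7, -0.3])
        s = lstm_step(np.ones(X), np.zeros(H), C_prev, p)
        np.testing.assert_allclose(s.C_t, C_prev, atol=1e-6)

    def test_gate_ranges(self):
        rng = np.random.default_rng(6)
        p = lstm_params(rng, 4, 3)
        s = lstm_step(rng.normal(size=3), rng.normal(size=4),
                      rng.normal(size=4), p)
        for gate in (s.f_t, s.i_t, s.o_t):
            assert np.all((gate > 0) & (gate < 1))
        assert np.all(np.abs(s.c_tilde) < 1)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        p = lstm_params(rng, 2, 2)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(3), np.zeros(2), np.zeros(2), p)

    def test_matches_scalar_oracle_randomly(self):
        rng = np.random.default_rng(8)
        for _ in range(120):
            H = int(rng.integers(1, 5))
            X = int(rng.integers(1, 5))
            p = lstm_params(rng, H, X)
            x, h, C = (rng.normal(size=X), rng.normal(size=H),
                       rng.normal(size=H))
            s = lstm_step(x, h, C, p)
            f, i, o, ct, Cn, hn = oracle_lstm(x, h, C, p)
            np.testing.assert_allclose(s.f_t, f, atol=1e-6)
            np.testing.assert_allclose(s.C_t, Cn, atol=1e-6)
            np.testing.assert_allclose(s.h_t, hn, atol=1e-6)


# ---------------------------------------------------------------------
# CBAM
# ---------------------------------------------------------------------

class TestCBAM:
    def identity_mlp(self, C, ks=1):
        return CBAMParams(
            mlp_w1=np.eye(C), mlp_b1=np.zeros(C),
            mlp_w2=np.eye(C), mlp_b2=np.zeros(C),
            spatial_w=np.zeros((2, ks, ks)), spatial_b=0.0,
        )

    def test_channel_attention_identity_mlp_constant_channels(self):
        # per-channel constant c > 0: AvgPool = MaxPool = c -> sigmoid(2c)
        c = np.array([0.5, 1.5, 2.0])
        F = np.broadcast_to(c[:, None, None], (3, 4, 5)).copy()
        mc = cbam_channel_attention(F, self.identity_mlp(3))
        np.testing.assert_allclose(mc, sigmoid(2 * c), atol=1e-12)

    def test_channel_attention_in_open_unit_interval(self):
        rng = np.random.default_rng(9)
        p = random_cbam_params(rng, 4)
        mc = cbam_channel_attention(rng.normal(size=(4, 3, 3)), p)
        assert np.all((mc > 0) & (mc < 1))

    def test_identical_channels_get_equal_weights_under_symmetric_mlp(self):
        rng = np.random.default_rng(9)
        F = rng.normal(size=(3, 3, 3))
        F[1] = F[0]
        mc = cbam_channel_attention(F, self.identity_mlp(3))
        assert mc[0] == pytest.approx(mc[1], abs=1e-12)

    def test_spatial_attention_zero_kernel_is_half(self):
        rng = np.random.default_rng(10)
        p = self.identity_mlp(2, ks=3)
        ms = cbam_spatial_attention(rng.normal(size=(2, 4, 4)), p)
        np.testing.assert_allclose(ms, 0.5)

    def test_spatial_pooled_maps_coincide_for_single_channel(self):
        # avg across channels == max across channels == the channel itself
        F = np.arange(6.0).reshape(1, 2, 3)
        np.testing.assert_allclose(F.mean(axis=0), F[0])
        np.testing.assert_allclose(F.max(axis=0), F[0])

    def test_spatial_toy_1x1_kernel_hand_oracle(self):
        F = np.array([[[1.0, -2.0], [0.5, 3.0]]])  # (1, 2, 2)
        w = np.array([[[2.0]], [[-1.0]]])  # 1x1 kernel over [avg; max]
        p = CBAMParams(mlp_w1=np.eye(1), mlp_b1=np.zeros(1),
                       mlp_w2=np.eye(1), mlp_b2=np.zeros(1),
                       spatial_w=w, spatial_b=0.25)
        # single channel: avg map = max map = F[0]
        expect = sigmoid(2.0 * F[0] - 1.0 * F[0] + 0.25)
        np.testing.assert_allclose(cbam_spatial_attention(F, p), expect,
                                   atol=1e-12)

    def test_apply_zero_input(self):
        rng = np.random.default_rng(11)
        p = random_cbam_params(rng, 3)
        assert np.all(cbam_apply(np.zeros((3, 4, 4)), p) == 0.0)

    def test_apply_saturated_attention_recovers_input(self):
        C = 2
        p = CBAMParams(mlp_w1=np.zeros((C, C)), mlp_b1=np.zeros(C),
                       mlp_w2=np.zeros((C, C)), mlp_b2=np.full(C, 100.0),
                       spatial_w=np.zeros((2, 3, 3)), spatial_b=100.0)
        rng = np.random.default_rng(12)
        F = rng.normal(size=(C, 5, 4))
        np.testing.assert_allclose(cbam_apply(F, p), F, atol=1e-4)

    def test_apply_is_contraction(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            C = int(rng.integers(1, 5))
            p = random_cbam_params(rng, C)
            F = rng.normal(size=(C, int(rng.integers(1, 6)),
                                 int(rng.integers(1, 6))))
            out = cbam_apply(F, p)
            assert np.all(np.abs(out) <= np.abs(F) + 1e-12)

    def test_matches_scalar_oracle_randomly(self):
        rng = np.random.default_rng(14)
        for _ in range(120):
            C = int(rng.integers(1, 5))
            H = int(rng.integers(1, 6))
            W = int(rng.integers(1, 6))
            p = random_cbam_params(rng, C, ks=int(rng.choice([1, 3])))
            F = rng.normal(size=(C, H, W))
            np.testing.assert_allclose(cbam_apply(F, p), oracle_cbam(F, p),
                                       atol=1e-6)
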