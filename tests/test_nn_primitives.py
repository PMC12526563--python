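"""Unit tests for the reusable network blocks."""

import numpy as np
import pytest

from falsseg import autograd as ag
from falsseg.autograd import Tensor
from falsseg.nn_primitives import (
    C2f,
    Conv,
    Conv2d,
    ConvGN,
    ConvSpec,
    DFL,
    Scale,
    SPPF,
    ShapeError,
)

RNG = np.random.default_rng(0)


def rand(*shape):
    return Tensor(RNG.normal(0, 1, shape).astype(np.float32))


class TestConv:
    def test_stride2_halves_spatial_size(self):
        y = Conv(3, 16, 3, 2)(rand(1, 3, 64, 64))
        assert y.shape == (1, 16, 32, 32)

    def test_output_shape_formula(self):
        spec = ConvSpec(4, 7, (5, 3), (2, 1), (0, 2))
        layer = Conv2d(4, 7, (5, 3), (2, 1), (0, 2))
        y = layer(rand(2, 4, 17, 11))
        assert y.shape[2:] == spec.out_hw(17, 11)

    def test_parameter_count_3x3_s2(self):
        # 3x3, 16->32: 4608 conv weights + 64 norm affine = 4672 trainable
        layer = Conv(16, 32, 3, 2)
        assert layer.num_parameters() == 4672
        # deploy count folds the norm into a bias
        assert layer.fused_param_count() == 4608 + 32

    def test_identity_1x1(self):
        layer = Conv2d(5, 5, 1, 1, bias=False)
        layer.weight.data[...] = np.eye(5, dtype=np.float32).reshape(5, 5, 1, 1)
        x = rand(1, 5, 6, 6)
        np.testing.assert_allclose(layer(x).data, x.data, atol=1e-6)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ShapeError, match="expected 4"):
            Conv2d(4, 8, 3)(rand(1, 3, 8, 8))


class TestC2f:
    def test_shape_preserved(self):
        y = C2f(64, 64, n=1, shortcut=True)(rand(1, 64, 16, 16))
        assert y.shape == (1, 64, 16, 16)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError, match="even"):
            C2f(64, 63, 1)

    def test_param_count_matches_enumeration(self):
        # independent per-tensor enumeration of C2f(64->64, n=1, shortcut)
        c = 32
        cv1 = 64 * 2 * c + 2 * 2 * c
        cv2 = 3 * c * 64 + 2 * 64
        bottleneck = 2 * (9 * c * c + 2 * c)
        assert C2f(64, 64, 1, True).num_parameters() == cv1 + cv2 + bottleneck

    def test_zero_input_finite(self):
        y = C2f(32, 32, 2, True)(Tensor(np.zeros((1, 32, 8, 8), np.float32)))
        assert np.isfinite(y.data).all()


class TestSPPF:
    def test_shape_preserved(self):
        y = SPPF(64, 64)(rand(1, 64, 10, 10))
        assert y.shape == (1, 64, 10, 10)

    def test_constant_input_constant_output(self):
        layer = SPPF(8, 8).eval()
        x = Tensor(np.full((1, 8, 9, 9), 0.7, np.float32))
        y = layer(x).data
        # max-pool of a constant is the constant, so every spatial position
        # sees the same fused-conv input
        assert np.allclose(y, y[:, :, :1, :1], atol=1e-5)

    def test_chained_5x5_equals_parallel_5_9_13(self):
        x = RNG.normal(0, 1, (1, 4, 8, 8)).astype(np.float32)
        t = Tensor(x)
        p5 = ag.max_pool2d(t, 5, 1)
        p9 = ag.max_pool2d(p5, 5, 1)
        p13 = ag.max_pool2d(p9, 5, 1)
        q9 = ag.max_pool2d(t, 9, 1)
        q13 = ag.max_pool2d(t, 13, 1)
        np.testing.assert_allclose(p9.data, q9.data, atol=1e-6)
        np.testing.assert_allclose(p13.data, q13.data, atol=1e-6)


class TestConvGN:
    def test_batch_independence(self):
        layer = ConvGN(8, 16, 3).eval()
        x4 = rand(4, 8, 10, 10)
        y4 = layer(x4).data
        y1 = layer(Tensor(x4.data[2:3])).data
        np.testing.assert_allclose(y4[2:3], y1, atol=1e-5)

    def test_groups_equal_channels_is_instance_norm(self):
        x = RNG.normal(0, 1, (2, 8, 6, 6)).astype(np.float32)
        layer = ConvGN(8, 8, 1, groups=8, act=False)
        layer.conv.weight.data[...] = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1)
        y = layer(Tensor(x)).data
        # direct per-channel normalisation oracle
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        np.testing.assert_allclose(y, (x - mu) / np.sqrt(var + 1e-5), atol=1e-4)

    def test_groups_one_is_layer_norm(self):
        x = RNG.normal(0, 1, (2, 8, 6, 6)).astype(np.float32)
        layer = ConvGN(8, 8, 1, groups=1, act=False)
        layer.conv.weight.data[...] = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1)
        y = layer(Tensor(x)).data
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        np.testing.assert_allclose(y, (x - mu) / np.sqrt(var + 1e-5), atol=1e-4)

    def test_constant_channel_normalises_to_zero(self):
        layer = ConvGN(4, 4, 1, groups=4, act=False)
        layer.conv.weight.data[...] = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
        y = layer(Tensor(np.full((1, 4, 5, 5), 3.0, np.float32))).data
        assert np.abs(y).max() < 1e-3

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ConvGN(8, 20, 3, groups=16)


class TestScale:
    def test_identity_at_init(self):
        x = rand(2, 64, 4, 4)
        np.testing.assert_array_equal(Scale()(x).data, x.data)

    def test_scalar_multiply_and_annihilator(self):
        s = Scale(2.0)
        np.testing.assert_allclose(s(Tensor([0.5, -1.0])).data, [1.0, -2.0])
        s.theta.data[...] = 0.0
        assert np.all(s(Tensor([3.0, 4.0])).data == 0.0)

    def test_gradient_reaches_theta(self):
        s = Scale(1.0)
        out = s(rand(3, 4))
        out.sum().backward()
        assert s.theta.grad is not None and abs(s.theta.grad) > 0


class TestDFL:
    def test_one_hot_spike_decodes_to_bin(self):
        dfl = DFL(16)
        logits = np.zeros((1, 1, 16, 1), np.float32)
        logits[0, 0, 11, 0] = 30.0
        assert abs(dfl(Tensor(logits)).data[0, 0, 0] - 11.0) < 1e-4

    def test_uniform_logits_decode_to_midpoint(self):
        dfl = DFL(16)
        d = dfl(Tensor(np.zeros((1, 4, 16, 5), np.float32))).data
        np.testing.assert_allclose(d, 7.5, atol=1e-6)

    def test_matches_bruteforce_expectation(self):
        dfl = DFL(16)
        logits = RNG.normal(0, 2, (2, 4, 16, 7)).astype(np.float32)
        got = dfl(Tensor(logits)).data
        e = np.exp(logits - logits.max(axis=2, keepdims=True))
        p = e / e.sum(axis=2, keepdims=True)
        want = (p * np.arange(16).reshape(1, 1, 16, 1)).sum(axis=2)
        np.testing.assert_allclose(got, want, atol=1e-5)
        assert got.min() >= 0 and got.max() <= 15

    def test_reg_max_too_small_rejected(self):
        with pytest.raises(ValueError):
            DFL(1)


def test_blocks_preserve_batch_and_finiteness():
    x = rand(3, 16, 12, 12)
    for block in (Conv(16, 8, 3), C2f(16, 16, 1, True), SPPF(16, 16), ConvGN(16, 16, 3)):
        y = block(x)
        assert y.shape[0] == 3 and np.isfinite(y.data).all()
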