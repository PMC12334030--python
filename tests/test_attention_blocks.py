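"""Behavioural tests of the attention token mixer and channel mixer."""

import numpy as np
import pytest

from lkdanet import nn
from lkdanet.attention_blocks import (ConfigurationError, DWCA, DWCAConfig,
                                      LKDABlock, LKDAttention,
                                      LKDAttentionConfig, SqueezeExcite)


def make_attention(channels, **kw):
    kw.setdefault("se_reduction", min(4, channels // 2))
    return LKDAttention(LKDAttentionConfig(channels, **kw),
                        rng=np.random.default_rng(0))


def zero_(param):
    param.data[...] = 0.0


def brute_force_depthwise(x, kernel, dilation):
    """Triple-loop sliding-window correlation with zero 'same' padding.

    Independent oracle for the depthwise convolutions: per channel, each
    output voxel is the sum of kernel taps times input voxels offset by
    dilation, out-of-range voxels contributing zero.
    """
    C, D, H, W = x.shape
    k = kernel.shape[-1]
    half = (k - 1) // 2
    out = np.zeros_like(x)
    for c in range(C):
        for z in range(D):
            for y in range(H):
                for xx in range(W):
                    acc = 0.0
                    for a in range(k):
                        for b in range(k):
                            for cc in range(k):
                                zz = z + (a - half) * dilation
                                yy = y + (b - half) * dilation
                                ww = xx + (cc - half) * dilation
                                if 0 <= zz < D and 0 <= yy < H and 0 <= ww < W:
                                    acc += kernel[c, a, b, cc] * x[c, zz, yy, ww]
                    out[c, z, y, xx] = acc
    return out


class TestProjectHalve:
    def test_halves_channels_and_preserves_space(self):
        attn = make_attention(48)
        out = attn.project_halve(nn.Tensor(np.random.default_rng(0)
                                           .normal(size=(1, 48, 8, 8, 8))))
        assert out.shape == (1, 24, 8, 8, 8)

    def test_identity_weights_select_first_channel(self):
        attn = make_attention(2)
        attn.proj.weight.data[...] = np.array([[[[[1.0]]], [[[0.0]]]]])
        zero_(attn.proj.bias)
        x = np.zeros((1, 2, 3, 3, 3))
        x[0, 0] = np.random.default_rng(1).normal(size=(3, 3, 3))
        out = attn.project_halve(nn.Tensor(x))
        assert np.allclose(out.data[0, 0], x[0, 0])

    def test_single_voxel_matches_matrix_vector_product(self):
        attn = make_attention(4)
        W = np.arange(8, dtype=float).reshape(2, 4)
        attn.proj.weight.data[...] = W.reshape(2, 4, 1, 1, 1)
        attn.proj.bias.data[...] = [0.5, -0.5]
        v = np.array([1.0, -2.0, 3.0, 0.25])
        out = attn.project_halve(nn.Tensor(v.reshape(1, 4, 1, 1, 1)))
        assert np.allclose(out.data.ravel(), W @ v + [0.5, -0.5])

    def test_odd_channel_count_rejected(self):
        with pytest.raises(ConfigurationError, match="47"):
            LKDAttentionConfig(47)


class TestCascade:
    def test_zero_weights_give_zero(self):
        attn = make_attention(4)
        zero_(attn.dw1.weight)
        zero_(attn.dw1.bias)
        zero_(attn.dw2.weight)
        zero_(attn.dw2.bias)
        x1, x2 = attn.cascade_dw(nn.Tensor(np.ones((1, 2, 6, 6, 6))))
        assert np.all(x1.data == 0) and np.all(x2.data == 0)

    def test_impulse_response_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        attn = make_attention(2)
        zero_(attn.dw1.bias)
        zero_(attn.dw2.bias)
        k1 = rng.normal(size=(1, 5, 5, 5))
        k2 = rng.normal(size=(1, 7, 7, 7))
        attn.dw1.weight.data[...] = k1[:, None][None].reshape(1, 1, 5, 5, 5)
        attn.dw2.weight.data[...] = k2[:, None][None].reshape(1, 1, 7, 7, 7)
        x = np.zeros((1, 15, 15, 15))
        x[0, 7, 7, 7] = 1.0  # unit impulse at the centre
        x1, x2 = attn.cascade_dw(nn.Tensor(x[None]))
        ref1 = brute_force_depthwise(x, k1, dilation=1)
        assert np.allclose(x1.data[0], ref1, atol=1e-5)
        ref2 = brute_force_depthwise(ref1, k2, dilation=3)
        assert np.allclose(x2.data[0], ref2, atol=1e-5)

    def test_channels_never_mix(self):
        attn = make_attention(4)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 2, 6, 6, 6))
        x1a, x2a = attn.cascade_dw(nn.Tensor(x))
        xp = x.copy()
        xp[:, 1] += rng.normal(size=(6, 6, 6))
        x1b, x2b = attn.cascade_dw(nn.Tensor(xp))
        assert np.allclose(x1a.data[:, 0], x1b.data[:, 0])
        assert np.allclose(x2a.data[:, 0], x2b.data[:, 0])
        assert not np.allclose(x1a.data[:, 1], x1b.data[:, 1])


class TestSpatialWeights:
    def test_zero_mixing_conv_gives_half_everywhere(self):
        attn = make_attention(4)
        zero_(attn.mix.weight)
        zero_(attn.mix.bias)
        w1, w2 = attn.spatial_weights(
            nn.Tensor(np.random.default_rng(0).normal(size=(1, 4, 5, 5, 5))))
        assert np.allclose(w1.data, 0.5) and np.allclose(w2.data, 0.5)

    def test_pooling_statistics(self):
        from lkdanet.nn import core as F
        x = np.zeros((1, 2, 1, 1, 1))
        x[0, :, 0, 0, 0] = [1.0, 3.0]
        t = nn.Tensor(x)
        assert F.channel_mean(t).data.item() == 2.0
        assert F.channel_max(t).data.item() == 3.0
        # constant across channels: avg equals max voxel-wise
        c = nn.Tensor(np.random.default_rng(1)
                      .normal(size=(1, 1, 4, 4, 4))
                      .repeat(3, axis=1))
        assert np.allclose(F.channel_mean(c).data, F.channel_max(c).data)

    def test_weights_strictly_inside_unit_interval(self):
        attn = make_attention(8)
        w1, w2 = attn.spatial_weights(
            nn.Tensor(np.random.default_rng(4).normal(size=(2, 8, 6, 6, 6))))
        for w in (w1, w2):
            assert (w.data > 0).all() and (w.data < 1).all()


class TestSqueezeExcite:
    def test_zero_gate_path_halves_input(self):
        se = SqueezeExcite(4, 2, rng=np.random.default_rng(0))
        for p in se.parameters():
            zero_(p)
        x = np.random.default_rng(5).normal(size=(1, 4, 3, 3, 3))
        assert np.allclose(se(nn.Tensor(x)).data, 0.5 * x)

    def test_zero_input_stays_zero(self):
        se = SqueezeExcite(4, 2, rng=np.random.default_rng(0))
        assert np.all(se(nn.Tensor(np.zeros((1, 4, 2, 2, 2)))).data == 0)

    def test_hand_computed_bottleneck_on_constant_volume(self):
        se = SqueezeExcite(4, 2, rng=np.random.default_rng(0))
        W1 = np.array([[0.1, 0.2, 0.3, 0.4], [-0.1, 0.0, 0.1, 0.2]])
        W2 = np.array([[1.0, 0.5], [0.0, -1.0], [0.2, 0.2], [-0.5, 1.5]])
        se.fc1.weight.data[...] = W1
        se.fc1.bias.data[...] = [0.05, -0.05]
        se.fc2.weight.data[...] = W2
        se.fc2.bias.data[...] = [0.0, 0.1, -0.1, 0.2]
        v = np.array([1.0, 2.0, -1.0, 0.5])
        x = np.broadcast_to(v[None, :, None, None, None], (1, 4, 2, 2, 2))
        h = np.maximum(W1 @ v + [0.05, -0.05], 0.0)
        gate = 1.0 / (1.0 + np.exp(-(W2 @ h + [0.0, 0.1, -0.1, 0.2])))
        out = se(nn.Tensor(np.array(x)))
        assert np.allclose(out.data[0, :, 0, 0, 0], gate * v, atol=1e-12)

    def test_reduction_larger_than_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            SqueezeExcite(2, 4, rng=np.random.default_rng(0))

    def test_gate_strictly_inside_unit_interval(self):
        se = SqueezeExcite(8, 4, rng=np.random.default_rng(1))
        g = se.gate(nn.Tensor(np.random.default_rng(6)
                              .normal(size=(3, 8, 4, 4, 4))))
        assert (g.data > 0).all() and (g.data < 1).all()


class TestDWCA:
    def test_parameter_count_is_13C(self):
        dwca = DWCA(DWCAConfig(48), rng=np.random.default_rng(0))
        assert dwca.num_parameters() == 13 * 48 == 624

    def test_zero_weights_give_zero(self):
        dwca = DWCA(DWCAConfig(4), rng=np.random.default_rng(0))
        for p in dwca.parameters():
            zero_(p)
        out = dwca(nn.Tensor(np.random.default_rng(7)
                             .normal(size=(1, 4, 3, 3, 3))))
        assert np.all(out.data == 0)

    def test_channel_independence(self):
        dwca = DWCA(DWCAConfig(4), rng=np.random.default_rng(0))
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1, 4, 3, 3, 3))
        base = dwca(nn.Tensor(x)).data
        xp = x.copy()
        xp[:, 2] += 1.0
        pert = dwca(nn.Tensor(xp)).data
        changed = [j for j in range(4)
                   if not np.allclose(base[:, j], pert[:, j])]
        assert changed == [2]


class TestLKDAttentionForward:
    def test_shape_preserved(self):
        attn = make_attention(48)
        x = nn.Tensor(np.random.default_rng(9).normal(size=(1, 48, 8, 8, 8)))
        assert attn(x).shape == (1, 48, 8, 8, 8)

    def test_zero_output_projection_gives_residual_identity(self):
        attn = make_attention(8)
        zero_(attn.out_proj.weight)
        zero_(attn.out_proj.bias)
        x = np.random.default_rng(10).normal(size=(2, 8, 5, 5, 5))
        out = attn(nn.Tensor(x))
        assert np.abs(out.data - x).max() == 0.0

    def test_single_voxel_hand_computation(self):
        """On a 1×1×1 volume every convolution is a per-channel affine map;
        the whole pipeline collapses to scalar arithmetic checked by hand."""
        attn = make_attention(2, se_reduction=1)
        x_in = np.array([2.0, -1.0])
        # projection 2 -> 1: weights (0.5, 0.25), bias 0.1
        attn.proj.weight.data[...] = np.array([0.5, 0.25]).reshape(1, 2, 1, 1, 1)
        attn.proj.bias.data[...] = [0.1]
        xp = 0.5 * 2.0 + 0.25 * -1.0 + 0.1
        # depthwise convs on a single voxel: only the centre tap touches it
        attn.dw1.weight.data[...] = 0.0
        attn.dw1.weight.data[0, 0, 2, 2, 2] = 0.8
        attn.dw1.bias.data[...] = [0.05]
        x1 = 0.8 * xp + 0.05
        attn.dw2.weight.data[...] = 0.0
        attn.dw2.weight.data[0, 0, 3, 3, 3] = -0.6
        attn.dw2.bias.data[...] = [0.2]
        x2 = -0.6 * x1 + 0.2
        # spatial statistics of [x1, x2]: mean and max over the 2 channels
        w_avg, w_max = (x1 + x2) / 2.0, max(x1, x2)
        attn.mix.weight.data[...] = 0.0
        attn.mix.weight.data[0, 0, 2, 2, 2] = 1.0   # w1 path reads the mean
        attn.mix.weight.data[1, 1, 2, 2, 2] = -1.0  # w2 path reads -max
        attn.mix.bias.data[...] = [0.0, 0.3]
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        w1, w2 = sig(w_avg), sig(-w_max + 0.3)
        x4 = w1 * x1 + w2 * x2
        # SE with r=1: 1 -> 1 -> 1 bottleneck on the pooled scalar
        attn.se.fc1.weight.data[...] = [[2.0]]
        attn.se.fc1.bias.data[...] = [0.1]
        attn.se.fc2.weight.data[...] = [[1.5]]
        attn.se.fc2.bias.data[...] = [-0.2]
        gate = sig(1.5 * max(2.0 * x4 + 0.1, 0.0) - 0.2)
        x4g = gate * x4
        # final projection 1 -> 2 and gated residual
        attn.out_proj.weight.data[...] = np.array([0.7, -0.3]).reshape(2, 1, 1, 1, 1)
        attn.out_proj.bias.data[...] = [0.0, 0.1]
        w3 = np.array([0.7 * x4g, -0.3 * x4g + 0.1])
        expected = w3 * x_in + x_in
        out = attn(nn.Tensor(x_in.reshape(1, 2, 1, 1, 1)))
        assert np.allclose(out.data.ravel(), expected, atol=1e-6)


class TestLKDABlock:
    def test_zeroing_output_layers_makes_identity(self):
        blk = LKDABlock(8, rng=np.random.default_rng(0))
        zero_(blk.attn.out_proj.weight)
        zero_(blk.attn.out_proj.bias)
        for p in blk.dwca.parameters():
            zero_(p)
        x = np.random.default_rng(11).normal(size=(2, 8, 4, 4, 4))
        out = blk(nn.Tensor(x))
        assert np.abs(out.data - x).max() == 0.0

    @pytest.mark.parametrize("shape", [(2, 96, 4, 4, 4), (1, 8, 3, 5, 7),
                                       (1, 4, 1, 1, 1)])
    def test_shape_preserved(self, shape):
        blk = LKDABlock(shape[1], rng=np.random.default_rng(0),
                        attention=LKDAttentionConfig(shape[1], se_reduction=2))
        x = nn.Tensor(np.random.default_rng(12).normal(size=shape))
        assert blk(x).shape == shape

    def test_gradient_reaches_every_input_voxel(self):
        blk = LKDABlock(4, rng=np.random.default_rng(1),
                        attention=LKDAttentionConfig(4, se_reduction=2))
        x = nn.Tensor(np.random.default_rng(13).normal(size=(1, 4, 5, 5, 5)),
                      requires_grad=True)
        blk(x).mean().backward()
        assert (x.grad != 0).all()
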