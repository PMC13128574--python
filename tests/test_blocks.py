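"""Building blocks: shapes, locality, gating, gradients."""

import numpy as np
import pytest

from anisoseg.autodiff import Tensor, no_grad
from anisoseg.blocks import (BlockConfig, ChannelAttention, Conv3dLayer,
                             Downsample, LayerNormChannels, ResidualBlock,
                             RVSSM, SAAModule, SIAModule, Upsample, VSSM)
from anisoseg.exceptions import ConfigurationError, DimensionError


def _vol(rng, shape=(1, 4, 2, 4, 4)):
    return Tensor(rng.standard_normal(shape).astype(np.float32))


def _grad_check(module, shape, rng, tol=3e-2, n_probe=4):
    """Finite-difference check of d(sum of squares)/d(input)."""
    x = rng.standard_normal(shape).astype(np.float64)
    xt = Tensor(x, requires_grad=True)
    (module(xt) ** 2).sum().backward()
    g = xt.grad
    eps = 1e-4

    def f(a):
        with no_grad():
            return float((module(Tensor(a)) ** 2).sum())

    for idx in rng.choice(x.size, size=n_probe, replace=False):
        i = np.unravel_index(idx, x.shape)
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num = (f(xp) - f(xm)) / (2 * eps)
        assert g[i] == pytest.approx(num, rel=tol, abs=1e-3), f"at {i}"


class TestBlockConfig:
    def test_invariants(self):
        with pytest.raises(ConfigurationError):
            BlockConfig(4, 4, kernel=(2, 3, 3))
        with pytest.raises(ConfigurationError):
            BlockConfig(4, 4, stride=(3, 1, 1))
        with pytest.raises(ConfigurationError):
            BlockConfig(4, 4, scan_kind="diagonal")


class TestChannelAttention:
    def test_zero_logits_halve_every_channel(self, rng):
        ca = ChannelAttention(4, reduction=4, rng=rng)
        for p in (ca.w1, ca.b1, ca.w2, ca.b2):
            p.data[...] = 0.0
        x = _vol(rng)
        out = ca(x)
        np.testing.assert_allclose(out.data, 0.5 * x.data, rtol=1e-6)

    def test_identical_channels_get_identical_gates(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        # identical MLP rows/columns for channels 0 and 1
        ca.w1.data[1] = ca.w1.data[0]
        ca.w2.data[:, 1] = ca.w2.data[:, 0]
        ca.b2.data[1] = ca.b2.data[0]
        x = rng.standard_normal((1, 4, 2, 3, 3)).astype(np.float32)
        x[:, 1] = x[:, 0]
        out = ca(Tensor(x))
        np.testing.assert_allclose(out.data[:, 1], out.data[:, 0], rtol=1e-6)

    def test_gate_is_spatially_constant(self, rng):
        ca = ChannelAttention(4, rng=rng)
        x = rng.uniform(0.5, 1.5, (1, 4, 2, 3, 3)).astype(np.float32)
        ratio = ca(Tensor(x)).data / x
        for c in range(4):
            np.testing.assert_allclose(ratio[0, c], ratio[0, c].ravel()[0], rtol=1e-5)

    def test_too_few_channels(self):
        with pytest.raises(ConfigurationError):
            ChannelAttention(2, reduction=4)


class TestResidualBlock:
    def test_zero_weights_reduce_to_activation(self, rng):
        rb = ResidualBlock(3, (1, 3, 3), rng=rng)
        for _, p in rb.named_parameters():
            if p.data.ndim >= 3 or p.data.ndim == 1:
                p.data[...] = 0.0
        rb.norm1.gamma.data[...] = 0.0   # zero branch entirely
        rb.norm2.gamma.data[...] = 0.0
        x = _vol(rng, (1, 3, 2, 4, 4))
        out = rb(x)
        expect = x.data * (1.0 / (1.0 + np.exp(-x.data)))   # SiLU
        np.testing.assert_allclose(out.data, expect, atol=1e-6)

    def test_shape_preserved_for_all_kernels(self, rng):
        for kernel in ((1, 3, 3), (3, 1, 1), (3, 3, 3)):
            rb = ResidualBlock(2, kernel, rng=rng)
            x = _vol(rng, (1, 2, 3, 4, 5))
            assert rb(x).shape == x.shape

    def test_depth_receptive_field_of_planar_kernel(self, rng):
        """A 1x3x3 residual block never mixes information across slices."""
        rb = ResidualBlock(2, (1, 3, 3), rng=rng)
        x = rng.standard_normal((1, 2, 3, 4, 4)).astype(np.float32)
        with no_grad():
            base = rb(Tensor(x)).data
            x2 = x.copy()
            x2[:, :, 0] += 5.0
            pert = rb(Tensor(x2)).data
        np.testing.assert_array_equal(base[:, :, 1:], pert[:, :, 1:])
        assert not np.array_equal(base[:, :, 0], pert[:, :, 0])

    def test_gradient(self, rng):
        _grad_check(ResidualBlock(2, (1, 3, 3), rng=rng), (1, 2, 2, 3, 3), rng)


class TestRVSSM:
    def test_zeroed_inner_transforms_give_identity(self, rng):
        block = RVSSM(4, "2d-expanded", state_dim=2, rng=rng)
        block.vssm = lambda x: x * 0.0
        block.attn = lambda x: x * 0.0
        x = _vol(rng)
        np.testing.assert_allclose(block(x).data, x.data, rtol=1e-6)

    @pytest.mark.parametrize("kind", ["2d-expanded", "3d-expanded", "bidirectional"])
    def test_shape_preserved_all_scan_kinds(self, rng, kind):
        block = RVSSM(4, kind, state_dim=2, rng=rng)
        x = _vol(rng, (1, 4, 2, 4, 4))
        assert block(x).shape == x.shape
        assert np.isfinite(block(x).data).all()

    def test_gradient_finite_and_nonzero(self, rng):
        block = RVSSM(4, "bidirectional", state_dim=2, rng=rng)
        x = Tensor(rng.standard_normal((1, 4, 2, 3, 3)), requires_grad=True)
        (block(x) ** 2).sum().backward()
        assert np.isfinite(x.grad).all() and np.abs(x.grad).max() > 0
        _grad_check(block, (1, 4, 2, 3, 3), rng)


class TestSAA:
    def test_channel_count_preserved(self, rng):
        saa = SAAModule(4, state_dim=2, rng=rng)
        x = _vol(rng, (1, 4, 2, 4, 4))
        assert saa(x).shape == x.shape

    def test_depth_one_input_passes(self, rng):
        saa = SAAModule(4, state_dim=2, rng=rng)
        x = _vol(rng, (1, 4, 1, 4, 4))
        assert saa(x).shape == x.shape

    def test_planar_branch_is_slice_local(self, rng):
        """Branch-1 (planar) output at slice d ignores other slices."""
        saa = SAAModule(4, state_dim=2, rng=rng)

        def branch1(x):
            return saa.res_plane(saa.conv_plane(saa.rvssm_plane(x)))

        x = rng.standard_normal((1, 4, 3, 4, 4)).astype(np.float32)
        with no_grad():
            base = branch1(Tensor(x)).data
            x2 = x.copy()
            x2[:, :, 2] += 3.0
            pert = branch1(Tensor(x2)).data
        np.testing.assert_allclose(base[:, :, :2], pert[:, :, :2], atol=1e-6)

    def test_identity_ssm_ablation_is_pure_convolution(self, rng):
        saa = SAAModule(4, use_ssm=False, rng=rng)
        x = _vol(rng, (1, 4, 2, 4, 4))
        out = saa(x)
        assert out.shape == x.shape and np.isfinite(out.data).all()
        names = [n for n, _ in saa.named_parameters()]
        assert not any("rvssm" in n for n in names)


class TestSIA:
    def test_two_distinct_scan_orders(self, rng):
        sia = SIAModule(4, state_dim=2, rng=rng)
        assert len(set(sia.orders)) == 2

    def test_shape_preserved_and_finite(self, rng):
        sia = SIAModule(4, state_dim=2, rng=rng)
        x = _vol(rng, (1, 4, 2, 4, 4))
        out = sia(x)
        assert out.shape == x.shape and np.isfinite(out.data).all()

    def test_identity_ssm_ablation_finite(self, rng):
        sia = SIAModule(4, use_ssm=False, rng=rng)
        x = _vol(rng, (1, 4, 2, 4, 4))
        assert np.isfinite(sia(x).data).all()


class TestResampling:
    def test_downsample_stride_arithmetic_table_schedule(self, rng):
        ds = Downsample(1, 2, (1, 2, 2), rng=rng)
        x = Tensor(rng.standard_normal((1, 1, 8, 256, 256)).astype(np.float32))
        with no_grad():
            assert ds(x).shape == (1, 2, 8, 128, 128)

    def test_downsample_identity_stride(self, rng):
        ds = Downsample(2, 3, (1, 1, 1), rng=rng)
        x = _vol(rng, (1, 2, 3, 5, 7))
        assert ds(x).shape == (1, 3, 3, 5, 7)

    def test_downsample_isotropic_stride(self, rng):
        ds = Downsample(1, 1, (2, 2, 2), rng=rng)
        x = Tensor(rng.standard_normal((1, 1, 8, 64, 64)).astype(np.float32))
        with no_grad():
            assert ds(x).shape == (1, 1, 4, 32, 32)

    def test_downsample_rejects_too_small_extent(self, rng):
        ds = Downsample(1, 1, (2, 2, 2), rng=rng)
        with pytest.raises(DimensionError):
            ds(Tensor(np.zeros((1, 1, 1, 4, 4), dtype=np.float32)))

    def test_upsample_constant_exactness(self, rng):
        up = Upsample(1, 1, rng=rng)
        up.conv.weight.data[...] = 1.0
        up.conv.bias.data[...] = 0.0
        x = Tensor(np.full((1, 1, 2, 4, 4), 3.0, dtype=np.float32))
        out = up(x, (4, 8, 8))
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-6)

    def test_upsample_doubles_only_requested_axes(self, rng):
        up = Upsample(2, 3, rng=rng)
        x = _vol(rng, (1, 2, 4, 8, 8))
        assert up(x, (4, 16, 16)).shape == (1, 3, 4, 16, 16)

    def test_upsample_preserves_linear_ramp(self, rng):
        up = Upsample(1, 1, rng=rng)
        up.conv.weight.data[...] = 1.0
        up.conv.bias.data[...] = 0.0
        ramp = np.broadcast_to(np.arange(8.0, dtype=np.float32), (1, 1, 2, 4, 8)).copy()
        out = up(Tensor(ramp), (2, 4, 16)).data
        diffs = np.diff(out[0, 0, 0, 0])
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-5)


class TestVSSMGradients:
    @pytest.mark.parametrize("kind", ["2d-expanded", "3d-expanded", "bidirectional"])
    def test_gradients_each_scan_kind(self, rng, kind):
        _grad_check(VSSM(2, kind, state_dim=2, rng=rng), (1, 2, 2, 4, 4), rng)

    def test_layernorm_and_conv_gradients(self, rng):
        _grad_check(LayerNormChannels(3), (1, 3, 2, 3, 3), rng)
        _grad_check(Conv3dLayer(2, 3, (1, 3, 3), rng=rng), (1, 2, 2, 4, 4), rng)
        _grad_check(ChannelAttention(4, rng=rng), (1, 4, 2, 3, 3), rng)
        _grad_check(SAAModule(4, state_dim=2, rng=rng), (2, 4, 2, 4, 4), rng,
                    n_probe=3)
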