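"""Network blocks against naive loop oracles, analytic attention cases,
parameter accounting and the ghost-efficiency claim."""

import numpy as np
import pytest

import orchardseg.autodiff as ad
from orchardseg import blocks
import oracles


def rand_input(rng, c, h=6, w=6, batch=2):
    return rng.standard_normal((batch, c, h, w)).astype(np.float32)


def randomize_bn(module, rng):
    """Give running statistics non-trivial values so eval-mode oracles
    exercise the normalisation arithmetic."""
    for name, buf in module.named_buffers():
        if name.endswith("running_mean"):
            buf[...] = rng.normal(0, 0.3, buf.shape)
        else:
            buf[...] = rng.uniform(0.5, 1.5, buf.shape)


def rel_err(a, b):
    return np.abs(a - b).max() / (np.abs(b).max() + 1e-9)


class TestGhostModule:
    def test_identity_construction_duplicates_input(self):
        """Primary = identity, cheap depthwise = centred delta: output is
        concat(x, x)."""
        gm = blocks.GhostModule(4, 8, r=2, act=None,
                                rng=np.random.default_rng(0))
        gm.primary.weight.data[:] = np.eye(4).reshape(4, 4, 1, 1)
        gm.primary.bn.running_mean[:] = 0
        gm.primary.bn.running_var[:] = 1 - blocks.BN_EPS
        gm.cheap.weight.data[:] = 0
        gm.cheap.weight.data[:, 0, 1, 1] = 1
        gm.cheap.bn.running_mean[:] = 0
        gm.cheap.bn.running_var[:] = 1 - blocks.BN_EPS
        x = np.random.default_rng(1).standard_normal((1, 4, 5, 5)).astype(np.float32)
        out = gm(ad.astensor(x)).data
        assert np.allclose(out, np.concatenate([x, x], axis=1), atol=1e-5)

    def test_parameter_count_16_to_32(self):
        gm = blocks.GhostModule(16, 32, r=2)
        assert gm.conv_weight_count() == 16 * 16 + 16 * 9 == 400
        dense = 16 * 32 * 9
        assert dense == 4608
        assert gm.conv_weight_count() < dense

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_composition(self, seed):
        rng = np.random.default_rng(seed)
        c1, r = int(rng.integers(2, 7)), 2
        c2 = int(rng.integers(1, 5)) * 2
        gm = blocks.GhostModule(c1, c2, r=r, rng=rng)
        randomize_bn(gm, rng)
        x = rand_input(rng, c1)
        assert rel_err(gm(ad.astensor(x)).data,
                       oracles.ghost_module_naive(gm, x)) < 1e-5


class TestSELayer:
    def test_zero_parameters_halve_the_input(self):
        se = blocks.SELayer(8, reduction=4)
        se.fc1.weight.data[:] = 0
        se.fc1.bias.data[:] = 0
        se.fc2.weight.data[:] = 0
        se.fc2.bias.data[:] = 0
        x = np.random.default_rng(0).standard_normal((2, 8, 4, 4)).astype(np.float32)
        out = se(ad.astensor(x)).data
        assert np.allclose(out, 0.5 * x, atol=1e-6)

    def test_constant_channel_pools_to_its_value(self):
        se = blocks.SELayer(4, rng=np.random.default_rng(3))
        x = np.zeros((1, 4, 5, 5), np.float32)
        x[0, 2] = 3.25
        pooled = ad.global_avg_pool(ad.astensor(x)).data
        assert pooled[0, 2, 0, 0] == pytest.approx(3.25)
        assert pooled[0, 0, 0, 0] == 0

    def test_scales_lie_in_unit_interval(self, rng):
        se = blocks.SELayer(8, rng=rng)
        x = rand_input(rng, 8)
        out = se(ad.astensor(x)).data
        ratio = out / np.where(np.abs(x) < 1e-9, 1, x)
        assert (out[x == 0] == 0).all()
        assert ratio[np.abs(x) > 1e-9].min() > 0
        assert ratio[np.abs(x) > 1e-9].max() < 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        c = int(rng.integers(1, 4)) * 4
        se = blocks.SELayer(c, rng=rng)
        x = rand_input(rng, c)
        assert rel_err(se(ad.astensor(x)).data, oracles.se_naive(se, x)) < 1e-5


class TestGhostBottleneck:
    def test_residual_identity_when_main_path_zeroed(self):
        gb = blocks.GhostBottleneck(8, 8, s=1, rng=np.random.default_rng(0))
        for _, p in gb.named_parameters():
            p.data[:] = 0
        x = np.random.default_rng(1).standard_normal((2, 8, 5, 5)).astype(np.float32)
        out = gb(ad.astensor(x)).data
        assert np.allclose(out, x, atol=1e-6)

    def test_stride2_halves_spatial_dims(self, rng):
        gb = blocks.GhostBottleneck(4, 8, s=2, rng=rng)
        out = gb(ad.astensor(rand_input(rng, 4, 32, 32, batch=1)))
        assert out.shape == (1, 8, 16, 16)

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            blocks.GhostBottleneck(4, 8, s=3)

    @pytest.mark.parametrize("seed,s,use_se", [
        (0, 1, False), (1, 2, False), (2, 1, True), (3, 2, True),
        (4, 2, True), (5, 1, False),
    ])
    def test_matches_compositional_oracle(self, seed, s, use_se):
        rng = np.random.default_rng(200 + seed)
        c1 = int(rng.integers(1, 3)) * 4
        c2 = int(rng.integers(1, 3)) * 8
        gb = blocks.GhostBottleneck(c1, c2, s=s, use_se=use_se, rng=rng)
        randomize_bn(gb, rng)
        x = rand_input(rng, c1)
        assert rel_err(gb(ad.astensor(x)).data,
                       oracles.ghost_bottleneck_naive(gb, x)) < 1e-5


class TestGAM:
    def test_zero_parameters_quarter_the_input(self):
        gam = blocks.GAM(8, reduction=4)
        for _, p in gam.named_parameters():
            p.data[:] = 0
        x = np.random.default_rng(0).standard_normal((2, 8, 6, 6)).astype(np.float32)
        out = gam(ad.astensor(x)).data
        assert np.allclose(out, 0.25 * x, atol=1e-6)

    def test_attention_never_amplifies(self, rng):
        gam = blocks.GAM(8, rng=rng)
        x = rand_input(rng, 8)
        out = gam(ad.astensor(x)).data
        assert (np.abs(out) <= np.abs(x) + 1e-6).all()

    def test_not_positively_homogeneous(self):
        """Attention is nonlinear: f(2x) != 2 f(x) in general."""
        gam = blocks.GAM(4, rng=np.random.default_rng(7))
        x = np.random.default_rng(8).standard_normal((1, 4, 5, 5)).astype(np.float32)
        f1 = gam(ad.astensor(x)).data
        f2 = gam(ad.astensor(2 * x)).data
        assert not np.allclose(f2, 2 * f1, rtol=1e-3, atol=1e-4)
        se = blocks.SELayer(4, rng=np.random.default_rng(9))
        s1 = se(ad.astensor(x)).data
        s2 = se(ad.astensor(2 * x)).data
        assert not np.allclose(s2, 2 * s1, rtol=1e-3, atol=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        gam = blocks.GAM(4, reduction=4, spatial_kernel=7, rng=rng)
        randomize_bn(gam, rng)
        x = rand_input(rng, 4)
        assert rel_err(gam(ad.astensor(x)).data,
                       oracles.gam_naive(gam, x)) < 1e-5


class TestConvBlock:
    def test_stride2_geometry(self, rng):
        conv = blocks.Conv(3, 8, 3, 2, rng=rng)
        out = conv(ad.astensor(rand_input(rng, 3, 64, 64, batch=1)))
        assert out.shape == (1, 8, 32, 32)

    def test_identity_1x1_is_activation_of_normalised_input(self, rng):
        conv = blocks.Conv(4, 4, 1, 1, rng=rng)
        conv.weight.data[:] = np.eye(4).reshape(4, 4, 1, 1)
        x = rand_input(rng, 4)
        out = conv(ad.astensor(x)).data
        ref = oracles.silu(oracles.batchnorm_eval_naive(
            x, conv.bn.gamma.data, conv.bn.beta.data,
            conv.bn.running_mean, conv.bn.running_var))
        assert rel_err(out, ref) < 1e-5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        c1, c2 = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        k = int(rng.choice([1, 3]))
        s = int(rng.choice([1, 2]))
        conv = blocks.Conv(c1, c2, k, s, rng=rng)
        randomize_bn(conv, rng)
        x = rand_input(rng, c1)
        assert rel_err(conv(ad.astensor(x)).data,
                       oracles.conv_block_naive(conv, x)) < 1e-5


class TestC2f:
    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_output_channels_match_config(self, n, rng):
        c2f = blocks.C2f(8, 12, n=n, rng=rng)
        out = c2f(ad.astensor(rand_input(rng, 8)))
        assert out.shape == (2, 12, 6, 6)

    def test_zeroed_bottleneck_reduces_to_split_concat_fuse(self, rng):
        c2f = blocks.C2f(8, 8, n=1, shortcut=False, rng=rng)
        b = c2f.bottlenecks[0]
        b.cv2.weight.data[:] = 0
        b.cv2.bn.gamma.data[:] = 0
        b.cv2.bn.beta.data[:] = 0
        x = rand_input(rng, 8)
        y = oracles.conv_block_naive(c2f.cv1, x)
        half = np.concatenate([y, np.zeros_like(y[:, :c2f.c])], axis=1)
        ref = oracles.conv_block_naive(c2f.cv2, half)
        assert rel_err(c2f(ad.astensor(x)).data, ref) < 1e-5

    @pytest.mark.parametrize("seed,n,shortcut", [
        (0, 1, False), (1, 2, True), (2, 3, False), (3, 1, True),
        (4, 2, False), (5, 3, True),
    ])
    def test_matches_stepwise_composition(self, seed, n, shortcut):
        rng = np.random.default_rng(500 + seed)
        c1 = int(rng.integers(1, 3)) * 4
        c2 = int(rng.integers(1, 3)) * 4
        c2f = blocks.C2f(c1, c2, n=n, shortcut=shortcut, rng=rng)
        randomize_bn(c2f, rng)
        x = rand_input(rng, c1)
        assert rel_err(c2f(ad.astensor(x)).data,
                       oracles.c2f_naive(c2f, x)) < 1e-5


class TestSPPF:
    def test_constant_input_gives_constant_fused_output(self, rng):
        sppf = blocks.SPPF(8, 8, rng=rng)
        x = np.full((1, 8, 8, 8), 0.7, np.float32)
        out = sppf(ad.astensor(x)).data
        # pooling a constant is the constant; output is spatially uniform
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-5)

    def test_chained_pools_equal_single_wide_pools(self, rng):
        x = rand_input(rng, 2, 12, 12, batch=1)
        t = ad.astensor(x)
        p1 = ad.maxpool2d(t, 5, 1, 2)
        p2 = ad.maxpool2d(p1, 5, 1, 2)
        p3 = ad.maxpool2d(p2, 5, 1, 2)
        assert np.allclose(p2.data, ad.maxpool2d(t, 9, 1, 4).data)
        assert np.allclose(p3.data, ad.maxpool2d(t, 13, 1, 6).data)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(600 + seed)
        sppf = blocks.SPPF(4, 6, rng=rng)
        randomize_bn(sppf, rng)
        x = rand_input(rng, 4, 8, 8)
        assert rel_err(sppf(ad.astensor(x)).data,
                       oracles.sppf_naive(sppf, x)) < 1e-5


class TestEfficiency:
    def test_ghost_beats_dense_over_configuration_grid(self):
        for c1 in (8, 16, 32, 64, 128):
            for c2 in (16, 32, 64, 128, 256):
                for r in (2, 4):
                    if c2 % r:
                        continue
                    ghost, dense = blocks.ghost_vs_dense_weight_counts(c1, c2, 3, r)
                    assert ghost < dense

    def test_counts_agree_with_materialised_module(self):
        gm = blocks.GhostModule(32, 64, r=2)
        ghost, _ = blocks.ghost_vs_dense_weight_counts(32, 64, 3, 2)
        assert gm.conv_weight_count() == ghost


def test_blocks_preserve_finiteness(rng):
    x = rand_input(rng, 8) * 50
    for block in (blocks.GhostBottleneck(8, 8, s=1, use_se=True, rng=rng),
                  blocks.GAM(8, rng=rng),
                  blocks.C2f(8, 8, 2, rng=rng),
                  blocks.SPPF(8, 8, rng=rng)):
        out = block(ad.astensor(x), training=False).data
        assert np.isfinite(out).all()


def test_state_dict_round_trip(rng):
    gb = blocks.GhostBottleneck(8, 16, s=2, use_se=True, rng=rng)
    x = rand_input(rng, 8)
    before = gb(ad.astensor(x)).data
    state = {k: v.copy() for k, v in gb.state_dict().items()}
    gb2 = blocks.GhostBottleneck(8, 16, s=2, use_se=True,
                                 rng=np.random.default_rng(999))
    gb2.load_state_dict(state)
    assert np.allclose(gb2(ad.astensor(x)).data, before)
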