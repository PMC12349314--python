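"""Unit and property tests for the detector building blocks."""

import numpy as np
import pytest

from citrusdet.autodiff import Tensor
from citrusdet.nn_blocks import (ConvBNSiLU, GroupNormParams, RGCSPELAN,
                                 RepConv, block_param_count,
                                 default_num_groups, group_normalize,
                                 repconv_forward, repconv_fuse,
                                 rgcspelan_forward, scale_apply)


# ------------------------------------------------------------ group norm
class TestGroupNormalize:
    def test_constant_map_normalizes_to_zero(self):
        x = np.full((1, 4, 3, 3), 5.0)
        p = GroupNormParams(2, np.ones(4), np.zeros(4), eps=1e-5)
        out = group_normalize(x, p)
        assert np.all(np.abs(out) <= np.sqrt(1e-5))

    def test_two_channel_hand_computation(self):
        # one group, values 1 and 3: mu=2, sigma=1 -> [-1, +1]
        x = np.array([1.0, 3.0]).reshape(1, 2, 1, 1)
        p = GroupNormParams(1, np.ones(2), np.zeros(2), eps=0.0)
        np.testing.assert_allclose(group_normalize(x, p).ravel(), [-1, 1],
                                   atol=1e-6)

    def test_affine_transform(self):
        x = np.array([1.0, 3.0]).reshape(1, 2, 1, 1)
        p = GroupNormParams(1, np.full(2, 2.0), np.ones(2), eps=0.0)
        np.testing.assert_allclose(group_normalize(x, p).ravel(), [-1, 3],
                                   atol=1e-6)

    def test_channel_group_mismatch_raises(self):
        x = np.zeros((1, 6, 2, 2))
        with pytest.raises(ValueError, match="divisible"):
            group_normalize(x, GroupNormParams(4, np.ones(6), np.zeros(6)))

    def test_moments_property(self, rng):
        """With gamma=1, beta=0 the per-group output is standardized."""
        for _ in range(20):
            c, g = 8, 4
            x = rng.standard_normal((2, c, 5, 5)) * rng.uniform(0.5, 4) + \
                rng.uniform(-3, 3)
            out = group_normalize(
                x, GroupNormParams(g, np.ones(c), np.zeros(c), eps=1e-5))
            grouped = out.reshape(2, g, c // g, 5, 5)
            m = grouped.mean(axis=(2, 3, 4))
            v = grouped.var(axis=(2, 3, 4))
            assert np.abs(m).max() < 1e-5
            assert np.all(v <= 1.0 + 1e-6) and np.all(v >= 1 - 10 * 1e-5)

    def test_default_group_rule(self):
        assert default_num_groups(64) == 16
        assert default_num_groups(8) == 8
        assert default_num_groups(65) == 13   # largest divisor <= 16


# ---------------------------------------------------------------- repconv
def _randomized_repconv(rng, c1=3, c2=5):
    rep = RepConv(c1, c2, rng=rng)
    for bn in (rep.bn3, rep.bn1):
        bn.gamma.data = rng.uniform(0.5, 1.5, c2).astype(np.float32)
        bn.beta.data = rng.standard_normal(c2).astype(np.float32)
        bn.running_mean[:] = rng.standard_normal(c2) * 0.3
        bn.running_var[:] = rng.uniform(0.5, 2.0, c2)
    return rep.eval()


class TestRepConv:
    def test_zero_pointwise_branch_degenerates_to_3x3(self, rng):
        rep = RepConv(3, 4, rng=rng).eval()
        rep.w1.data[:] = 0.0
        rep.bn3.running_var[:] = 1.0 - 1e-3   # fold to identity at eps
        rep.bn1.running_var[:] = 1.0 - 1e-3
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        got = repconv_forward(x, rep, "train")
        plain = Tensor(x).conv2d(rep.w3, padding=1).silu().numpy()
        np.testing.assert_allclose(got, plain, atol=1e-5)

    def test_fusion_equivalence_on_random_instances(self, rng):
        worst = 0.0
        for _ in range(100):
            rep = _randomized_repconv(rng)
            x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
            train = repconv_forward(x, rep, "train")
            repconv_fuse(rep)
            deploy = repconv_forward(x, rep, "deploy")
            worst = max(worst, float(np.abs(train - deploy).max()))
        assert worst < 1e-4

    def test_single_pixel_center_tap_hand_convolution(self, rng):
        rep = _randomized_repconv(rng, 2, 3)
        x = rng.standard_normal((1, 2, 1, 1)).astype(np.float32)
        got = repconv_forward(x, rep, "train")
        # only the center tap of the padded 3x3 sees the pixel
        w3c = rep.w3.data[:, :, 1, 1]
        y3 = w3c @ x[0, :, 0, 0]
        y3 = rep.bn3.gamma.data * (y3 - rep.bn3.running_mean) / \
            np.sqrt(rep.bn3.running_var + 1e-3) + rep.bn3.beta.data
        y1 = rep.w1.data[:, :, 0, 0] @ x[0, :, 0, 0]
        y1 = rep.bn1.gamma.data * (y1 - rep.bn1.running_mean) / \
            np.sqrt(rep.bn1.running_var + 1e-3) + rep.bn1.beta.data
        s = y3 + y1
        expect = s / (1 + np.exp(-s))
        np.testing.assert_allclose(got.ravel(), expect, rtol=1e-4, atol=1e-5)

    def test_deploy_without_fusion_is_an_error(self, rng):
        rep = RepConv(2, 2, rng=rng).eval()
        with pytest.raises(RuntimeError, match="fusion"):
            repconv_forward(np.zeros((1, 2, 3, 3)), rep, "deploy")

    def test_fusion_requires_eval_mode(self, rng):
        with pytest.raises(RuntimeError, match="evaluation"):
            RepConv(2, 2, rng=rng).fuse()

    def test_fusion_is_idempotent(self, rng):
        rep = _randomized_repconv(rng)
        repconv_fuse(rep)
        w, b = rep.fused_w.copy(), rep.fused_b.copy()
        repconv_fuse(rep)
        np.testing.assert_array_equal(w, rep.fused_w)
        np.testing.assert_array_equal(b, rep.fused_b)


# -------------------------------------------------------------- rgcspelan
class TestRGCSPELAN:
    def test_shape_contract(self, rng):
        blk = RGCSPELAN(64, 64, n=1, m=16, rng=rng).eval()
        x = rng.standard_normal((2, 64, 8, 8)).astype(np.float32)
        out = rgcspelan_forward(x, blk)
        assert out.shape == (2, 64, 8, 8)

    def test_param_total_matches_closed_form(self, rng):
        blk = RGCSPELAN(64, 64, n=1, m=16, rng=rng)
        assert blk.num_params() == block_param_count(
            "rgcspelan", c1=64, c2=64, n=1, m=16)
        blk2 = RGCSPELAN(64, 64, n=2, m=16, rng=rng)
        assert blk2.num_params() == block_param_count(
            "rgcspelan", c1=64, c2=64, n=2, m=16)

    def test_n_controls_repconv_unit_count(self, rng):
        assert len(RGCSPELAN(32, 32, n=2, m=8, rng=rng).reps) == 2
        assert len(RGCSPELAN(32, 32, n=1, m=8, rng=rng).reps) == 1

    def test_invalid_configs_raise(self, rng):
        with pytest.raises(ValueError):
            RGCSPELAN(32, 32, n=0, m=8, rng=rng)
        with pytest.raises(ValueError):
            RGCSPELAN(32, 32, n=1, e=0.01, s=0.01, rng=rng)
        blk = RGCSPELAN(32, 32, n=1, m=8, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            rgcspelan_forward(np.zeros((1, 16, 4, 4), np.float32), blk)

    def test_batch_permutation_equivariance(self, rng):
        blk = RGCSPELAN(16, 16, n=1, m=4, rng=rng).eval()
        x = rng.standard_normal((4, 16, 6, 6)).astype(np.float32)
        out = rgcspelan_forward(x, blk)
        perm = [2, 0, 3, 1]
        out_p = rgcspelan_forward(x[perm], blk)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-6)


# ------------------------------------------------------------- scale/count
def test_scale_apply_is_elementwise():
    x = np.ones((1, 2, 2, 2))
    np.testing.assert_array_equal(scale_apply(x, 1.0), x)
    np.testing.assert_array_equal(scale_apply(x, 0.0), np.zeros_like(x))
    np.testing.assert_array_equal(scale_apply(x, 2.0), 2 * x)


class TestBlockParamCount:
    def test_closed_form_examples(self):
        assert block_param_count("cbs", c1=3, c2=16, k=3) == 464
        assert block_param_count("repconv", c1=8, c2=8) == 672

    def test_matches_instantiated_modules(self, rng):
        conv = ConvBNSiLU(3, 16, 3, rng=rng)
        assert conv.num_params() == 464
        rep = RepConv(8, 8, rng=rng)
        assert rep.num_params() == 672

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            block_param_count("mystery", c1=1, c2=1)

    def test_independent_of_spatial_size(self, rng):
        # parameter arithmetic takes no spatial argument at all; check the
        # instantiated module count is unchanged by the input it processes
        blk = RGCSPELAN(16, 16, n=1, m=4, rng=rng).eval()
        n0 = blk.num_params()
        for hw in (4, 16):
            blk(Tensor(np.zeros((1, 16, hw, hw), np.float32)))
            assert blk.num_params() == n0
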