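"""Deformable pathway: sampling, operator oracle, blocks and pyramid."""

import numpy as np
import pytest

from dentseg.deformable_pathway import (
    AdaptiveStem, BaseBlock, DCNv3, DeformablePathway, SamplingSpec,
    StageConfig, base_grid_offsets, bilinear_sample, dcn_v3,
)
from dentseg.nn import Tensor


def dcn_triple_loop_oracle(feature, projection_weights, spec):
    """Independent per-pixel / per-group / per-point reference."""
    C, H, W = feature.shape
    G, K = spec.groups, spec.points
    Cg = C // G
    m = spec.modulation_weights()
    out = np.zeros_like(feature)
    for r in range(H):
        for c in range(W):
            for g in range(G):
                acc = np.zeros(Cg)
                for k in range(K):
                    pr = r + spec.base_offsets[k, 0] + spec.offset_field[g, k, r, c, 0]
                    pc = c + spec.base_offsets[k, 1] + spec.offset_field[g, k, r, c, 1]
                    acc += m[g, k, r, c] * bilinear_sample(
                        feature[g * Cg:(g + 1) * Cg], (pr, pc))
                out[g * Cg:(g + 1) * Cg, r, c] = projection_weights[g] @ acc
    return out


def random_instance(rng, C=4, H=6, W=6, G=2, K=9, offset_scale=1.0):
    feature = rng.standard_normal((C, H, W))
    spec = SamplingSpec(G, K,
                        rng.uniform(-offset_scale, offset_scale, (G, K, H, W, 2)),
                        rng.standard_normal((G, K, H, W)))
    w = rng.standard_normal((G, C // G, C // G))
    return feature, w, spec


class TestBilinearSample:
    def test_integer_location_exact(self, rng):
        f = rng.standard_normal((3, 5, 6))
        np.testing.assert_allclose(bilinear_sample(f, (2, 3)), f[:, 2, 3])

    def test_midpoint_is_four_neighbour_mean(self, rng):
        f = rng.standard_normal((2, 4, 4))
        expected = f[:, 1:3, 1:3].mean(axis=(1, 2))
        np.testing.assert_allclose(bilinear_sample(f, (1.5, 1.5)), expected)

    def test_outside_grid_is_zero(self, rng):
        f = rng.standard_normal((2, 4, 4))
        np.testing.assert_array_equal(bilinear_sample(f, (-5.0, -5.0)), 0.0)


class TestDCNv3:
    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            feature, w, spec = random_instance(rng)
            got = dcn_v3(feature, w, spec)
            want = dcn_triple_loop_oracle(feature, w, spec)
            assert np.abs(got - want).max() < 1e-5

    def test_constant_field_preserved_in_interior(self, rng):
        # zero offsets + equal logits + identity projections average to 1/K
        C, G, K = 4, 2, 9
        spec = SamplingSpec(G, K, np.zeros((G, K, 5, 7, 2)), np.zeros((G, K, 5, 7)))
        w = np.stack([np.eye(C // G)] * G)
        out = dcn_v3(np.full((C, 5, 7), 3.25), w, spec)
        np.testing.assert_allclose(out[:, 1:-1, 1:-1], 3.25, atol=1e-12)

    def test_modulation_weights_sum_to_one(self, rng):
        _, _, spec = random_instance(rng)
        sums = spec.modulation_weights().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_zero_offset_reduces_to_grouped_average_conv(self, rng):
        # independent reference: grouped 3x3 box filter (1/K weights) then w_g
        C, H, W, G, K = 4, 6, 6, 2, 9
        feature = rng.standard_normal((C, H, W))
        spec = SamplingSpec(G, K, np.zeros((G, K, H, W, 2)), np.zeros((G, K, H, W)))
        w = rng.standard_normal((G, C // G, C // G))
        got = dcn_v3(feature, w, spec)
        padded = np.pad(feature, ((0, 0), (1, 1), (1, 1)))
        box = np.zeros_like(feature)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                box += padded[:, 1 + dr:1 + dr + H, 1 + dc:1 + dc + W] / K
        want = np.concatenate([
            np.einsum("dc,chw->dhw", w[g], box[g * 2:(g + 1) * 2]) for g in range(G)])
        assert np.abs(got - want).max() < 1e-10

    def test_indivisible_groups_rejected(self, rng):
        feature, w, spec = random_instance(rng, C=4, G=2)
        with pytest.raises(ValueError, match="divisible"):
            dcn_v3(rng.standard_normal((5, 6, 6)), w, spec)
        with pytest.raises(ValueError, match="divisible"):
            DCNv3(channels=5, groups=2)

    def test_module_matches_functional(self, rng):
        mod = DCNv3(4, groups=2, points=9, rng=np.random.default_rng(1))
        mod.offset_conv.weight.data = rng.standard_normal(
            mod.offset_conv.weight.shape) * 0.2
        mod.modulation_conv.weight.data = rng.standard_normal(
            mod.modulation_conv.weight.shape) * 0.2
        x = rng.standard_normal((1, 4, 6, 6))
        got = mod(Tensor(x)).data[0]
        off = mod.offset_conv(Tensor(x)).data[0].reshape(2, 9, 2, 6, 6)
        off = off.transpose(0, 1, 3, 4, 2)
        logits = mod.modulation_conv(Tensor(x)).data[0].reshape(2, 9, 6, 6)
        want = dcn_v3(x[0], mod.projection.data, SamplingSpec(2, 9, off, logits))
        assert np.abs(got - want).max() < 1e-10

    def test_base_grid_is_3x3_for_k9(self):
        grid = base_grid_offsets(9)
        assert sorted(map(tuple, grid)) == [(r, c) for r in (-1, 0, 1)
                                            for c in (-1, 0, 1)]


class TestBaseBlock:
    def test_shape_preserved(self, rng):
        block = BaseBlock(8, groups=2, rng=rng)
        x = Tensor(rng.standard_normal((2, 8, 6, 6)))
        assert block(x).shape == (2, 8, 6, 6)

    def test_eval_mode_deterministic_despite_droppath(self, rng):
        block = BaseBlock(4, groups=2, droppath_rate=0.5, rng=rng)
        block.eval()
        x = Tensor(rng.standard_normal((1, 4, 5, 5)))
        np.testing.assert_array_equal(block(x).data, block(x).data)

    def test_matches_manual_composition(self, rng):
        # oracle: compose the stated sub-operations step by step
        block = BaseBlock(4, groups=2, droppath_rate=0.0, rng=rng)
        x = Tensor(rng.standard_normal((1, 4, 5, 5)))
        d = block.norm_dcn(block.dcn(x))
        branch = block.mlp(d + x) * block.scale.reshape(1, -1, 1, 1)
        want = block.norm_out(branch + d)
        np.testing.assert_allclose(block(x).data, want.data, atol=1e-12)

    def test_gradients_reach_all_parameters(self, rng):
        block = BaseBlock(4, groups=2, droppath_rate=0.0, rng=rng)
        out = block(Tensor(rng.standard_normal((1, 4, 5, 5))))
        (out * out).sum().backward()
        assert all(p.grad is not None for p in block.parameters())


class TestAdaptiveStem:
    def test_output_stride_4(self, rng):
        stem = AdaptiveStem(8, rng=rng)
        out = stem(Tensor(rng.standard_normal((1, 3, 64, 128))))
        assert out.shape[2:] == (16, 32)

    def test_native_resolution_320x640(self, rng):
        stem = AdaptiveStem(8, rng=rng)
        out = stem(Tensor(rng.standard_normal((1, 3, 320, 640))))
        assert out.shape[2:] == (80, 160)

    def test_finite_output(self, rng):
        stem = AdaptiveStem(8, rng=rng)
        out = stem(Tensor(rng.standard_normal((1, 3, 32, 32))))
        assert np.all(np.isfinite(out.data))


class TestDeformablePathway:
    @pytest.fixture
    def pathway(self):
        cfg = StageConfig(depths=(2, 2, 2, 2), channels=(4, 8, 8, 8),
                          groups=2, droppath_rate=0.0, mlp_ratio=1.0)
        return DeformablePathway(cfg, rng=np.random.default_rng(0))

    def test_pyramid_strides(self, pathway, rng):
        pyramid = pathway(Tensor(rng.standard_normal((1, 3, 64, 128))))
        assert len(pyramid) == 4
        assert [p.shape[2:] for p in pyramid] == [(16, 32), (8, 16), (4, 8), (2, 4)]

    def test_block_invocation_count(self, pathway, rng):
        calls = []
        for block in pathway.blocks:
            orig = block.forward
            block.forward = (lambda f, o=orig: (calls.append(1), o(f))[1])
        pathway(Tensor(rng.standard_normal((1, 3, 32, 32))))
        assert len(calls) == 8  # depths (2,2,2,2)

    def test_invalid_stage_configs(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            StageConfig(channels=(64, 32, 128, 256))
        with pytest.raises(ValueError, match="four"):
            StageConfig(depths=(1, 1, 1))

    def test_all_parameters_get_gradients(self, pathway, rng):
        pyramid = pathway(Tensor(rng.standard_normal((1, 3, 32, 32))))
        sum((p * p).sum() for p in pyramid).backward()
        missing = [n for n, p in pathway.named_parameters() if p.grad is None]
        assert not missing
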