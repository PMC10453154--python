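import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdfuse.gd_core import (
    GDConfig,
    PRESETS,
    DifferenceMap,
    DifferencePair,
    SmoothedDifferenceMap,
    directional_differences,
    edge_magnitude,
    fuse,
    gaussian_kernel,
    gd_fuse,
    compute_weights,
    normalize_weights,
    smooth_differences,
)
from gdfuse.image_io import ImageRaster, ImageStack
from gdfuse.synthetic import FixtureSpec, make_stack

from oracles import naive_gd_fuse


def _stack_from(rng, K, h=8, w=8):
    return ImageStack(tuple(ImageRaster(rng.random((h, w))) for _ in range(K)))


class TestDirectionalDifferences:
    def test_constant_plane_has_zero_differences(self):
        pair = directional_differences(np.full((5, 5), 0.3))
        assert (pair.cd == 0).all() and (pair.rd == 0).all()

    def test_hand_evaluated_2x2_example(self):
        plane = np.array([[0.0, 1.0], [2.0, 3.0]]) / 3.0
        pair = directional_differences(plane)
        np.testing.assert_allclose(pair.cd * 3, [[-1, 0], [-1, 0]], atol=1e-12)
        np.testing.assert_allclose(pair.rd * 3, [[-2, -2], [0, 0]], atol=1e-12)

    def test_horizontal_ramp_closed_form(self):
        w = 9
        plane = np.tile(np.linspace(0, 1, w), (4, 1))
        pair = directional_differences(plane)
        np.testing.assert_allclose(pair.cd[:, :-1], -1.0 / (w - 1), atol=1e-12)
        np.testing.assert_allclose(pair.cd[:, -1], 0.0)
        np.testing.assert_allclose(pair.rd, 0.0, atol=1e-12)

    def test_zero_boundary_keeps_edge_intensity(self):
        plane = np.full((3, 3), 0.5)
        pair = directional_differences(plane, boundary="zero")
        np.testing.assert_allclose(pair.cd[:, -1], 0.5)
        np.testing.assert_allclose(pair.rd[-1, :], 0.5)

    def test_multichannel_input_rejected(self, rng):
        with pytest.raises(ValueError, match="single channel"):
            directional_differences(ImageRaster(rng.random((4, 4, 3))))


class TestEdgeMagnitude:
    @pytest.mark.parametrize(
        "rule,expected", [("euclidean", 5.0), ("sum_abs", 7.0), ("sum_sq", 25.0)]
    )
    def test_rules_on_3_4_pair(self, rule, expected):
        pair = DifferencePair(cd=np.full((2, 2), 3.0), rd=np.full((2, 2), 4.0))
        np.testing.assert_allclose(edge_magnitude(pair, rule).d, expected)

    def test_euclidean_of_minus1_minus2(self):
        pair = DifferencePair(cd=np.full((2, 2), -1.0), rd=np.full((2, 2), -2.0))
        np.testing.assert_allclose(
            edge_magnitude(pair).d, np.sqrt(5), atol=1e-12
        )

    def test_zero_differences_give_zero_magnitude(self):
        pair = DifferencePair(cd=np.zeros((3, 3)), rd=np.zeros((3, 3)))
        assert (edge_magnitude(pair).d == 0).all()

    def test_unknown_rule_rejected(self):
        pair = DifferencePair(cd=np.zeros((2, 2)), rd=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="unknown"):
            edge_magnitude(pair, "manhattan")


class TestGaussianKernel:
    def test_s3_window_is_7x7(self):
        assert gaussian_kernel(3, 1.0).coefficients.shape == (7, 7)

    def test_singleton_kernel_is_one(self):
        np.testing.assert_allclose(gaussian_kernel(0, 2.0).coefficients, [[1.0]])

    def test_center_corner_ratio_is_e_for_unit_sigma(self):
        k = gaussian_kernel(1, 1.0).coefficients
        assert k[1, 1] / k[0, 0] == pytest.approx(np.e, rel=1e-12)

    def test_symmetric_normalized_and_centrally_peaked(self):
        k = gaussian_kernel(4, 1.7).coefficients
        np.testing.assert_allclose(k, k[::-1, ::-1], atol=1e-15)
        np.testing.assert_allclose(k, k.T, atol=1e-15)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert k[4, 4] == k.max()

    @pytest.mark.parametrize("s,sigma", [(-1, 1.0), (2, 0.0), (2, -1.0)])
    def test_invalid_parameters_rejected(self, s, sigma):
        with pytest.raises(ValueError):
            gaussian_kernel(s, sigma)


class TestSmoothing:
    def test_constant_map_is_fixed_point(self):
        sm = smooth_differences(
            DifferenceMap(np.full((10, 10), 0.7)), gaussian_kernel(2, 1.0)
        )
        np.testing.assert_allclose(sm.gd, 0.7, atol=1e-12)

    def test_interior_impulse_reproduces_kernel(self):
        d = np.zeros((11, 11))
        d[5, 5] = 1.0
        kernel = gaussian_kernel(2, 1.0)
        sm = smooth_differences(DifferenceMap(d), kernel)
        np.testing.assert_allclose(
            sm.gd[3:8, 3:8], kernel.coefficients, atol=1e-14
        )

    def test_matches_double_loop_convolution(self, rng):
        d = rng.random((8, 8))
        kernel = gaussian_kernel(2, 1.0)
        sm = smooth_differences(DifferenceMap(d), kernel)
        s = kernel.s
        expected = np.zeros_like(d)
        for i in range(8):
            for j in range(8):
                for p in range(-s, s + 1):
                    for r in range(-s, s + 1):
                        expected[i, j] += kernel.coefficients[p + s, r + s] * d[
                            min(max(i + p, 0), 7), min(max(j + r, 0), 7)
                        ]
        np.testing.assert_allclose(sm.gd, expected, atol=1e-12)

    def test_oversized_kernel_warns_but_computes(self):
        with pytest.warns(UserWarning, match="kernel side"):
            sm = smooth_differences(
                DifferenceMap(np.ones((4, 4))), gaussian_kernel(8, 3.0)
            )
        np.testing.assert_allclose(sm.gd, 1.0, atol=1e-12)


class TestWeightNormalization:
    def test_worked_example_2_3_gives_04_06(self):
        gds = [
            SmoothedDifferenceMap(np.full((3, 3), 2.0)),
            SmoothedDifferenceMap(np.full((3, 3), 3.0)),
        ]
        w = normalize_weights(gds)
        np.testing.assert_allclose(w.fw[0], 0.4, atol=1e-12)
        np.testing.assert_allclose(w.fw[1], 0.6, atol=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 5])
    def test_identical_maps_give_uniform_weights(self, rng, K):
        gd = rng.random((6, 6))
        w = normalize_weights([SmoothedDifferenceMap(gd)] * K)
        np.testing.assert_allclose(w.fw, 1.0 / K, atol=1e-12)

    def test_zero_activity_falls_back_to_uniform(self):
        gds = [SmoothedDifferenceMap(np.zeros((4, 4)))] * 3
        np.testing.assert_allclose(normalize_weights(gds).fw, 1.0 / 3)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            normalize_weights(
                [SmoothedDifferenceMap(np.ones((3, 3))),
                 SmoothedDifferenceMap(np.ones((4, 4)))]
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), K=st.integers(2, 6))
    def test_weight_conservation_property(self, seed, K):
        """Per-pixel weights sum to one for any K and any activity maps."""
        r = np.random.default_rng(seed)
        gds = [SmoothedDifferenceMap(r.random((7, 5)) * 10) for _ in range(K)]
        sums = normalize_weights(gds).fw.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestFusion:
    def test_worked_example_04_06_blend(self):
        stack = ImageStack(
            (ImageRaster(np.full((3, 3), 0.2)), ImageRaster(np.full((3, 3), 0.7)))
        )
        weights = normalize_weights(
            [SmoothedDifferenceMap(np.full((3, 3), 2.0)),
             SmoothedDifferenceMap(np.full((3, 3), 3.0))]
        )
        fused = fuse(stack, weights)
        np.testing.assert_allclose(fused.pixels.pixels, 0.5, atol=1e-12)

    def test_identical_inputs_reproduced_exactly(self, rng):
        img = ImageRaster(rng.random((16, 16)))
        stack = ImageStack((img, img))
        fused = gd_fuse(stack, GDConfig(s=3, sigma=1.0))
        np.testing.assert_allclose(fused.pixels.pixels, img.pixels, atol=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_fused_within_per_pixel_envelope(self, rng, K):
        stack = _stack_from(rng, K, 16, 16)
        fused = gd_fuse(stack, GDConfig(s=2, sigma=1.0)).pixels.pixels
        lo = np.min([im.pixels for im in stack], axis=0)
        hi = np.max([im.pixels for im in stack], axis=0)
        assert (fused >= lo - 1e-12).all() and (fused <= hi + 1e-12).all()

    def test_permutation_equivariance(self, rng):
        stack = _stack_from(rng, 3)
        config = GDConfig(s=2, sigma=1.0)
        w = compute_weights(stack, config)
        permuted = ImageStack((stack[2], stack[0], stack[1]))
        wp = compute_weights(permuted, config)
        np.testing.assert_allclose(wp.fw, w.fw[[2, 0, 1]], atol=1e-12)
        np.testing.assert_allclose(
            gd_fuse(permuted, config).pixels.pixels,
            gd_fuse(stack, config).pixels.pixels,
            atol=1e-12,
        )

    def test_kernel_scale_invariance(self, rng):
        """Scaling all kernel coefficients cancels in the weight ratio."""
        from gdfuse.gd_core import GaussianKernel, smooth_differences

        stack = _stack_from(rng, 2)
        kernel = gaussian_kernel(2, 1.0)
        scaled = GaussianKernel(
            s=kernel.s, sigma=kernel.sigma, coefficients=kernel.coefficients * 7.3
        )
        gds, gds_scaled = [], []
        for im in stack:
            d = edge_magnitude(directional_differences(im.pixels))
            gds.append(smooth_differences(d, kernel))
            gds_scaled.append(smooth_differences(d, scaled))
        np.testing.assert_allclose(
            normalize_weights(gds).fw, normalize_weights(gds_scaled).fw, atol=1e-12
        )

    def test_k_mismatch_rejected(self, rng):
        stack = _stack_from(rng, 2)
        w3 = compute_weights(_stack_from(rng, 3), GDConfig(s=1, sigma=0.5))
        with pytest.raises(ValueError, match="weight maps"):
            fuse(stack, w3)


class TestPipelineOracle:
    @pytest.mark.parametrize("K,s,rule", [
        (2, 1, "euclidean"),
        (2, 2, "sum_abs"),
        (3, 3, "sum_sq"),
        (2, 3, "euclidean"),
    ])
    def test_matches_nested_loop_reference(self, rng, K, s, rule):
        stack = _stack_from(rng, K, 16, 16)
        sigma = s / 3.0
        fused = gd_fuse(
            stack, GDConfig(s=s, sigma=sigma, magnitude_rule=rule)
        ).pixels.pixels
        expected = naive_gd_fuse([im.pixels for im in stack], s, sigma, rule)
        np.testing.assert_allclose(fused, expected, atol=1e-12)

    def test_8x8_random_pair_s2(self, rng):
        stack = _stack_from(rng, 2, 8, 8)
        fused = gd_fuse(stack, GDConfig(s=2, sigma=2 / 3)).pixels.pixels
        expected = naive_gd_fuse([im.pixels for im in stack], 2, 2 / 3)
        np.testing.assert_allclose(fused, expected, atol=1e-12)


class TestConfig:
    def test_auto_sigma_is_s_over_3(self):
        assert GDConfig(s=9).effective_sigma == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "name,s,sigma", [("gd5", 5, 1.6), ("gd10", 10, 3.3), ("gd15", 15, 5.0)]
    )
    def test_presets_resolve_to_published_values(self, name, s, sigma):
        assert PRESETS[name].s == s
        assert PRESETS[name].effective_sigma == pytest.approx(sigma)

    @pytest.mark.parametrize("kwargs", [
        dict(s=0), dict(s=2, sigma=-1.0), dict(s=2, magnitude_rule="bogus"),
        dict(s=2, boundary="wrap"),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GDConfig(**kwargs)


class TestActivityMeasure:
    def test_sharp_source_dominates_weights_on_its_sharp_half(self):
        stack, truth, masks = make_stack(FixtureSpec(scenario="multifocus", seed=3))
        weights = compute_weights(stack, GDConfig(s=10))
        # image 1 is sharp where masks say so; its mean weight there > 0.5
        assert weights.fw[0][masks["sharp_1"]].mean() > 0.5
        assert weights.fw[1][masks["sharp_2"]].mean() > 0.5
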