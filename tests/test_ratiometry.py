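"""Masking, ratio maps, sample means, pseudocolor rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from matplotlib import colormaps

from tpmratio import (
    IMAGING_CALIBRATIONS,
    build_phantom,
    foreground_mask,
    pseudocolor,
    ratio_map,
    render_stack,
    sample_mean_ratio,
    simulate_sample,
)
from tpmratio.errors import AnalysisError, ValidationError
from tpmratio.ratiometry import default_display_range

from conftest import make_stack
from oracles import brute_ratio_map, brute_sample_mean


class TestForegroundMask:
    def test_all_zero_ch1_is_analysis_error(self):
        stack = make_stack(np.zeros((2, 4, 4)), np.ones((2, 4, 4)))
        with pytest.raises(AnalysisError):
            foreground_mask(stack)

    def test_otsu_recovers_gland_voxels(self, small_acquisition):
        """Two-population image (background ~5, glands ~500): >=99% recovery."""
        phantom = build_phantom("normal", IMAGING_CALIBRATIONS["SG1"],
                                acquisition=small_acquisition, seed=11)
        stack = render_stack(phantom, small_acquisition, seed=11)
        mask = foreground_mask(stack)
        recovered = (mask & phantom.gland_mask).sum() / phantom.gland_mask.sum()
        assert recovered >= 0.99
        # and few background voxels leak in
        fp = (mask & ~phantom.gland_mask).sum() / mask.sum()
        assert fp < 0.05

    def test_percentile_zero_keeps_all_positive_voxels(self):
        ch1 = np.arange(1.0, 17.0).reshape(1, 4, 4)
        ch2 = np.full((1, 4, 4), 5.0)
        stack = make_stack(ch1, ch2)
        mask = foreground_mask(stack, method="percentile", percentile=0.0)
        assert mask.all()

    def test_saturated_voxels_excluded(self):
        ch1 = np.full((1, 2, 2), 100.0)
        ch2 = np.full((1, 2, 2), 100.0)
        ch2[0, 0, 0] = 65535.0
        stack = make_stack(ch1, ch2)
        mask = foreground_mask(stack, method="percentile", percentile=0.0)
        assert not mask[0, 0, 0]
        assert mask.sum() == 3


class TestRatioMap:
    def test_identity_when_channels_equal(self):
        stack = make_stack(np.full((2, 3, 3), 50.0), np.full((2, 3, 3), 50.0))
        rv = ratio_map(stack, np.ones((2, 3, 3), dtype=bool))
        np.testing.assert_allclose(rv.ratios, 1.0)

    def test_hand_computed_2x2(self):
        ch1 = [[100.0, 200.0], [400.0, 500.0]]
        ch2 = [[50.0, 300.0], [200.0, 1000.0]]
        stack = make_stack(ch1, ch2)
        rv = ratio_map(stack, np.ones((1, 2, 2), dtype=bool))
        np.testing.assert_allclose(rv.ratios[0], [[0.5, 1.5], [0.5, 2.0]])

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        """ratio_map(c*stack) == ratio_map(stack) for any c > 0."""
        rng = np.random.default_rng(5)
        ch1 = rng.uniform(10, 100, (2, 4, 4))
        ch2 = rng.uniform(10, 100, (2, 4, 4))
        mask = np.ones((2, 4, 4), dtype=bool)
        base = ratio_map(make_stack(ch1, ch2), mask)
        scaled = ratio_map(make_stack(c * ch1, c * ch2), mask)
        np.testing.assert_allclose(scaled.ratios, base.ratios, rtol=1e-9)

    def test_matches_brute_force_oracle(self, small_acquisition):
        stack, _ = simulate_sample("SE1", "cancer", seed=2,
                                   acquisition=small_acquisition)
        sub = make_stack(stack.ch1[:3, :4, :4], stack.ch2[:3, :4, :4],
                         z=stack.z_positions_um[:3])
        mask = foreground_mask(sub, method="percentile", percentile=0.0)
        rv = ratio_map(sub, mask)
        expected = brute_ratio_map(sub.ch1, sub.ch2, mask)
        np.testing.assert_array_equal(np.isnan(rv.ratios), np.isnan(expected))
        np.testing.assert_allclose(rv.ratios[mask], expected[mask])


class TestSampleMean:
    def test_uniform_ratio_exact(self, uniform_stack):
        rv = ratio_map(uniform_stack, np.ones_like(uniform_stack.ch1, dtype=bool))
        assert sample_mean_ratio(rv).mean_ratio == 2.0

    def test_hand_computed_two_sections(self):
        ch1 = np.full((2, 2, 2), 1.0)
        ch2 = np.zeros((2, 2, 2))
        mask = np.zeros((2, 2, 2), dtype=bool)
        ch2[0, 0, 0], ch2[0, 0, 1], ch2[1, 0, 0] = 1.0, 2.0, 3.0
        mask[0, 0, 0] = mask[0, 0, 1] = mask[1, 0, 0] = True
        rv = ratio_map(make_stack(ch1, ch2), mask)
        assert sample_mean_ratio(rv).mean_ratio == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, small_acquisition):
        stack, _ = simulate_sample("SG1", "normal", seed=4,
                                   acquisition=small_acquisition)
        sub = make_stack(stack.ch1[:3, :4, :4], stack.ch2[:3, :4, :4],
                         z=stack.z_positions_um[:3])
        mask = foreground_mask(sub, method="percentile", percentile=0.0)
        rv = ratio_map(sub, mask)
        assert sample_mean_ratio(rv).mean_ratio == pytest.approx(
            brute_sample_mean(rv.ratios, mask), rel=1e-12)

    def test_monotone_in_true_ratio(self, small_acquisition):
        """Raising every true ratio strictly raises the noise-free sample mean."""
        phantom = build_phantom("normal", IMAGING_CALIBRATIONS["SG1"],
                                acquisition=small_acquisition, seed=6)
        lo = render_stack(phantom, small_acquisition, noise=False)
        phantom.true_ratio_field = phantom.true_ratio_field * 1.3
        hi = render_stack(phantom, small_acquisition, noise=False)
        mask = foreground_mask(lo)
        mean_lo = sample_mean_ratio(ratio_map(lo, mask)).mean_ratio
        mean_hi = sample_mean_ratio(ratio_map(hi, mask)).mean_ratio
        assert mean_hi > mean_lo

    def test_empty_window_is_analysis_error(self, uniform_stack):
        rv = ratio_map(uniform_stack, np.ones_like(uniform_stack.ch1, dtype=bool))
        with pytest.raises(AnalysisError):
            sample_mean_ratio(rv, depth_window=(300.0, 400.0))


class TestPseudocolor:
    def _rv(self, ratios, lo=0.0, hi=2.0):
        ratios = np.asarray(ratios, dtype=float)
        mask = np.isfinite(ratios) & (ratios > 0)
        from tpmratio.ratiometry import RatioVolume
        return RatioVolume(ratios=ratios, mask=mask,
                           z_positions_um=np.arange(ratios.shape[0]) * 10.0 + 80,
                           display_range=(lo, hi))

    def test_midpoint_ratio_maps_to_midpoint_color(self):
        rv = self._rv(np.full((1, 2, 2), 1.0), lo=0.0, hi=2.0)
        rgb = pseudocolor(rv, modulate_brightness=False)
        expected = np.array(colormaps["turbo"](0.5)[:3])
        np.testing.assert_allclose(rgb[0, 0, 0], expected, atol=1e-12)

    def test_hue_is_scale_invariant(self, small_acquisition):
        """x10 global intensity change leaves hues identical."""
        stack, _ = simulate_sample("SG1", "cancer", seed=8,
                                   acquisition=small_acquisition)
        mask = foreground_mask(stack)
        rv = ratio_map(stack, mask)
        scaled = make_stack(10 * stack.ch1, 10 * stack.ch2, z=stack.z_positions_um)
        rv10 = ratio_map(scaled, mask)
        a = pseudocolor(rv, display_range=(0.5, 1.7), modulate_brightness=False)
        b = pseudocolor(rv10, display_range=(0.5, 1.7), modulate_brightness=False)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_background_is_black_and_brightness_modulates(self):
        ratios = np.full((1, 2, 2), 1.0)
        ratios[0, 1, 1] = np.nan
        rv = self._rv(ratios)
        intensity = np.array([[[100.0, 50.0], [25.0, 0.0]]])
        rgb = pseudocolor(rv, intensity_volume=intensity)
        np.testing.assert_allclose(rgb[0, 1, 1], 0.0)       # background black
        assert rgb[0, 0, 1].max() < rgb[0, 0, 0].max()      # dimmer voxel dimmer

    def test_cancer_render_shifted_toward_high_ratio_end(self, small_acquisition):
        """SG1 normal vs cancer renders: modal colormap position is higher in cancer."""
        cmap_lut = colormaps["turbo"](np.linspace(0, 1, 256))[:, :3]

        def modal_position(probe_cls_seed):
            probe, cls, seed = probe_cls_seed
            stack, _ = simulate_sample(probe, cls, seed=seed,
                                       acquisition=small_acquisition)
            mask = foreground_mask(stack)
            rv = ratio_map(stack, mask)
            rgb = pseudocolor(rv, display_range=default_display_range("SG1"),
                              modulate_brightness=False)
            fg = rgb[mask]
            dists = np.linalg.norm(fg[:, None, :] - cmap_lut[None, :, :], axis=2)
            return np.median(np.argmin(dists, axis=1))

        pos_normal = modal_position(("SG1", "normal", 1))
        pos_cancer = modal_position(("SG1", "cancer", 1))
        assert pos_cancer > pos_normal

    def test_invalid_display_range_rejected(self):
        rv = self._rv(np.full((1, 2, 2), 1.0))
        with pytest.raises(ValidationError):
            pseudocolor(rv, display_range=(2.0, 1.0))

    def test_default_display_range_ordered_for_all_probes(self):
        for probe in IMAGING_CALIBRATIONS:
            lo, hi = default_display_range(probe)
            assert lo < hi
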