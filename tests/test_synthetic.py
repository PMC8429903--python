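"""Phantom construction, the forward imaging model, cohorts, lysate series."""

import numpy as np
import pytest

from tpmratio import (
    AcquisitionParams,
    CohortDesign,
    GlandGeometry,
    IMAGING_CALIBRATIONS,
    LysateAssayParams,
    build_phantom,
    first_order_ratio,
    render_stack,
    simulate_cohort,
    simulate_lysate_series,
    simulate_sample,
)
from tpmratio.errors import ConfigurationError, ValidationError
from tpmratio.synthetic import draw_sample_mean, expected_channels


class TestSampleMeanDraws:
    def test_zero_sd_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert draw_sample_mean(1.127, 0.0, rng) == 1.127

    def test_monte_carlo_mean_matches_calibration(self):
        """10,000 draws for SG1 normal land within 3 SE of 0.656."""
        rng = np.random.default_rng(0)
        draws = np.array([draw_sample_mean(0.656, 0.142, rng) for _ in range(10_000)])
        se = 0.142 / np.sqrt(10_000)
        assert abs(draws.mean() - 0.656) < 3 * se
        assert np.all(draws > 0)

    def test_cancer_draw_is_from_calibrated_distribution(self):
        cal = IMAGING_CALIBRATIONS["SG1"]
        phantom = build_phantom("cancer", cal, seed=1)
        # a draw from N(1.127, 0.109): within 5 sigma of the mean
        assert abs(phantom.sample_ratio_mean - 1.127) < 5 * 0.109


class TestPhantom:
    def test_ratio_field_positive_and_mean_centred(self, small_acquisition):
        cal = IMAGING_CALIBRATIONS["SG1"]
        phantom = build_phantom("normal", cal, acquisition=small_acquisition, seed=3)
        assert np.all(phantom.true_ratio_field > 0)
        gland_mean = phantom.true_ratio_field[phantom.gland_mask].mean()
        assert gland_mean == pytest.approx(phantom.sample_ratio_mean, rel=1e-12)

    def test_zero_disorder_gives_periodic_lattice(self, small_acquisition):
        """disorder=0 phantoms have identical gland sections (up to wobble-free build)."""
        geom = GlandGeometry(disorder_fraction=0.0)
        cal = IMAGING_CALIBRATIONS["SG1"]
        p = build_phantom("normal", cal, gland_geometry=geom,
                          acquisition=small_acquisition, seed=0)
        # the lattice is periodic: shifting by one spacing (10 px at 4 um/px)
        sec = p.gland_mask.any(axis=0)
        spacing_px = int(geom.spacing_um / small_acquisition.pixel_size_um)
        if spacing_px < sec.shape[0]:
            inner = sec[:-spacing_px, :]
            shifted = sec[spacing_px:, :]
            assert (inner == shifted).mean() > 0.9

    def test_unknown_class_and_probe_rejected(self):
        cal = IMAGING_CALIBRATIONS["SG1"]
        with pytest.raises(ConfigurationError):
            build_phantom("polyp", cal)

    def test_cancer_geometry_is_disordered(self):
        from tpmratio.synthetic import default_geometry
        assert default_geometry("cancer").disorder_fraction >= 0.5
        assert default_geometry("normal").disorder_fraction < 0.2


class TestForwardModel:
    def test_single_voxel_channel_split(self):
        """B=1000, r=2 -> E[Ch2]=666.67, E[Ch1]=333.33."""
        acq = AcquisitionParams(image_size=1, z_positions_um=(0.0,),
                                attenuation_length_um=100.0, photon_budget=1000.0)
        cal = IMAGING_CALIBRATIONS["SG1"]
        phantom = build_phantom("normal", cal, acquisition=acq, seed=0, texture_sd=0.0)
        phantom.true_ratio_field[:] = 2.0
        phantom.brightness_field[:] = 1.0
        ch1, ch2 = expected_channels(phantom, acq)
        assert ch2.ravel()[0] == pytest.approx(666.6667, abs=1e-3)
        assert ch1.ravel()[0] == pytest.approx(333.3333, abs=1e-3)

    def test_equal_channels_when_ratio_is_one(self, small_acquisition):
        cal = IMAGING_CALIBRATIONS["SG1"]
        phantom = build_phantom("normal", cal, acquisition=small_acquisition,
                                seed=0, texture_sd=0.0)
        phantom.true_ratio_field[:] = 1.0
        ch1, ch2 = expected_channels(phantom, small_acquisition)
        np.testing.assert_allclose(ch1, ch2)

    def test_depth_attenuation_is_exponential(self):
        """Same section content at z=100 vs z=200 um differs by exp(-1) at L=100."""
        acq = AcquisitionParams(image_size=8, z_positions_um=(100.0, 200.0),
                                attenuation_length_um=100.0)
        cal = IMAGING_CALIBRATIONS["SG1"]
        phantom = build_phantom("normal", cal, acquisition=acq, seed=0, texture_sd=0.0)
        phantom.brightness_field[1] = phantom.brightness_field[0]
        phantom.true_ratio_field[1] = phantom.true_ratio_field[0]
        ch1, ch2 = expected_channels(phantom, acq)
        total = ch1 + ch2
        assert total[1].sum() == pytest.approx(np.exp(-1.0) * total[0].sum(), rel=1e-12)

    def test_channel_conservation(self, small_acquisition):
        """Noise-free Ch1 + Ch2 equals B at every voxel."""
        cal = IMAGING_CALIBRATIONS["SE1"]
        phantom = build_phantom("cancer", cal, acquisition=small_acquisition, seed=5)
        ch1, ch2 = expected_channels(phantom, small_acquisition)
        atten = np.exp(-small_acquisition.z_array / small_acquisition.attenuation_length_um)
        b = phantom.brightness_field * small_acquisition.photon_budget * atten[:, None, None]
        np.testing.assert_allclose(ch1 + ch2, b, rtol=1e-12)

    def test_noise_free_ratio_roundtrip(self, small_acquisition):
        """Rendered noise-free Ch2/Ch1 equals the true ratio field to <=1e-9."""
        cal = IMAGING_CALIBRATIONS["SG1"]
        phantom = build_phantom("cancer", cal, acquisition=small_acquisition, seed=7)
        stack = render_stack(phantom, small_acquisition, noise=False)
        ratio = stack.ch2 / stack.ch1
        np.testing.assert_allclose(ratio, phantom.true_ratio_field, rtol=1e-9)

    def test_seed_determinism(self, small_acquisition):
        a, _ = simulate_sample("SG1", "cancer", seed=42, acquisition=small_acquisition)
        b, _ = simulate_sample("SG1", "cancer", seed=42, acquisition=small_acquisition)
        np.testing.assert_array_equal(a.ch1, b.ch1)
        np.testing.assert_array_equal(a.ch2, b.ch2)

    def test_invalid_acquisition_rejected(self):
        with pytest.raises(ValidationError):
            AcquisitionParams(photon_budget=-5.0)
        with pytest.raises(ValidationError):
            AcquisitionParams(z_positions_um=(200.0, 100.0))
        with pytest.raises(ValidationError):
            AcquisitionParams(z_positions_um=(100.0, 600.0))


class TestCohort:
    def test_default_design_gives_76_samples_per_probe(self, small_acquisition):
        design = CohortDesign(acquisition=small_acquisition, probes=("SG1",),
                              master_seed=1)
        stacks, manifest = simulate_cohort(design)
        assert len(stacks) == 76
        assert len(manifest) == 76
        assert manifest["tissue_class"].value_counts().to_dict() == {
            "normal": 21, "ulcer": 18, "adenoma": 17, "cancer": 20}

    def test_manifest_labels_match_stacks(self, small_acquisition):
        design = CohortDesign(counts={"normal": 1, "cancer": 1},
                              acquisition=small_acquisition, probes=("SE1",),
                              master_seed=3)
        stacks, manifest = simulate_cohort(design)
        for stack, (_, row) in zip(stacks, manifest.iterrows()):
            assert stack.tissue_class == row["tissue_class"]
            assert stack.sample_id == row["sample_id"]
            assert stack.probe_id == "SE1"

    def test_cohort_determinism(self, small_acquisition):
        design = CohortDesign(counts={"normal": 1, "cancer": 1},
                              acquisition=small_acquisition, probes=("SG1",),
                              master_seed=9)
        s1, m1 = simulate_cohort(design)
        s2, m2 = simulate_cohort(design)
        assert m1.equals(m2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.ch1, b.ch1)


class TestLysateSeries:
    def test_zero_rate_is_flat(self):
        params = LysateAssayParams(r0=0.5, r_inf=1.8, k_per_min=0.0, noise_sd=0.0)
        series = simulate_lysate_series(params, seed=0)
        np.testing.assert_allclose(series.ratio, 0.5)

    def test_closed_form_at_120_min(self):
        assert first_order_ratio(120.0, 0.5, 1.8, 0.05) == pytest.approx(1.7968, abs=5e-5)
        params = LysateAssayParams(r0=0.5, r_inf=1.8, k_per_min=0.05, noise_sd=0.0)
        series = simulate_lysate_series(params, seed=0)
        assert series.ratio[-1] == pytest.approx(1.7968, abs=5e-5)

    def test_13_time_points_every_10_min(self):
        series = simulate_lysate_series(LysateAssayParams(), seed=1)
        assert len(series.time_min) == 13
        np.testing.assert_allclose(np.diff(series.time_min), 10.0)
        assert series.time_min[-1] == 120.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            LysateAssayParams(k_per_min=-0.1)
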