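"""Generator: truncated-normal targets, Beer-Lambert spectra, scene cubes."""

import numpy as np
import pytest
from scipy import stats

import spectrareg as sr
from spectrareg.exceptions import GeometryError, ParameterError
from spectrareg.synthetic import SSC_HI, SSC_LO, SSC_MEAN, SSC_SD, default_baseline


class TestGenerateTargets:
    def test_values_respect_truncation_bounds(self):
        y = sr.generate_targets(357, SSC_MEAN, SSC_SD, SSC_LO, SSC_HI, seed=3)
        assert y.shape == (357,)
        assert y.min() >= SSC_LO and y.max() <= SSC_HI

    def test_zero_sd_returns_the_mean_exactly(self):
        y = sr.generate_targets(5, 4.20, 0.0, 3.0, 5.0, seed=0)
        assert np.all(y == 4.20)

    def test_sample_mean_matches_truncated_normal_moment(self):
        # oracle: closed-form truncated-normal mean via scipy
        n = 10000
        y = sr.generate_targets(n, SSC_MEAN, SSC_SD, SSC_LO, SSC_HI, seed=11)
        a, b = (SSC_LO - SSC_MEAN) / SSC_SD, (SSC_HI - SSC_MEAN) / SSC_SD
        dist = stats.truncnorm(a, b, loc=SSC_MEAN, scale=SSC_SD)
        se = dist.std() / np.sqrt(n)
        assert abs(y.mean() - dist.mean()) < 3 * se

    def test_sample_sd_within_5pct_of_truncation_adjusted_sd(self):
        n = 10000
        y = sr.generate_targets(n, SSC_MEAN, SSC_SD, SSC_LO, SSC_HI, seed=11)
        a, b = (SSC_LO - SSC_MEAN) / SSC_SD, (SSC_HI - SSC_MEAN) / SSC_SD
        expected_sd = stats.truncnorm(a, b, loc=SSC_MEAN, scale=SSC_SD).std()
        assert abs(y.std(ddof=1) - expected_sd) / expected_sd < 0.05

    def test_deterministic_for_fixed_seed(self):
        a = sr.generate_targets(50, 6.9, 1.41, 4.2, 10.2, seed=9)
        b = sr.generate_targets(50, 6.9, 1.41, 4.2, 10.2, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("kwargs", [
        {"n": 0, "mean": 5, "sd": 1, "lo": 0, "hi": 10},
        {"n": 5, "mean": 5, "sd": 1, "lo": 10, "hi": 0},
        {"n": 5, "mean": 5, "sd": -1, "lo": 0, "hi": 10},
        {"n": 5, "mean": 20, "sd": 0, "lo": 0, "hi": 10},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            sr.generate_targets(seed=0, **kwargs)


class TestGenerateSpectra:
    def test_null_model_returns_baseline(self):
        cfg = sr.SyntheticConfig(n_samples=4, bands=[], noise_sd=0.0,
                                 scatter_slope_range=(1.0, 1.0),
                                 scatter_offset_range=(0.0, 0.0), seed=1)
        ssc = np.full(4, 6.9)
        ph = np.full(4, 4.2)
        spectra, truth = sr.generate_spectra(ssc, ph, cfg)
        expected = default_baseline(cfg.wavelengths)
        np.testing.assert_allclose(spectra.values, np.tile(expected, (4, 1)), rtol=0, atol=1e-14)

    def test_observed_is_affine_in_clean_when_noiseless(self):
        cfg = sr.SyntheticConfig(n_samples=6, noise_sd=0.0, seed=5)
        ssc = sr.generate_targets(6, 6.9, 1.41, 4.2, 10.2, seed=2)
        ph = sr.generate_targets(6, 4.2, 0.2, 3.77, 4.78, seed=3)
        spectra, truth = sr.generate_spectra(ssc, ph, cfg)
        reconstructed = truth.offset[:, None] + truth.slope[:, None] * truth.clean_spectra
        np.testing.assert_allclose(spectra.values, reconstructed, rtol=0, atol=1e-14)

    def test_absorbance_regression_recovers_band_coefficient(self):
        # oracle: least-squares slope of absorbance at the band centre vs SSC
        band = sr.ComponentBand(1450.0, 40.0, coeff_ssc=0.012)
        cfg = sr.SyntheticConfig(n_samples=30, bands=[band], noise_sd=0.0,
                                 scatter_slope_range=(1.0, 1.0),
                                 scatter_offset_range=(0.0, 0.0), seed=1)
        ssc = np.linspace(4.2, 10.2, 30)
        ph = np.full(30, 4.2)
        spectra, truth = sr.generate_spectra(ssc, ph, cfg)
        j = int(np.argmin(np.abs(cfg.wavelengths - band.center_nm)))
        absorbance = -np.log10(spectra.values[:, j] / cfg.baseline[j])
        center_gain = np.exp(-((cfg.wavelengths[j] - band.center_nm) ** 2)
                             / (2 * band.width_nm ** 2))
        slope = np.polyfit(ssc, absorbance, 1)[0]
        assert abs(slope - band.coeff_ssc * center_gain) < 1e-6

    def test_bit_identical_for_same_config_and_seed(self):
        cfg = sr.SyntheticConfig(n_samples=8, seed=21)
        a, _, _ = sr.generate_dataset(cfg)
        b, _, _ = sr.generate_dataset(sr.SyntheticConfig(n_samples=8, seed=21))
        np.testing.assert_array_equal(a.values, b.values)

    def test_clean_spectra_within_physical_range(self, small_dataset):
        clean = small_dataset["truth"].clean_spectra
        assert clean.min() > 0 and clean.max() < 1.2

    def test_mismatched_target_lengths_rejected(self):
        cfg = sr.SyntheticConfig(n_samples=3)
        with pytest.raises(ParameterError):
            sr.generate_spectra(np.ones(3), np.ones(4), cfg)


class TestSyntheticConfigValidation:
    def test_rejects_decreasing_wavelengths(self):
        with pytest.raises(ParameterError):
            sr.SyntheticConfig(wavelengths=np.array([1700.0, 900.0]))

    def test_rejects_slope_range_containing_zero(self):
        with pytest.raises(ParameterError):
            sr.SyntheticConfig(scatter_slope_range=(-0.5, 0.5))

    def test_rejects_band_outside_grid(self):
        with pytest.raises(ParameterError):
            sr.SyntheticConfig(bands=[sr.ComponentBand(2500.0, 40.0, coeff_ssc=0.01)])


class TestSceneCube:
    def test_scene_has_expected_components_and_background(self):
        cfg = sr.SyntheticConfig(n_samples=15, seed=2)
        spectra, _, _ = sr.generate_dataset(cfg)
        cube, masks = sr.generate_scene_cube(spectra, layout_rows=3, layout_cols=5)
        assert len(masks) == 15
        union = np.zeros(cube.data.shape[:2], dtype=bool)
        for m in masks:
            assert not (union & m).any()  # disks never overlap
            union |= m
        background = cube.data[~union]
        assert np.all(background == 0.05)

    def test_disk_pixel_mean_equals_assigned_spectrum(self):
        # oracle: average over the true mask, no within-disk variation
        cfg = sr.SyntheticConfig(n_samples=6, seed=3)
        spectra, _, _ = sr.generate_dataset(cfg)
        cube, masks = sr.generate_scene_cube(spectra, layout_rows=2, layout_cols=3)
        for k, mask in enumerate(masks):
            np.testing.assert_allclose(cube.data[mask].mean(axis=0), spectra.values[k],
                                       rtol=0, atol=1e-12)

    def test_overlapping_geometry_rejected(self):
        cfg = sr.SyntheticConfig(n_samples=4, seed=1)
        spectra, _, _ = sr.generate_dataset(cfg)
        with pytest.raises(GeometryError):
            sr.generate_scene_cube(spectra, layout_rows=2, layout_cols=2,
                                   disk_radius=10, cell_size=20)

    def test_layout_capacity_enforced(self):
        cfg = sr.SyntheticConfig(n_samples=5, seed=1)
        spectra, _, _ = sr.generate_dataset(cfg)
        with pytest.raises(ParameterError):
            sr.generate_scene_cube(spectra, layout_rows=2, layout_cols=2)
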