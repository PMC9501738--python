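"""Segmentation, ROI extraction, cropping and wavelet smoothing contracts."""

import numpy as np
import pytest

from herbspec import (
    SpectralCube,
    SpectraTable,
    SyntheticConfig,
    calibrate,
    crop_wavelengths,
    extract_pixel_spectra,
    make_class_profiles,
    mean_spectrum,
    select_band,
    simulate_cube,
    threshold_mask,
    wavelet_denoise,
)
from herbspec.extraction import BinaryMask


def cube_of(values, wavelengths):
    return SpectralCube(np.asarray(values, dtype=float), wavelengths,
                        kind="reflectance")


class TestSelectBand:
    @pytest.mark.parametrize("axis,target,expected_idx", [
        ([1000, 1019, 1040], 1019, 1),   # exact hit
        ([1000, 1020], 1009, 0),          # plain nearest
        ([1000, 1020], 1010, 0),          # tie breaks toward lower wavelength
    ])
    def test_nearest_with_lower_tie(self, axis, target, expected_idx):
        bands = len(axis)
        values = np.arange(bands)[None, None, :] * np.ones((2, 2, 1))
        cube = cube_of(values, np.array(axis, dtype=float))
        assert np.all(select_band(cube, target) == expected_idx)

    def test_out_of_range_target(self):
        cube = cube_of(np.zeros((2, 2, 3)), np.array([1000.0, 1100.0, 1200.0]))
        with pytest.raises(ValueError, match="outside"):
            select_band(cube, 900)


class TestThresholdMask:
    def test_bimodal_disc_recovered(self, rng):
        yy, xx = np.mgrid[0:60, 0:60]
        disc = (yy - 30) ** 2 + (xx - 30) ** 2 <= 12**2
        image = rng.normal(0.05, 0.01, (60, 60))
        image[disc] = rng.normal(0.6, 0.01, disc.sum())
        mask = threshold_mask(image)
        assert (mask.values == disc).mean() >= 0.99

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_mask(np.full((10, 10), 0.3))

    def test_two_level_image_is_exact(self):
        image = np.zeros((10, 10))
        image[2:8, 2:8] = 1.0
        mask = threshold_mask(image, min_region_px=1)
        assert np.array_equal(mask.values, image == 1.0)

    def test_speckle_components_removed(self, rng):
        image = np.zeros((40, 40))
        image[5:30, 5:30] = 1.0     # real sample, 625 px
        image[35, 35] = 1.0          # speckle
        mask = threshold_mask(image, min_region_px=20)
        assert mask.values[10, 10] and not mask.values[35, 35]


class TestExtractAndMean:
    def test_single_pixel_mask(self):
        cube = cube_of(np.arange(24).reshape(2, 3, 4), np.linspace(900, 1200, 4))
        mask = np.zeros((2, 3), dtype=bool)
        mask[1, 2] = True
        table = extract_pixel_spectra(cube, BinaryMask(mask))
        assert table.X.shape == (1, 4)
        assert np.array_equal(table.X[0], cube.values[1, 2])
        assert table.provenance == [(1, 2)]

    def test_row_count_matches_bruteforce(self, rng):
        cube = cube_of(rng.random((8, 9, 5)), np.linspace(900, 1300, 5))
        mask = rng.random((8, 9)) > 0.5
        table = extract_pixel_spectra(cube, BinaryMask(mask))
        brute = sum(bool(mask[r, c]) for r in range(8) for c in range(9))
        assert table.n_samples == brute

    def test_zero_noise_rows_identical_to_profile(self):
        cfg = SyntheticConfig(pixel_noise_sd=0.0, edge_noise_sd=0.0, seed=0)
        cube, refs, mask = simulate_cube(cfg, 2)
        refl = calibrate(cube, refs)
        table = extract_pixel_spectra(refl, BinaryMask(mask))
        profile = make_class_profiles(cfg)[2]
        assert np.allclose(table.X, profile, atol=1e-10)

    def test_mean_matches_bruteforce_loop(self, rng):
        X = rng.random((5, 7))
        table = SpectraTable(X, np.linspace(900, 1500, 7))
        brute = np.array([sum(X[i, j] for i in range(5)) / 5 for j in range(7)])
        assert np.allclose(mean_spectrum(table), brute)

    def test_mask_shape_mismatch(self):
        cube = cube_of(np.zeros((2, 2, 3)), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="shape"):
            extract_pixel_spectra(cube, BinaryMask(np.ones((3, 3), dtype=bool)))


class TestCropWavelengths:
    def test_full_span_is_identity(self, default_table):
        out = crop_wavelengths(default_table, 874, 1734)
        assert np.array_equal(out.X, default_table.X)

    def test_closed_interval(self):
        table = SpectraTable(np.zeros((2, 3)), np.array([900.0, 1000.0, 1100.0]))
        out = crop_wavelengths(table, 950, 1050)
        assert list(out.wavelengths) == [1000.0]

    def test_retained_count_matches_bruteforce(self, rng):
        wl = np.sort(rng.uniform(800, 1800, 40))
        table = SpectraTable(rng.random((3, 40)), wl)
        lo, hi = 1000.0, 1500.0
        out = crop_wavelengths(table, lo, hi)
        assert out.n_bands == sum(lo <= w <= hi for w in wl)

    def test_idempotent(self, default_table):
        once = crop_wavelengths(default_table, 875, 1546)
        twice = crop_wavelengths(once, 875, 1546)
        assert np.array_equal(once.X, twice.X)

    def test_empty_window_rejected(self):
        table = SpectraTable(np.zeros((2, 3)), np.array([900.0, 1000.0, 1100.0]))
        with pytest.raises(ValueError, match="retains no bands"):
            crop_wavelengths(table, 1210, 1220)


class TestWaveletDenoise:
    def test_constant_spectrum_unchanged(self):
        out = wavelet_denoise(np.full(200, 0.4))
        assert np.allclose(out, 0.4, atol=1e-10)

    def test_noise_reduction_over_seeds(self, default_config):
        profile = make_class_profiles(default_config)[0][:200]
        improved = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = profile + rng.normal(0, 0.02, 200)
            den = wavelet_denoise(noisy)
            if np.mean((den - profile) ** 2) < np.mean((noisy - profile) ** 2):
                improved += 1
        assert improved == 100

    def test_near_idempotent(self, default_config):
        profile = make_class_profiles(default_config)[0][:200]
        noisy = profile + np.random.default_rng(0).normal(0, 0.02, 200)
        once = wavelet_denoise(noisy)
        twice = wavelet_denoise(once)
        assert np.abs(twice - once).max() < 0.01 * np.ptp(once)

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            wavelet_denoise(np.zeros(8), level=3)

    def test_output_length_preserved(self):
        for n in (181, 200):
            assert len(wavelet_denoise(np.random.default_rng(1).random(n))) == n


class TestEndToEndRecovery:
    def test_pipeline_recovers_profile(self, default_config):
        """simulate -> calibrate -> segment at 1019 nm -> extract -> mean ->
        crop -> denoise correlates > 0.99 with the class profile."""
        wl = default_config.wavelengths
        window = (wl >= 875) & (wl <= 1546)
        profiles = make_class_profiles(default_config)
        for class_id in (0, 5, 11):
            cube, refs, _ = simulate_cube(default_config, class_id)
            refl = calibrate(cube, refs)
            mask = threshold_mask(select_band(refl, 1019))
            table = extract_pixel_spectra(refl, mask)
            spec = mean_spectrum(crop_wavelengths(table, 875, 1546))
            den = wavelet_denoise(spec)
            r = np.corrcoef(den, profiles[class_id][window])[0, 1]
            assert r > 0.99
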