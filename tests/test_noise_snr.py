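"""Magnitude-noise statistics and corrected-SNR estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from f19mri.errors import DomainError, EstimationError
from f19mri.images import MagnitudeImage, RegionMask
from f19mri.noise_snr import (
    CSIGMA_PRINTED,
    NoiseModel,
    background_stats,
    c_sigma_closed_form,
    central_circular_roi,
    correct_snr,
    expected_magnitude_ratio,
    noise_floor_mean_ratio,
    roi_snr,
    snr_map,
)

RICIAN = NoiseModel(channels=1, c_sigma_source="derived_closed_form")
CHI4 = NoiseModel(channels=2, c_sigma_source="derived_closed_form")


class TestNoiseModel:
    def test_printed_constants_are_defaults(self):
        assert NoiseModel(1).c_sigma == 0.655
        assert NoiseModel(2).c_sigma == 0.687

    def test_closed_form_constants(self):
        # Rayleigh: sqrt(2 - pi/2); 4-DOF chi from its first two moments
        assert c_sigma_closed_form(1) == pytest.approx(math.sqrt(2 - math.pi / 2), abs=1e-12)
        assert c_sigma_closed_form(1) == pytest.approx(0.6551, abs=5e-5)
        assert c_sigma_closed_form(2) == pytest.approx(0.6824, abs=5e-5)

    def test_derived_mode_rejects_inconsistent_constant(self):
        with pytest.raises(DomainError):
            NoiseModel(channels=2, c_sigma=0.687, c_sigma_source="derived_closed_form")

    def test_invalid_channels(self):
        with pytest.raises(DomainError):
            NoiseModel(channels=0)


class TestExpectedMagnitudeRatio:
    def test_noise_floor_means(self):
        # Rayleigh mean sqrt(pi/2); 4-DOF chi mean sqrt(2)*Gamma(2.5)/Gamma(2)
        assert expected_magnitude_ratio(0.0, RICIAN) == pytest.approx(1.2533, abs=5e-5)
        assert expected_magnitude_ratio(0.0, CHI4) == pytest.approx(1.8800, abs=5e-5)

    def test_asymptotically_unbiased(self):
        assert expected_magnitude_ratio(1000.0, RICIAN) / 1000.0 == pytest.approx(1.0, abs=1e-4)
        assert expected_magnitude_ratio(1000.0, CHI4) / 1000.0 == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("model", [RICIAN, CHI4], ids=["rician", "chi4"])
    def test_strictly_increasing_on_grid(self, model):
        grid = np.arange(0.0, 50.0 + 1e-9, 0.1)
        vals = expected_magnitude_ratio(grid, model)
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("model", [RICIAN, CHI4], ids=["rician", "chi4"])
    def test_dominates_signal_and_floor(self, model):
        grid = np.linspace(0.0, 30.0, 301)
        vals = expected_magnitude_ratio(grid, model)
        floor = noise_floor_mean_ratio(model.channels)
        assert np.all(vals >= np.maximum(grid, floor) - 1e-12)

    def test_rejects_negative_snr(self):
        with pytest.raises(DomainError):
            expected_magnitude_ratio(-0.1, RICIAN)

    @pytest.mark.parametrize("model", [RICIAN, CHI4], ids=["rician", "chi4"])
    def test_matches_monte_carlo_mean(self, model, rng, sample_magnitude_noise):
        for s in (0.0, 2.0, 7.0):
            mags = sample_magnitude_noise(rng, s, 1.0, model.channels, 200_000)
            se = mags.std() / math.sqrt(mags.size)
            assert expected_magnitude_ratio(s, model) == pytest.approx(mags.mean(), abs=4 * se)


class TestBackgroundStats:
    @pytest.mark.parametrize(
        "model,expected",
        [(RICIAN, 0.655), (CHI4, 0.682)],
        ids=["rician", "chi4"],
    )
    def test_pure_noise_background_std(self, model, expected, rng, sample_magnitude_noise):
        """1e6 signal-free samples reproduce c_sigma (0.655 Rician, 0.682 chi)."""
        mags = sample_magnitude_noise(rng, 0.0, 1.0, model.channels, 1_000_000)
        img = MagnitudeImage(mags.reshape(1000, 1000), (0.1, 0.1, 1.0))
        bg = RegionMask(np.ones_like(img.values, dtype=bool), role="background")
        sigma_m, sigma_hat = background_stats(img, bg, model)
        assert sigma_m == pytest.approx(expected, abs=0.002)
        assert sigma_hat == pytest.approx(sigma_m / model.c_sigma)

    def test_closed_form_within_monte_carlo_error(self, rng, sample_magnitude_noise):
        """Derived c_sigma agrees with sampling to within 3 standard errors."""
        for model in (RICIAN, CHI4):
            mags = sample_magnitude_noise(rng, 0.0, 1.0, model.channels, 1_000_000)
            # std-of-std standard error for an approximately chi-derived sample
            se = mags.std(ddof=1) / math.sqrt(2 * (mags.size - 1))
            assert abs(mags.std(ddof=1) - c_sigma_closed_form(model.channels)) < 3 * se

    def test_constant_background_raises(self):
        img = MagnitudeImage(np.zeros((20, 20)), (1.0, 1.0, 1.0))
        bg = RegionMask(np.ones((20, 20), dtype=bool), role="background")
        with pytest.raises(EstimationError):
            background_stats(img, bg, RICIAN)

    def test_empty_background_raises(self):
        img = MagnitudeImage(np.ones((20, 20)), (1.0, 1.0, 1.0))
        bg = RegionMask(np.zeros((20, 20), dtype=bool), role="background")
        with pytest.raises(EstimationError):
            background_stats(img, bg, RICIAN)

    def test_small_background_warns(self, rng):
        img = MagnitudeImage(rng.random((5, 5)) + 0.1, (1.0, 1.0, 1.0))
        bg = RegionMask(np.ones((5, 5), dtype=bool), role="background")
        with pytest.warns(UserWarning, match="voxels"):
            background_stats(img, bg, RICIAN)


class TestCorrectSNR:
    def test_noise_floor_measurement_flagged_zero(self):
        # s_m equal to the sigma=1 Rician noise-floor mean
        est = correct_snr(1.2533, 0.655, NoiseModel(1))
        assert est.snr == 0.0 and est.flagged_subfloor

    def test_high_snr_inversion_matches_grid_oracle(self):
        # brute-force oracle: scan the mean function for the best matching S
        model = NoiseModel(1)
        grid = np.linspace(90.0, 110.0, 200_001)
        ratios = expected_magnitude_ratio(grid, model)
        oracle = grid[np.argmin(np.abs(ratios - 100.0 / (0.655 / model.c_sigma)))]
        est = correct_snr(100.0, 0.655, model)
        assert est.snr == pytest.approx(oracle, abs=1e-3)
        assert est.snr == pytest.approx(100.0, abs=0.1)

    def test_monte_carlo_round_trip_two_channel(self, rng, sample_magnitude_noise):
        """Sample mean + background std at true SNR 5 invert back to 5."""
        mags = sample_magnitude_noise(rng, 5.0, 1.0, 2, 100_000)
        noise = sample_magnitude_noise(rng, 0.0, 1.0, 2, 100_000)
        est = correct_snr(float(mags.mean()), float(noise.std(ddof=1)), CHI4)
        assert est.snr == pytest.approx(5.0, abs=0.1)

    @pytest.mark.parametrize("model", [RICIAN, CHI4], ids=["rician", "chi4"])
    def test_inversion_consistency(self, model):
        """correct_snr inverts expected_magnitude_ratio across [0.5, 50]."""
        sigma = 2.3
        for x in np.linspace(0.5, 50.0, 25):
            s_m = expected_magnitude_ratio(x, model) * sigma
            est = correct_snr(s_m, model.c_sigma * sigma, model)
            assert est.snr == pytest.approx(x, abs=1e-3)

    def test_high_ratio_close_to_rescaled_naive(self):
        # at high measured ratio the correction is a sub-0.5% effect
        # (the deviation falls off as (dof-1)/(2 r^2))
        for model in (NoiseModel(1), NoiseModel(2)):
            s_m, sigma_m = 30.0, 1.0
            naive = s_m / (sigma_m / model.c_sigma)
            est = correct_snr(s_m, sigma_m, model)
            assert abs(est.snr - naive) / naive < 0.005

    @pytest.mark.parametrize("true_snr", [1.0, 2.0, 5.0, 10.0])
    def test_bias_removal(self, true_snr, rng, sample_magnitude_noise):
        """Corrected estimator within 2% of truth at n=1e5; naive biased high at low SNR."""
        model = RICIAN
        mags = sample_magnitude_noise(rng, true_snr, 1.0, 1, 100_000)
        noise = sample_magnitude_noise(rng, 0.0, 1.0, 1, 100_000)
        s_m, sigma_m = float(mags.mean()), float(noise.std(ddof=1))
        est = correct_snr(s_m, sigma_m, model)
        assert abs(est.snr - true_snr) / true_snr < 0.02
        if true_snr <= 2.0:
            naive = s_m / (sigma_m / model.c_sigma)
            assert naive > true_snr * 1.05

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            correct_snr(1.0, 0.0, RICIAN)
        with pytest.raises(DomainError):
            correct_snr(-1.0, 1.0, RICIAN)


class TestCentralCircularROI:
    @staticmethod
    def _disc(n=64, radius=17.8):
        yy, xx = np.indices((n, n))
        return RegionMask(np.hypot(yy - n / 2, xx - n / 2) <= radius, role="cross_section")

    def test_ninety_percent_disc(self):
        region = self._disc()
        n = region.n_voxels
        assert n == pytest.approx(1000, abs=15)  # ~1000-px disc
        roi = central_circular_roi(region, fraction=0.9)
        assert roi.n_voxels <= int(0.9 * n)
        assert roi.n_voxels >= int(0.86 * n)  # discretization ring

    def test_fraction_one_is_identity_for_disc(self):
        region = self._disc()
        roi = central_circular_roi(region, fraction=1.0)
        assert np.array_equal(roi.mask, region.mask)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(DomainError):
            central_circular_roi(self._disc(), fraction=fraction)

    def test_roi_is_concentric_subset(self):
        region = self._disc()
        roi = central_circular_roi(region, fraction=0.5)
        assert np.all(region.mask[roi.mask])


class TestSNRMap:
    def _calibrated_setup(self, rng, value, channels=1):
        model = NoiseModel(channels, c_sigma_source="derived_closed_form")
        noise = rng.normal(0.0, 1.0, size=(2 * channels, 200, 200))
        bg_vals = np.sqrt((noise**2).sum(0))
        img_vals = np.concatenate([np.full((200, 200), float(value)), bg_vals], axis=0)
        img = MagnitudeImage(img_vals, (0.1, 0.1, 1.0))
        bg = np.zeros_like(img_vals, dtype=bool)
        bg[200:] = True
        return img, RegionMask(bg, role="background"), model

    def test_uniform_signal_maps_to_constant(self, rng):
        img, bg, model = self._calibrated_setup(rng, 10.0)
        smap = snr_map(img, bg, model)
        signal_part = smap[:200]
        assert np.allclose(signal_part, signal_part[0, 0])
        assert signal_part[0, 0] == pytest.approx(10.0, abs=0.2)

    def test_threshold_zeroes_low_values(self, rng):
        img, bg, model = self._calibrated_setup(rng, 6.0)
        img2 = MagnitudeImage(
            np.where(np.arange(img.shape[0])[:, None] < 100, img.values, img.values * 0.35),
            img.voxel_size_mm,
        )
        smap = snr_map(img2, bg, model, threshold=4.0)
        assert np.all(smap[(smap > 0)] >= 4.0)

    def test_overlapping_signal_mask_warns_but_computes(self, rng):
        img, bg, model = self._calibrated_setup(rng, 10.0)
        sig = RegionMask(np.ones(img.shape, dtype=bool), role="signal")
        with pytest.warns(UserWarning, match="overlaps"):
            smap = snr_map(img, bg, model, signal=sig)
        assert smap.shape == img.shape


class TestRoiSNR:
    def test_roi_mode_averages_then_corrects(self, rng, sample_magnitude_noise):
        model = RICIAN
        vals = sample_magnitude_noise(rng, 8.0, 1.0, 1, (100, 100))
        noise = sample_magnitude_noise(rng, 0.0, 1.0, 1, (100, 100))
        img = MagnitudeImage(np.concatenate([vals, noise]), (0.1, 0.1, 1.0))
        roi = np.zeros(img.shape, dtype=bool)
        roi[:100] = True
        bg = ~roi
        est = roi_snr(img, RegionMask(roi), RegionMask(bg, role="background"), model)
        assert est.snr == pytest.approx(8.0, abs=0.15)
        assert est.n_voxels == 10_000


@given(x=st.floats(0.1, 40.0), channels=st.sampled_from([1, 2]))
def test_mean_function_inversion_property(x, channels):
    """Round trip through the mean function recovers the true SNR."""
    model = NoiseModel(channels, c_sigma_source="derived_closed_form")
    sigma = 1.7
    s_m = expected_magnitude_ratio(x, model) * sigma
    est = correct_snr(s_m, model.c_sigma * sigma, model)
    assert est.snr == pytest.approx(x, abs=1e-3)
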