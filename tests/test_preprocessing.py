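"""Smoothing, decile binning, systemic removal, step extraction, selection."""

import numpy as np
import pytest

import nirstherm as nt
from nirstherm.exceptions import (
    CollinearityError,
    DegenerateInputError,
    RangeError,
    SelectionError,
)
from nirstherm.preprocessing import detect_steps


def _recording_from_matrix(grid, atten, temp=None, systemic=None):
    n = atten.shape[0]
    return nt.SpectralRecording(
        grid, np.arange(n, dtype=float), atten,
        temp if temp is not None else np.linspace(37.0, 33.5, n),
        systemic or {},
    )


class TestSmoothing:
    def test_reproduces_low_order_polynomials(self, animal_grid):
        lam = animal_grid.wavelengths_nm
        atten = np.tile(1e-4 * (lam - 800.0) ** 2 + 0.3, (12, 1))
        rec = _recording_from_matrix(animal_grid, atten)
        out = nt.smooth_spectra(rec, window_points=60, poly_order=3)
        np.testing.assert_allclose(out.attenuation, atten, atol=1e-9)

    def test_constant_unchanged_and_offset_commutes(self, animal_grid):
        rng = np.random.default_rng(0)
        atten = rng.normal(0.5, 0.01, (12, len(animal_grid)))
        rec = _recording_from_matrix(animal_grid, atten)
        shifted = _recording_from_matrix(animal_grid, atten + 0.7)
        a = nt.smooth_spectra(rec).attenuation
        b = nt.smooth_spectra(shifted).attenuation
        np.testing.assert_allclose(b, a + 0.7, atol=1e-12)
        const = _recording_from_matrix(animal_grid, np.full((12, len(animal_grid)), 0.4))
        np.testing.assert_allclose(nt.smooth_spectra(const).attenuation, 0.4, atol=1e-12)

    def test_reduces_noise_variance(self, animal_grid):
        """On a smooth truth (cubic in wavelength) SG smoothing is unbiased,
        so the variance about the truth must shrink."""
        lam = animal_grid.wavelengths_nm
        truth = np.tile(1e-8 * (lam - 800.0) ** 3 + 1e-4 * lam, (30, 1))
        rng = np.random.default_rng(5)
        noisy = _recording_from_matrix(
            animal_grid, truth + rng.normal(0, 2e-3, truth.shape),
            temp=np.linspace(37.0, 33.5, 30))
        smoothed = nt.smooth_spectra(noisy, 61, 3).attenuation
        assert np.var(smoothed - truth) < 0.2 * np.var(noisy.attenuation - truth)

    def test_window_longer_than_axis_errors(self, animal_grid):
        rec = _recording_from_matrix(animal_grid, np.zeros((12, len(animal_grid))))
        with pytest.raises(ValueError, match="12"):
            nt.smooth_spectra(rec, window_points=15, axis="time")


class TestTemperatureBinning:
    def test_equal_count_bins(self, animal_table):
        proto = nt.Protocol.continuous_cooling(duration_s=1000.0)
        rec = nt.simulate_recording(animal_table, proto, seed=0)
        bins = nt.bin_by_temperature(rec)
        assert [b.count for b in bins] == [10] * 10

    def test_remainder_goes_to_lowest_bins(self, animal_grid):
        atten = np.zeros((13, len(animal_grid)))
        rec = _recording_from_matrix(animal_grid, atten, temp=np.linspace(33.5, 37.0, 13))
        bins = nt.bin_by_temperature(rec)
        assert [b.count for b in bins] == [2, 2, 2, 1, 1, 1, 1, 1, 1, 1]

    def test_partition_property(self, animal_table):
        rec = nt.simulate_recording(
            animal_table, nt.Protocol.continuous_cooling(duration_s=1170.0),
            noise_sd=1e-3, seed=2)
        bins = nt.bin_by_temperature(rec)
        assert sum(b.count for b in bins) == rec.n_times
        assert all(b1.bin_label <= b2.bin_label
                   for b1, b2 in zip(bins, bins[1:]))

    def test_monotone_attenuation_at_water_peak(self, cooling_recording, animal_grid):
        bins = nt.bin_by_temperature(cooling_recording)
        j = animal_grid.nearest_index(740.0)
        vals = [b.values[j] for b in bins]
        assert np.all(np.diff(vals) > 0)  # warmer bin -> more absorption

    def test_constant_temperature_degenerate(self, animal_grid):
        rec = _recording_from_matrix(animal_grid, np.zeros((20, len(animal_grid))),
                                     temp=np.full(20, 36.0))
        with pytest.raises(DegenerateInputError):
            nt.bin_by_temperature(rec)


class TestWavelengthBinning:
    def test_zero_difference_at_minimum_temperature(self, cooling_recording, band_selection):
        bins = nt.bin_by_wavelength(cooling_recording, band_selection)
        i_min = int(np.argmin(cooling_recording.temperature_c))
        for b in bins:
            assert b.reference_subtracted
            assert b.values[i_min] == pytest.approx(0.0, abs=1e-15)

    def test_affine_and_monotone_in_temperature(self, cooling_recording, band_selection,
                                                animal_table):
        """Noiseless difference attenuation is affine in temperature; its
        direction follows the sign of the bin's mean temperature coefficient."""
        bins = nt.bin_by_wavelength(cooling_recording, band_selection)
        temp = cooling_recording.temperature_c
        order = np.argsort(temp)
        lam = cooling_recording.grid.wavelengths_nm
        for b in bins:
            coef = np.polyfit(temp, b.values, 1)
            np.testing.assert_allclose(np.polyval(coef, temp), b.values, atol=1e-12)
            in_bin = np.abs(lam - b.bin_label) <= (b.count / 2 + 1) * np.mean(np.diff(lam))
            mean_kappa = animal_table.kappa_h2o[in_bin].mean()
            sorted_vals = b.values[order]
            if abs(np.ptp(sorted_vals)) > 1e-8:
                assert np.sign(coef[0]) == np.sign(mean_kappa)
                assert np.all(np.sign(np.diff(sorted_vals)) == np.sign(mean_kappa))

    def test_ten_point_band_gives_single_wavelength_bins(self, cooling_recording, animal_grid):
        sel = nt.select_wavelengths(animal_grid, animal_grid.wavelengths_nm[:10])
        bins = nt.bin_by_wavelength(cooling_recording, sel)
        assert [b.count for b in bins] == [1] * 10

    def test_small_band_rejected(self, cooling_recording, animal_grid):
        sel = nt.select_wavelengths(animal_grid, animal_grid.wavelengths_nm[:5])
        with pytest.raises(ValueError):
            nt.bin_by_wavelength(cooling_recording, sel)


class TestAttenuationTemperatureR2:
    def test_linear_bin_means_give_unity(self, animal_grid):
        bins = [
            nt.BinnedAttenuation("temperature_binned", i + 1, 34.0 + 0.3 * i,
                                 np.full(4, 0.1 * i), 10)
            for i in range(10)
        ]
        assert nt.attenuation_temperature_r2(bins) == pytest.approx(1.0)

    def test_shuffled_bins_give_near_zero(self):
        rng = np.random.default_rng(3)
        r2s = []
        for _ in range(200):
            bins = [
                nt.BinnedAttenuation("temperature_binned", i + 1, 34.0 + 0.3 * i,
                                     rng.normal(size=4), 10)
                for i in range(10)
            ]
            r2s.append(nt.attenuation_temperature_r2(bins))
        assert np.mean(r2s) < 0.25  # E[R2] = 1/(n-2) ~ 0.125 under the null

    def test_noiseless_cooling_simulation_strongly_linear(self, cooling_recording):
        bins = nt.bin_by_temperature(cooling_recording)
        assert nt.attenuation_temperature_r2(bins) > 0.95

    def test_zero_variance_degenerate(self):
        bins = [
            nt.BinnedAttenuation("temperature_binned", i + 1, 34.0, np.ones(4), 10)
            for i in range(10)
        ]
        with pytest.raises(DegenerateInputError):
            nt.attenuation_temperature_r2(bins)


class TestSystemicRegression:
    @staticmethod
    def _mixed_recording(grid, seed=0, extra=None):
        rng = np.random.default_rng(seed)
        n = 120
        hr = 160 + 8 * np.sin(np.linspace(0, 7, n)) + rng.normal(0, 0.5, n)
        bp = 45 + 5 * np.cos(np.linspace(0, 3, n)) + rng.normal(0, 0.5, n)
        w_hr = rng.normal(size=len(grid))
        w_bp = rng.normal(size=len(grid))
        atten = np.outer(hr, w_hr) + np.outer(bp, w_bp) + 0.3
        if extra is not None:
            atten = atten + extra
        return nt.SpectralRecording(
            grid, np.arange(n, dtype=float), atten,
            np.linspace(33.5, 37.0, n), {"heart_rate": hr, "mean_bp": bp})

    def test_exact_mix_gives_zero_residuals(self, human_grid):
        rec = self._mixed_recording(human_grid)
        out = nt.regress_out_systemic(rec)
        np.testing.assert_allclose(out.attenuation, 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_channels(self, human_grid):
        rng = np.random.default_rng(1)
        rec = self._mixed_recording(
            human_grid, seed=1, extra=rng.normal(0, 0.01, (120, len(human_grid))))
        out = nt.regress_out_systemic(rec)
        for ch in out.systemic.values():
            inner = out.attenuation.T @ (ch - ch.mean())
            assert np.max(np.abs(inner)) < 1e-8

    def test_idempotent(self, human_grid):
        rng = np.random.default_rng(2)
        rec = self._mixed_recording(
            human_grid, seed=2, extra=rng.normal(0, 0.01, (120, len(human_grid))))
        once = nt.regress_out_systemic(rec)
        twice = nt.regress_out_systemic(once)
        np.testing.assert_allclose(twice.attenuation, once.attenuation, atol=1e-10)

    def test_reduces_heart_rate_correlation(self, human_table):
        proto = nt.Protocol.stepwise_rewarming(duration_s=1800.0, step_interval_s=600.0)
        rec = nt.simulate_recording(
            human_table, proto, systemic_spec=nt.SystemicSpec(leakage_od=5e-3),
            noise_sd=1e-4, seed=4)
        out = nt.regress_out_systemic(rec)
        hr = rec.systemic["heart_rate"]

        def max_corr(a):
            ac = a - a.mean(axis=0)
            hc = hr - hr.mean()
            denom = np.linalg.norm(ac, axis=0) * np.linalg.norm(hc)
            return np.max(np.abs(ac.T @ hc) / denom)

        assert max_corr(out.attenuation) < max_corr(rec.attenuation)

    def test_collinear_channels_rejected(self, human_grid):
        n = 50
        hr = np.linspace(100, 200, n)
        rec = nt.SpectralRecording(
            human_grid, np.arange(n, dtype=float),
            np.zeros((n, len(human_grid))), np.linspace(33.5, 37, n),
            {"heart_rate": hr, "hr_copy": 2 * hr + 3})
        with pytest.raises(CollinearityError):
            nt.regress_out_systemic(rec)


class TestStepExtraction:
    def test_one_sample_per_step(self, rewarming_recording):
        steps = detect_steps(rewarming_recording)
        assert steps.size == 7
        out = nt.extract_step_responses(rewarming_recording, steps)
        assert out.n_times == 7
        np.testing.assert_allclose(out.temperature_c,
                                   34.0 + 0.5 * np.arange(7))

    def test_exponential_relaxation_closed_form(self, human_grid):
        """Difference ~ a*(1 - exp(-window/tau)) for a pure relaxation step."""
        tau, amp, window = 30.0, 0.05, 60.0
        t = np.arange(0.0, 300.0, 1.0)
        step_t = 100.0
        resp = np.where(t >= step_t, amp * (1 - np.exp(-(t - step_t) / tau)), 0.0)
        atten = np.tile(resp[:, None], (1, len(human_grid)))
        temp = np.where(t >= step_t, 34.0, 33.5)
        rec = nt.SpectralRecording(human_grid, t, atten, temp)
        out = nt.extract_step_responses(rec, [step_t], window_s=window)
        expected = amp * (1 - np.exp(-window / tau))
        np.testing.assert_allclose(out.attenuation, expected, rtol=1e-10)

    def test_zero_amplitude_steps(self, human_grid):
        t = np.arange(0.0, 300.0, 1.0)
        rec = nt.SpectralRecording(
            human_grid, t, np.full((t.size, len(human_grid)), 0.2),
            np.where(t >= 150, 34.0, 33.5))
        out = nt.extract_step_responses(rec, [150.0])
        np.testing.assert_allclose(out.attenuation, 0.0, atol=1e-15)

    def test_overlapping_windows_rejected(self, rewarming_recording):
        with pytest.raises(ValueError, match="overlap"):
            nt.extract_step_responses(rewarming_recording, [600.0, 630.0], 60.0)

    def test_step_outside_recording_rejected(self, rewarming_recording):
        with pytest.raises(RangeError):
            nt.extract_step_responses(rewarming_recording, [4490.0], 60.0)


class TestWavelengthSelection:
    def test_single_wavelength_nearest_point(self, human_grid):
        sel = nt.select_wavelengths(human_grid, "840")
        assert len(sel) == 1
        assert abs(sel.wavelengths_nm[0] - 840.0) <= 1.0

    def test_band_on_animal_grid(self, animal_grid):
        sel = nt.select_wavelengths(animal_grid, "band_720_880")
        lam = sel.wavelengths_nm
        assert lam.min() >= 720.0 and lam.max() <= 880.0
        full = animal_grid.wavelengths_nm
        assert len(sel) == np.sum((full >= 720) & (full <= 880))

    def test_740_unavailable_on_human_grid(self, human_grid):
        """The 770-906 nm grid cannot honour a 740 nm request."""
        with pytest.raises(SelectionError):
            nt.select_wavelengths(human_grid, "740")

    def test_band_unavailable_on_human_grid(self, human_grid):
        with pytest.raises(SelectionError):
            nt.select_wavelengths(human_grid, "band_720_880")

    def test_custom_selection(self, animal_grid):
        sel = nt.select_wavelengths(animal_grid, [740, 840, 970])
        assert sel.label == "custom"
        assert len(sel) == 3
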