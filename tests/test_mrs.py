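"""31P processing and quantification: closed-form oracles and round trips."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myoenergetics import mrs
from myoenergetics.datatypes import (DEFAULT_WINDOWS, AcquisitionParams,
                                     DynamicAcquisition, Spectrum)
from myoenergetics.synthetic import (TruthParams, _fid_from_peaks,
                                     _spectrum_from_peaks, default_peaks,
                                     PeakModel, simulate_dynamic_timecourse,
                                     simulate_fully_relaxed)


class TestProcessSpectrum:
    def test_single_line_halfwidth_matches_closed_form(self):
        """A decaying cosinusoid transforms to a Lorentzian of FWHM
        (R2 + pi LB)/pi Hz — the closed-form apodization identity."""
        acq = AcquisitionParams(line_broadening=10.0)
        r2 = np.pi * 20.0
        t = np.arange(acq.n_points) * acq.dwell_time
        f0 = 500.0
        fid = np.exp((2j * np.pi * f0 - r2) * t)
        spec = mrs.process_spectrum(fid, acq, phase_mode="none")
        f_hz = spec.ppm * acq.spectrometer_freq
        y = spec.real
        half = y.max() / 2
        i = int(np.argmax(y))
        # interpolate the two half-maximum crossings
        j = i
        while y[j] > half:
            j -= 1
        left = np.interp(half, [y[j], y[j + 1]], [f_hz[j], f_hz[j + 1]])
        j = i
        while y[j] > half:
            j += 1
        right = np.interp(half, [y[j], y[j - 1]], [f_hz[j], f_hz[j - 1]])
        fwhm = right - left
        expected = (r2 + np.pi * acq.line_broadening) / np.pi
        assert fwhm == pytest.approx(expected, rel=0.05)
        assert f_hz[np.argmax(y)] == pytest.approx(f0, abs=3.0)

    def test_no_broadening_no_phase_is_plain_dft(self):
        acq = AcquisitionParams()
        rng = np.random.default_rng(0)
        fid = rng.normal(size=acq.n_points) + 1j * rng.normal(size=acq.n_points)
        spec = mrs.process_spectrum(fid, acq, phase_mode="none")
        expected = fid.copy()
        expected[0] *= 0.5  # documented first-point convention
        np.testing.assert_allclose(spec.intensity,
                                   np.fft.fftshift(np.fft.fft(expected)),
                                   rtol=1e-12)

    def test_auto_phase_recovers_90_degree_misphase(self, truth):
        acq = AcquisitionParams.fully_relaxed()
        fid = _fid_from_peaks(
            default_peaks(truth.pcr_rest, truth.pi_rest, truth.atp,
                          truth.ph_rest), acq) * np.exp(1j * np.pi / 2)
        spec = mrs.process_spectrum(fid, acq, phase_mode="auto")
        tag = next(f for f in spec.flags if f.startswith("phase:"))
        phi0 = float(tag.split(":")[1].split(",")[0])
        err = np.degrees((phi0 - np.pi / 2 + np.pi) % (2 * np.pi) - np.pi)
        assert abs(err) < 1.0

    def test_all_zero_input_flagged_empty(self):
        acq = AcquisitionParams()
        spec = mrs.process_spectrum(np.zeros(acq.n_points, complex), acq)
        assert "empty" in spec.flags

    def test_wrong_length_rejected(self):
        acq = AcquisitionParams()
        with pytest.raises(ValueError, match="n_points"):
            mrs.process_spectrum(np.ones(10, complex), acq)


class TestIntegrateRelaxed:
    def test_identical_peaks_give_unit_ratio(self):
        acq = AcquisitionParams.fully_relaxed()
        peaks = [PeakModel("pcr", 0.0, 15.0, 5.0),
                 PeakModel("gatp", -2.48, 15.0, 5.0)]
        spec = Spectrum(acq.ppm_axis(), _spectrum_from_peaks(peaks, acq), acq)
        quant = mrs.integrate_relaxed(
            spec, {"pcr": DEFAULT_WINDOWS["pcr"],
                   "gatp": DEFAULT_WINDOWS["gatp"]})
        assert quant.areas["pcr"] / quant.areas["gatp"] == pytest.approx(
            1.0, rel=1e-8)

    @pytest.mark.parametrize("method,rtol", [("fit", 1e-6),
                                             ("trapezoid", 5e-3)])
    def test_noiseless_roundtrip_ratio(self, relaxed_noiseless, truth,
                                       method, rtol):
        quant = mrs.integrate_relaxed(relaxed_noiseless, method=method)
        assert quant.pcr_over_atp == pytest.approx(
            truth.pcr_rest / truth.atp, rel=rtol)
        # the plain trapezoid Pi ratio is tail-truncation limited (its
        # window is wider than the ATP one), hence the looser bound
        assert quant.pi_over_atp == pytest.approx(
            truth.pi_rest / truth.atp, rel=max(rtol * 6, 1e-4))

    def test_window_outside_axis_rejected(self, relaxed_noiseless):
        with pytest.raises(ValueError, match="outside"):
            mrs.integrate_relaxed(relaxed_noiseless,
                                  {"pcr": (0.0, 100.0)})

    def test_overlapping_windows_rejected(self, relaxed_noiseless):
        with pytest.raises(ValueError, match="overlap"):
            mrs.integrate_relaxed(relaxed_noiseless,
                                  {"a": (0.0, 2.0), "b": (1.0, 3.0)})

    def test_baseline_only_window_near_zero_area(self, relaxed_noiseless):
        quant = mrs.integrate_relaxed(
            relaxed_noiseless,
            {"pcr": DEFAULT_WINDOWS["pcr"], "gatp": DEFAULT_WINDOWS["gatp"],
             "empty": (8.0, 12.0)})
        assert quant.areas["empty"] == pytest.approx(
            0.0, abs=1e-4 * quant.areas["pcr"])

    def test_mean_ratio_within_2pct_at_snr_50(self, truth):
        vals = []
        for rep in range(40):
            t = dataclasses.replace(truth, seed=3000 + rep)
            spec = simulate_fully_relaxed(t, snr=50.0)
            vals.append(mrs.integrate_relaxed(spec).pcr_over_atp)
        assert np.mean(vals) == pytest.approx(truth.pcr_rest / truth.atp,
                                              rel=0.02)


class TestSumDynamic:
    def _tiny_series(self, n_frames, seed=0, snr=np.inf):
        acq = AcquisitionParams.dynamic(n_points=512, sweep_width=10_000.0)
        rng = np.random.default_rng(seed)
        base = _spectrum_from_peaks([PeakModel("pcr", 0.0, 15.0, 10.0)], acq)
        spectra = np.tile(base, (n_frames, 1))
        if np.isfinite(snr):
            sigma = base.real.max() / snr
            spectra = spectra + rng.normal(0, sigma, spectra.shape) \
                + 1j * rng.normal(0, sigma, spectra.shape)
        times = (np.arange(n_frames) + 0.5) * 6.0
        return DynamicAcquisition(acq.ppm_axis(), spectra, times,
                                  ["rest"] * n_frames, acq)

    def test_block_count_and_amplitude(self):
        series = self._tiny_series(9)
        summed = mrs.sum_dynamic(series, 3)
        assert len(summed) == 3
        np.testing.assert_allclose(summed.spectra[0],
                                   3 * series.spectra[0], rtol=1e-12)
        assert summed.times[0] == pytest.approx(series.times[:3].mean())

    def test_partial_block_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="partial block"):
            summed = mrs.sum_dynamic(self._tiny_series(10), 3)
        assert len(summed) == 3

    def test_snr_improves_sqrt_block(self):
        """Summing 3 iid-noise spectra improves PCr SNR by sqrt(3)."""
        gains = []
        for rep in range(100):
            series = self._tiny_series(3, seed=rep, snr=20.0)
            summed = mrs.sum_dynamic(series, 3)
            snr1 = mrs.peak_snr(series.frame(0))
            snr3 = mrs.peak_snr(summed.frame(0))
            gains.append(snr3 / snr1)
        assert np.mean(gains) == pytest.approx(np.sqrt(3.0), rel=0.10)


class TestFitToStandard:
    def test_half_amplitude_frame_gives_half_magnitudes(
            self, relaxed_noiseless):
        quant = mrs.integrate_relaxed(relaxed_noiseless)
        series = DynamicAcquisition(
            relaxed_noiseless.ppm,
            0.5 * relaxed_noiseless.intensity[None, :],
            np.array([0.0]), ["rest"], relaxed_noiseless.params)
        fits = mrs.fit_to_standard(relaxed_noiseless, series)
        for peak in ("pcr", "pi", "gatp"):
            assert fits[peak].iloc[0] == pytest.approx(
                0.5 * quant.areas[peak], rel=1e-9)

    def test_shifted_pi_recovered(self, relaxed_noiseless, truth):
        acq = relaxed_noiseless.params
        peaks = default_peaks(truth.pcr_rest, truth.pi_rest, truth.atp,
                              truth.ph_rest)
        shifted = [dataclasses.replace(p, center=p.center + 0.1)
                   if p.name == "pi" else p for p in peaks]
        frame = _spectrum_from_peaks(shifted, acq)
        series = DynamicAcquisition(relaxed_noiseless.ppm, frame[None, :],
                                    np.array([0.0]), ["rest"], acq)
        fits = mrs.fit_to_standard(relaxed_noiseless, series)
        assert fits["shift_pi"].iloc[0] == pytest.approx(0.1, abs=0.01)

    def test_pure_noise_frame_flagged(self, relaxed_noiseless):
        rng = np.random.default_rng(1)
        scale = np.abs(relaxed_noiseless.real).max()
        frame = rng.normal(0, scale, relaxed_noiseless.intensity.shape) \
            + 0j
        series = DynamicAcquisition(relaxed_noiseless.ppm, frame[None, :],
                                    np.array([0.0]), ["rest"],
                                    relaxed_noiseless.params)
        fits = mrs.fit_to_standard(relaxed_noiseless, series)
        assert bool(fits["flagged"].iloc[0])
        assert np.isnan(fits["pcr"].iloc[0])

    def test_fit_beats_windowed_integration_at_low_snr(self, truth):
        """Template fitting is at least as accurate as plain integration
        over repeated low-SNR frames (matched-filter argument)."""
        std = simulate_fully_relaxed(truth, snr=np.inf)
        acq = AcquisitionParams.dynamic()
        peaks = default_peaks(truth.pcr_rest, truth.pi_rest, truth.atp,
                              truth.ph_rest)
        clean = _spectrum_from_peaks(peaks, acq)
        rng = np.random.default_rng(8)
        sigma = clean.real.max() / 8.0  # low SNR
        n_frames = 200
        frames = clean[None, :] + rng.normal(
            0, sigma, (n_frames, acq.n_points)) + 1j * rng.normal(
            0, sigma, (n_frames, acq.n_points))
        series = DynamicAcquisition(acq.ppm_axis(), frames,
                                    np.arange(n_frames) * 6.0,
                                    ["rest"] * n_frames, acq)
        fits = mrs.fit_to_standard(std, series)
        fit_vals = fits["pcr"].to_numpy()
        trap_vals = np.array([
            mrs.integrate_relaxed(series.frame(i),
                                  method="trapezoid").areas["pcr"]
            for i in range(n_frames)])
        rmse_fit = np.std(fit_vals / np.mean(fit_vals))
        rmse_trap = np.std(trap_vals / np.mean(trap_vals))
        assert rmse_fit <= rmse_trap


class TestPH:
    def test_midpoint_gives_pka(self):
        assert mrs.compute_ph(4.465) == pytest.approx(6.77, abs=1e-10)

    def test_inverted_value_for_ph_7(self):
        assert mrs.compute_ph(mrs.inverse_ph(7.0)) == pytest.approx(7.0)
        assert mrs.compute_ph(4.784) == pytest.approx(7.0, abs=5e-3)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="3.23"):
            mrs.compute_ph(5.70)
        with pytest.raises(ValueError):
            mrs.compute_ph(3.23)

    @given(st.floats(min_value=6.2, max_value=7.6))
    def test_roundtrip_12_digits(self, ph):
        assert mrs.compute_ph(mrs.inverse_ph(ph)) == pytest.approx(
            ph, abs=1e-12)


class TestFreeADP:
    def test_reference_arithmetic(self):
        """ATP 8.2, Cr 10, PCr 32 mM at pH 7 give ~15.4 uM free ADP."""
        adp = mrs.compute_free_adp(pcr=32.0, atp=8.2, creatine_free=10.0,
                                   ph=7.0)
        assert adp * 1000 == pytest.approx(15.4, abs=0.05)

    def test_linear_in_creatine_and_inverse_in_proton(self):
        base = mrs.compute_free_adp(32.0, 8.2, 10.0, 7.0)
        assert mrs.compute_free_adp(32.0, 8.2, 20.0, 7.0) == pytest.approx(
            2 * base)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mrs.compute_free_adp(32.0, 8.2, 10.0, 6.0) \
                == pytest.approx(base / 10)

    @given(st.floats(min_value=1.0, max_value=40.0),
           st.floats(min_value=1.0, max_value=40.0))
    def test_monotone_in_creatine(self, cr_lo, cr_hi):
        lo, hi = sorted([cr_lo, cr_hi])
        a = mrs.compute_free_adp(32.0, 8.2, lo, 7.0)
        b = mrs.compute_free_adp(32.0, 8.2, hi, 7.0)
        assert a <= b

    def test_zero_pcr_rejected(self):
        with pytest.raises(ValueError):
            mrs.compute_free_adp(0.0, 8.2, 10.0, 7.0)

    def test_amp_equilibrium(self):
        assert mrs.compute_amp(0.015, 8.2) == pytest.approx(
            1.05 * 0.015 ** 2 / 8.2)


class TestCalibration:
    def test_noiseless_calibration_recovers_rest_state(
            self, noiseless_experiment, truth):
        met = noiseless_experiment["metabolites"]
        rest = met[met["phase"] == "rest"]
        assert rest["pcr"].mean() == pytest.approx(truth.pcr_rest, rel=1e-9)
        assert rest["atp"].mean() == pytest.approx(truth.atp, rel=1e-9)
        assert rest["ph"].mean() == pytest.approx(truth.ph_rest, abs=2e-3)
        assert rest["adp"].mean() * 1000 == pytest.approx(15.4, abs=0.1)

    def test_reference_scaling_is_multiplicative(
            self, relaxed_noiseless, truth):
        quant = mrs.integrate_relaxed(relaxed_noiseless)
        series = DynamicAcquisition(
            relaxed_noiseless.ppm, relaxed_noiseless.intensity[None, :],
            np.array([0.0]), ["rest"], relaxed_noiseless.params)
        fits = mrs.fit_to_standard(relaxed_noiseless, series)
        a = mrs.calibrate_concentrations(fits, quant, truth.atp, 42.0)
        b = mrs.calibrate_concentrations(fits, quant, 2 * truth.atp, 42.0)
        np.testing.assert_allclose(2 * a["pcr"], b["pcr"], rtol=1e-12)

    def test_empty_series_rejected(self, relaxed_noiseless):
        quant = mrs.integrate_relaxed(relaxed_noiseless)
        with pytest.raises(ValueError, match="empty"):
            mrs.calibrate_concentrations(pd.DataFrame(), quant, 8.2, 42.0)


class TestSlidingSum:
    def test_sliding_window_count_and_amplitude(self):
        helper = TestSumDynamic()
        series = helper._tiny_series(9)
        summed = mrs.sum_dynamic(series, 3, mode="sliding")
        assert len(summed) == 7
        np.testing.assert_allclose(summed.spectra[0],
                                   3 * series.spectra[0], rtol=1e-12)
        assert summed.times[0] == pytest.approx(series.times[:3].mean())

    def test_unknown_mode_rejected(self):
        helper = TestSumDynamic()
        with pytest.raises(ValueError, match="mode"):
            mrs.sum_dynamic(helper._tiny_series(9), 3, mode="median")
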