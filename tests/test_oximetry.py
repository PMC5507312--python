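"""Optical saturation inference: derivative identities and PLS recovery."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from myoenergetics import oximetry
from myoenergetics.datatypes import (OpticalSeries, PigmentConcentrations,
                                     ProtocolSpec, SaturationSeries)
from myoenergetics.oximetry import (_second_derivative_matrix,
                                    compute_o2_content, predict_saturations,
                                    second_derivative,
                                    train_saturation_model)
from myoenergetics.synthetic import (TruthParams, default_reference_library,
                                     saturation_truth,
                                     simulate_optical_timecourse)


def _series(wl, frames):
    frames = np.atleast_2d(frames)
    n = frames.shape[0]
    return OpticalSeries(wl, frames, np.arange(n, dtype=float), ["rest"] * n)


class TestSecondDerivative:
    wl = np.arange(500.0, 651.0)

    def test_quadratic_gives_constant_second_derivative(self):
        out = second_derivative(_series(self.wl, 3.0 * self.wl ** 2))
        np.testing.assert_allclose(out.frames[0], 6.0, rtol=1e-8)

    def test_affine_baseline_annihilated_exactly(self):
        base = np.sin(self.wl / 21.0)
        with_affine = base + 5.0 + 0.3 * self.wl
        a = second_derivative(_series(self.wl, base))
        b = second_derivative(_series(self.wl, with_affine))
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-9)

    def test_sine_second_derivative_closed_form(self):
        # window 5 is adequate for a period-60 sine at 1 nm sampling
        omega = 2 * np.pi / 60.0
        y = np.sin(omega * self.wl)
        out = second_derivative(_series(self.wl, y), window=5)
        expected = -omega ** 2 * np.sin(omega * out.wavelength)
        np.testing.assert_allclose(out.frames[0], expected,
                                   atol=0.01 * omega ** 2)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            second_derivative(_series(self.wl, self.wl), window=4)


class TestSaturationModel:
    refs = default_reference_library()
    conc = PigmentConcentrations()

    def _mixtures(self, s_grid, rng, baseline=0.5, noise=0.02):
        s_hb, s_mb = np.meshgrid(s_grid, s_grid, indexing="ij")
        s_hb, s_mb = s_hb.ravel(), s_mb.ravel()
        wl = self.refs.wavelength
        u = (wl - wl.mean()) / (wl[-1] - wl[0])
        frames = (np.outer(s_hb * self.conc.hb_sites, self.refs.oxy_hb)
                  + np.outer((1 - s_hb) * self.conc.hb_sites,
                             self.refs.deoxy_hb)
                  + np.outer(s_mb * self.conc.mb, self.refs.oxy_mb)
                  + np.outer((1 - s_mb) * self.conc.mb, self.refs.deoxy_mb))
        coef = rng.normal(0, baseline, (frames.shape[0], 3))
        frames += coef[:, [0]] + coef[:, [1]] * u + coef[:, [2]] * u ** 2
        frames += rng.normal(0, noise, frames.shape)
        return frames, np.column_stack([s_hb, s_mb])

    def test_held_out_grid_rmse(self):
        model = train_saturation_model(self.refs, self.conc)
        rng = np.random.default_rng(21)
        frames, targets = self._mixtures(np.arange(0.05, 0.96, 0.1), rng)
        series = _series(self.refs.wavelength, frames)
        sats = predict_saturations(model, series)
        pred = np.column_stack([sats.s_hb, sats.s_mb])
        rmse = np.sqrt(np.mean((pred - targets) ** 2))
        assert rmse <= 0.02

    def test_pure_oxy_predicts_full_saturation(self):
        model = train_saturation_model(self.refs, self.conc)
        frame = (self.conc.hb_sites * self.refs.oxy_hb
                 + self.conc.mb * self.refs.oxy_mb)
        sats = predict_saturations(model, _series(self.refs.wavelength,
                                                  frame))
        assert sats.s_hb[0] == pytest.approx(1.0, abs=0.02)
        assert sats.s_mb[0] == pytest.approx(1.0, abs=0.02)

    def test_permuted_labels_destroy_predictivity(self):
        """Negative control: shuffling training targets removes the
        spectral-saturation association (predictive R^2 near zero)."""
        rng = np.random.default_rng(3)
        frames, targets = self._mixtures(np.linspace(0, 1, 11), rng)
        x = _second_derivative_matrix(frames, self.refs.wavelength, 11, 3)
        shuffled = targets[rng.permutation(len(targets))]
        pls = PLSRegression(n_components=4, scale=False).fit(x, shuffled)
        frames2, targets2 = self._mixtures(np.linspace(0, 1, 11),
                                           np.random.default_rng(4))
        x2 = _second_derivative_matrix(frames2, self.refs.wavelength, 11, 3)
        pred = pls.predict(x2)
        ss_res = np.sum((targets2 - pred) ** 2)
        ss_tot = np.sum((targets2 - targets2.mean(axis=0)) ** 2)
        assert 1 - ss_res / ss_tot < 0.1

    def test_excessive_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            train_saturation_model(self.refs, self.conc, n_components=50,
                                   n_baseline_draws=0, noise_sd=0.0)

    def test_recovery_on_simulated_timecourse(self):
        truth = TruthParams()
        protocol = ProtocolSpec()
        model = train_saturation_model(self.refs, self.conc)
        series = simulate_optical_timecourse(truth, protocol, self.refs)
        sats = predict_saturations(model, series)
        s_hb, s_mb = saturation_truth(truth, protocol, series.times)
        rmse = np.sqrt(np.nanmean((sats.s_hb - s_hb) ** 2
                                  + (sats.s_mb - s_mb) ** 2) / 2)
        assert rmse <= 0.03

    def test_baseline_invariance_of_predictions(self):
        model = train_saturation_model(self.refs, self.conc)
        truth = TruthParams()
        series = simulate_optical_timecourse(truth, ProtocolSpec(), self.refs,
                                             baseline_scale=0.0, snr=np.inf)
        shifted = OpticalSeries(series.wavelength,
                                series.frames + 2.0
                                + 0.01 * series.wavelength,
                                series.times, list(series.phase_labels))
        a = predict_saturations(model, series)
        b = predict_saturations(model, shifted)
        assert np.nanmax(np.abs(a.s_hb - b.s_hb)) < 0.005
        assert np.nanmax(np.abs(a.s_mb - b.s_mb)) < 0.005

    def test_zero_frame_flagged(self):
        model = train_saturation_model(self.refs, self.conc)
        sats = predict_saturations(
            model, _series(self.refs.wavelength,
                           np.zeros_like(self.refs.wavelength)))
        assert bool(sats.flagged[0])
        assert np.isnan(sats.s_hb[0])

    def test_grid_mismatch_rejected(self):
        model = train_saturation_model(self.refs, self.conc)
        wl = self.refs.wavelength[:-10]
        with pytest.raises(ValueError, match="wavelength"):
            predict_saturations(model, _series(wl, np.zeros_like(wl)))


class TestO2Content:
    conc = PigmentConcentrations(hb_sites=1.2, mb=0.4)

    def _sats(self, s_hb, s_mb):
        n = len(np.atleast_1d(s_hb))
        return SaturationSeries(
            np.arange(n, dtype=float), np.atleast_1d(np.array(s_hb, float)),
            np.atleast_1d(np.array(s_mb, float)), np.zeros(n),
            np.zeros(n, bool), np.zeros(n, bool), ["rest"] * n)

    def test_full_saturation_content(self):
        o2 = compute_o2_content(self._sats([1.0], [1.0]), self.conc)
        assert o2["o2_mM"].iloc[0] == pytest.approx(1.6)

    def test_zero_saturation_zero_content(self):
        o2 = compute_o2_content(self._sats([0.0], [0.0]), self.conc)
        assert o2["o2_mM"].iloc[0] == 0.0

    def test_linearity_in_mb(self):
        half = PigmentConcentrations(hb_sites=1.2, mb=0.2)
        a = compute_o2_content(self._sats([0.0], [0.8]), self.conc)
        b = compute_o2_content(self._sats([0.0], [0.8]), half)
        assert b["o2_mM"].iloc[0] == pytest.approx(a["o2_mM"].iloc[0] / 2)
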