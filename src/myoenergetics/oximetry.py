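"""Hb/Mb O2 saturations from optical spectra, and tissue O2 content.

Second derivatives along wavelength (Savitzky-Golay smoothing
differentiation) suppress the smooth tissue-scattering baseline; a partial
least squares (PLS) regression trained on synthetic mixtures of the
reference spectra maps each second-derivative frame to the pair of
saturations.  Saturations times pigment concentrations give the bound O2
content used by the flux calculations: because a saturation already
encodes the binding curve, content is simple site-occupancy bookkeeping
(no Hill inversion is needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression

from .datatypes import (OpticalSeries, PigmentConcentrations,
                        ReferenceLibrary, SaturationSeries)

__all__ = [
    "second_derivative", "train_saturation_model", "predict_saturations",
    "compute_o2_content", "SaturationModel",
]

DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 3
DEFAULT_N_COMPONENTS = 4


def second_derivative(series: OpticalSeries,
                      window: int = DEFAULT_SG_WINDOW,
                      polyorder: int = DEFAULT_SG_POLYORDER) -> OpticalSeries:
    """Smoothed second derivative of each frame along wavelength.

    Polynomial smoothing-differentiation; the half-window at each end where
    the polynomial fit is one-sided is truncated.  Any affine-in-wavelength
    baseline is annihilated exactly.
    """
    if window % 2 == 0 or window < polyorder + 2:
        raise ValueError("window must be odd and > polyorder + 1")
    step = float(np.mean(np.diff(series.wavelength)))
    deriv = savgol_filter(series.frames, window, polyorder, deriv=2,
                          delta=step, axis=1, mode="interp")
    half = window // 2
    sl = slice(half, series.frames.shape[1] - half)
    return OpticalSeries(series.wavelength[sl], deriv[:, sl], series.times,
                         list(series.phase_labels))


def _second_derivative_matrix(frames: np.ndarray, wavelength: np.ndarray,
                              window: int, polyorder: int) -> np.ndarray:
    step = float(np.mean(np.diff(wavelength)))
    deriv = savgol_filter(frames, window, polyorder, deriv=2, delta=step,
                          axis=1, mode="interp")
    half = window // 2
    return deriv[:, half:frames.shape[1] - half]


@dataclass
class SaturationModel:
    """PLS map from second-derivative optical frames to (S_Hb, S_Mb)."""

    pls: PLSRegression
    wavelength: np.ndarray       # full input grid the model expects
    window: int
    polyorder: int
    conc: PigmentConcentrations
    training_rmse: float
    n_components: int
    x_mean: np.ndarray = None  # training mean of the derivative features


def train_saturation_model(refs: ReferenceLibrary,
                           conc: PigmentConcentrations | None = None,
                           n_components: int = DEFAULT_N_COMPONENTS,
                           grid_step: float = 0.1,
                           n_baseline_draws: int = 3,
                           baseline_scale: float = 0.5,
                           noise_sd: float = 0.02,
                           window: int = DEFAULT_SG_WINDOW,
                           polyorder: int = DEFAULT_SG_POLYORDER,
                           rng: np.random.Generator | None = None,
                           ) -> SaturationModel:
    """Train the saturation regression on a synthetic mixture grid.

    The training set spans (S_Hb, S_Mb) on a [0, 1] x [0, 1] grid at the
    stated pigment concentrations, replicated under random smooth quadratic
    baselines and additive noise, then second-differentiated.  With
    ``n_baseline_draws=0`` and ``noise_sd=0`` a single deterministic
    baseline-free grid is used (the map is then exactly linear).
    """
    conc = conc or PigmentConcentrations()
    rng = rng if rng is not None else np.random.default_rng(12345)
    s = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    s_hb, s_mb = np.meshgrid(s, s, indexing="ij")
    s_hb, s_mb = s_hb.ravel(), s_mb.ravel()

    wl = refs.wavelength
    u = (wl - wl.mean()) / (wl[-1] - wl[0])
    base_frames = (np.outer(s_hb * conc.hb_sites, refs.oxy_hb)
                   + np.outer((1 - s_hb) * conc.hb_sites, refs.deoxy_hb)
                   + np.outer(s_mb * conc.mb, refs.oxy_mb)
                   + np.outer((1 - s_mb) * conc.mb, refs.deoxy_mb))
    reps = max(n_baseline_draws, 1)
    frames = np.tile(base_frames, (reps, 1))
    targets = np.tile(np.column_stack([s_hb, s_mb]), (reps, 1))
    if n_baseline_draws > 0:
        coef = rng.normal(0, baseline_scale, (frames.shape[0], 3))
        frames = frames + (coef[:, [0]] + coef[:, [1]] * u
                           + coef[:, [2]] * u ** 2)
    if noise_sd > 0:
        frames = frames + rng.normal(0, noise_sd, frames.shape)

    x = _second_derivative_matrix(frames, wl, window, polyorder)
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    if n_components > min(rank, x.shape[0] - 1):
        raise ValueError(
            f"n_components={n_components} exceeds training rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, targets)
    pred = pls.predict(x)
    rmse = float(np.sqrt(np.mean((pred - targets) ** 2)))
    return SaturationModel(pls, wl, window, polyorder, conc, rmse,
                           n_components, x.mean(axis=0))


def predict_saturations(model: SaturationModel,
                        series: OpticalSeries,
                        zero_tol: float = 1e-10) -> SaturationSeries:
    """Per-frame saturation predictions with residual diagnostics.

    Predictions are clipped to [0, 1] (clip flags retained); frames with no
    signal (all-zero within tolerance) are flagged and returned as NaN.
    The residual is the relative distance between each frame and its
    reconstruction from the PLS latent scores.
    """
    if (series.wavelength.shape != model.wavelength.shape
            or not np.allclose(series.wavelength, model.wavelength)):
        raise ValueError("series wavelength grid does not match the model")
    x = _second_derivative_matrix(series.frames, series.wavelength,
                                  model.window, model.polyorder)
    flagged = np.abs(series.frames).max(axis=1) < zero_tol
    pred = model.pls.predict(x)
    recon = model.pls.inverse_transform(model.pls.transform(x))
    num = np.linalg.norm(x - recon, axis=1)
    den = np.linalg.norm(x - model.x_mean, axis=1)
    residual = num / np.where(den > 0, den, 1.0)

    s_hb, s_mb = pred[:, 0].copy(), pred[:, 1].copy()
    tol = 1e-9  # numerical grace at the [0, 1] boundaries
    clipped = ((s_hb < -tol) | (s_hb > 1 + tol)
               | (s_mb < -tol) | (s_mb > 1 + tol))
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} saturation predictions clipped "
                      "to [0, 1]", stacklevel=2)
    s_hb, s_mb = np.clip(s_hb, 0, 1), np.clip(s_mb, 0, 1)
    s_hb[flagged] = np.nan
    s_mb[flagged] = np.nan
    return SaturationSeries(series.times, s_hb, s_mb, residual, clipped,
                            flagged, list(series.phase_labels))


def compute_o2_content(sats: SaturationSeries,
                       conc: PigmentConcentrations) -> pd.DataFrame:
    """Bound O2 content [O2](t) = S_Hb*hb_sites + S_Mb*mb (mM).

    Hemoglobin is expressed per O2-binding site (4 per tetramer, handled at
    input).  Returns a DataFrame with columns time, phase, o2_mM.
    """
    o2 = sats.s_hb * conc.hb_sites + sats.s_mb * conc.mb
    phase = (list(sats.phase_labels) if sats.phase_labels
             else [""] * len(sats.times))
    return pd.DataFrame({"time": sats.times, "phase": phase, "o2_mM": o2})
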