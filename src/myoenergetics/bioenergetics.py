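"""Flux estimation from the quantified time series.

Resting ATPase is the least-squares slope of the PCr decline during the
initial phase of ischemia (the creatine-kinase reaction buffers ATP, so
resting ATP demand is paid out of the PCr pool once O2 delivery stops);
resting O2 consumption is the matching slope of the bound-O2 content.
ATPmax — the maximal mitochondrial ATP synthesis rate — comes from the
monoexponential rate constant k of PCr recovery after ischemia, scaled by
resting PCr (ATPmax = k * PCr_rest).  P/O, the coupling efficiency, is the
resting ATP flux per oxygen atom: ATPase / (2 * O2 flux).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .datatypes import FluxResult, PeakQuantification, ProtocolSpec

__all__ = [
    "resting_atpase", "resting_o2_consumption", "fit_atpmax", "compute_po",
    "resting_levels", "full_flux_analysis", "DEFAULT_ISCHEMIA_WINDOW",
]

# seconds after cuff onset: skip the on-transient, stay in the linear phase
DEFAULT_ISCHEMIA_WINDOW = (30.0, 210.0)


def _decline_slope(time_s: np.ndarray, y: np.ndarray,
                   what: str) -> dict:
    """-slope of y vs time (per minute) with CI and diagnostics."""
    if len(time_s) < 4:
        raise ValueError(f"{what}: need >= 4 points in the fit window, "
                         f"got {len(time_s)}")
    t_min = np.asarray(time_s, dtype=float) / 60.0
    res = stats.linregress(t_min, y)
    flux = -res.slope
    half = 1.96 * res.stderr
    diag = {
        "slope_per_min": res.slope,
        "stderr": res.stderr,
        "ci95": (flux - half, flux + half),
        "r_squared": res.rvalue ** 2,
        "residual_sd": float(np.std(y - (res.intercept + res.slope * t_min),
                                    ddof=2)),
        "n": int(len(t_min)),
        "window_s": (float(time_s[0]), float(time_s[-1])),
    }
    flags = []
    if res.slope > 0 and res.slope - 1.96 * res.stderr > 0:
        warnings.warn(f"{what}: positive slope beyond its CI "
                      "(non-physiological rise)", stacklevel=3)
        flags.append("positive_slope")
    diag["flags"] = flags
    return {"flux": float(flux), "diagnostics": diag}


def _window_mask(df: pd.DataFrame, window: tuple[float, float],
                 protocol: ProtocolSpec) -> np.ndarray:
    lo = protocol.ischemia_start + window[0]
    hi = protocol.ischemia_start + window[1]
    if hi > protocol.recovery_start:
        raise ValueError("fit window extends beyond ischemia")
    t = df["time"].to_numpy()
    return (t >= lo) & (t <= hi) & (df["phase"] == "ischemia").to_numpy()


def resting_atpase(metabolites: pd.DataFrame,
                   window: tuple[float, float] = DEFAULT_ISCHEMIA_WINDOW,
                   protocol: ProtocolSpec | None = None) -> dict:
    """Resting ATPase flux (mM ATP min^-1) from the ischemic PCr decline.

    ``window`` is (start, end) seconds after ischemia onset; it must lie
    inside ischemia and contain at least 4 frames.
    """
    protocol = protocol or ProtocolSpec()
    mask = _window_mask(metabolites, window, protocol)
    sub = metabolites[mask].dropna(subset=["pcr"])
    return _decline_slope(sub["time"].to_numpy(), sub["pcr"].to_numpy(),
                          "resting_atpase")


def resting_o2_consumption(o2_content: pd.DataFrame,
                           window: tuple[float, float] =
                           DEFAULT_ISCHEMIA_WINDOW,
                           protocol: ProtocolSpec | None = None) -> dict:
    """Resting O2 consumption (mM O2 min^-1) from the ischemic O2 decline."""
    protocol = protocol or ProtocolSpec()
    mask = _window_mask(o2_content, window, protocol)
    sub = o2_content[mask].dropna(subset=["o2_mM"])
    return _decline_slope(sub["time"].to_numpy(), sub["o2_mM"].to_numpy(),
                          "resting_o2_consumption")


def fit_atpmax(metabolites: pd.DataFrame,
               recovery_start: float | None = None,
               protocol: ProtocolSpec | None = None,
               k_grid: Sequence[float] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0),
               ) -> dict:
    """ATPmax and k from a monoexponential fit of PCr recovery.

    Fits PCr(t) = PCr_end - dPCr * exp(-k (t - t0)) by nonlinear least
    squares with multi-start initialization over ``k_grid`` (min^-1), then
    ATPmax = k * PCr_rest with PCr_rest the pre-ischemia resting mean.
    """
    protocol = protocol or ProtocolSpec()
    t0 = protocol.recovery_start if recovery_start is None else recovery_start

    rest = metabolites[metabolites["phase"] == "rest"].dropna(subset=["pcr"])
    if len(rest) == 0:
        raise ValueError("no resting frames to define PCr_rest")
    pcr_rest = float(rest["pcr"].mean())

    rec = metabolites[(metabolites["time"] >= t0)
                      & (metabolites["phase"] == "recovery")]
    rec = rec.dropna(subset=["pcr"])
    if len(rec) < 8:
        raise ValueError(f"need >= 8 recovery points, got {len(rec)}")
    t = (rec["time"].to_numpy() - t0) / 60.0  # min
    y = rec["pcr"].to_numpy()
    if y[: max(len(y) // 4, 2)].mean() >= pcr_rest:
        raise ValueError("PCr not depleted below rest at recovery start")

    def model(tt, pcr_end, dpcr, k):
        return pcr_end - dpcr * np.exp(-k * tt)

    depletion0 = max(pcr_rest - y[0], 1e-3)
    best = None
    for k0 in k_grid:
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=[pcr_rest, depletion0, k0],
                bounds=([0.0, 1e-9, 1e-4], [np.inf, np.inf, 50.0]),
                xtol=1e-13, ftol=1e-13, gtol=1e-13, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return {"atpmax": float("nan"), "k_recovery": float("nan"),
                "pcr_rest": pcr_rest,
                "diagnostics": {"flags": ["non_convergence"]}}
    sse, popt, pcov = best
    pcr_end, dpcr, k = popt
    if dpcr <= 0:
        raise ValueError("fitted PCr depletion is not positive")
    perr = np.sqrt(np.diag(pcov))
    tss = float(np.sum((y - y.mean()) ** 2))
    diag = {
        "pcr_end": float(pcr_end), "dpcr": float(dpcr),
        "k_stderr": float(perr[2]),
        "k_ci95": (float(k - 1.96 * perr[2]), float(k + 1.96 * perr[2])),
        "r_squared": 1.0 - sse / tss if tss > 0 else float("nan"),
        "residual_sd": float(np.sqrt(sse / max(len(y) - 3, 1))),
        "n": int(len(y)),
        "flags": [],
    }
    return {"atpmax": float(k * pcr_rest), "k_recovery": float(k),
            "pcr_rest": pcr_rest, "diagnostics": diag}


def compute_po(atpase_rest: float, o2_rest: float) -> float:
    """P/O = ATPase / (2 * O2 flux): ATP per oxygen *atom* (the factor 2
    converts O2 to O).  Undefined (NaN) when the O2 flux is not positive."""
    if o2_rest <= 0 or not np.isfinite(o2_rest):
        warnings.warn("P/O undefined: resting O2 flux <= 0", stacklevel=2)
        return float("nan")
    return atpase_rest / (2.0 * o2_rest)


def resting_levels(quant: PeakQuantification,
                   atp_reference: float) -> dict[str, float]:
    """Resting PCr, Pi (mM) and their ATP ratios from relaxed integrals."""
    if atp_reference <= 0:
        raise ValueError("atp_reference must be > 0")
    if quant.areas.get("gatp", 0.0) <= 0:
        raise ValueError("zero ATP area in the relaxed spectrum")
    return {
        "pcr_over_atp": quant.pcr_over_atp,
        "pi_over_atp": quant.pi_over_atp,
        "pcr_mM": quant.pcr_over_atp * atp_reference,
        "pi_mM": quant.pi_over_atp * atp_reference,
        "atp_mM": atp_reference,
    }


def full_flux_analysis(metabolites: pd.DataFrame,
                       o2_content: pd.DataFrame,
                       protocol: ProtocolSpec | None = None,
                       window: tuple[float, float] = DEFAULT_ISCHEMIA_WINDOW,
                       ) -> FluxResult:
    """All fluxes for one ischemia-recovery experiment."""
    protocol = protocol or ProtocolSpec()
    atpase = resting_atpase(metabolites, window, protocol)
    o2 = resting_o2_consumption(o2_content, window, protocol)
    rec = fit_atpmax(metabolites, protocol=protocol)
    po = compute_po(atpase["flux"], o2["flux"])
    flags = (atpase["diagnostics"].get("flags", [])
             + o2["diagnostics"].get("flags", [])
             + rec["diagnostics"].get("flags", []))
    return FluxResult(
        atpase_rest=atpase["flux"], o2_rest=o2["flux"],
        atpmax=rec["atpmax"], k_recovery=rec["k_recovery"], po_ratio=po,
        pcr_rest=rec["pcr_rest"],
        diagnostics={"atpase": atpase["diagnostics"],
                     "o2": o2["diagnostics"],
                     "recovery": rec["diagnostics"],
                     "window_s": window},
        flags=flags)
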