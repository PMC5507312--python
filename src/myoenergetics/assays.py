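"""Companion quantitative assays.

* Respirometry: per-state O2 fluxes from a closed-chamber trace with
  substrate-addition annotations, flux control ratios (FCR) to uncoupled
  respiration, and the cytochrome-c outer-membrane integrity check.
* Citrate synthase activity from the DTNB->TNB absorbance slope at 412 nm.
* Densitometry normalization of immunoblot band intensities to actin.
* ddPCR: Poisson copies-per-droplet from the positive-droplet fraction,
  absolute concentration, and the mtDNA deletion mutation frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import DropletCounts, RespirometryTrace

__all__ = [
    "StateFluxes", "respirometry_states", "citrate_synthase_activity",
    "densitometry_normalize", "ddpcr_frequency",
    "RESPIROMETRY_STATE_ORDER", "DTNB_EXTINCTION_MM_CM",
]

# state entered by each addition; state4 runs from the start of the trace
# (glutamate/pyruvate/malate present, no adenylates)
RESPIROMETRY_STATE_ORDER = ("state4", "state3_CI", "cytc", "state3_CI_CII",
                            "fccp")
_EVENT_TO_STATE = {"ADP": "state3_CI", "cytochrome_c": "cytc",
                   "succinate": "state3_CI_CII", "FCCP": "fccp"}

DTNB_EXTINCTION_MM_CM = 13.6  # mM^-1 cm^-1 for TNB at 412 nm


@dataclass
class StateFluxes:
    """Per-state O2 fluxes (pmol O2 s^-1 mg^-1) and flux control ratios."""

    fluxes: dict[str, float]
    fcr: dict[str, float]
    cytc_increase: float
    flags: list[str] = field(default_factory=list)


def respirometry_states(trace: RespirometryTrace,
                        steady_window: float = 60.0,
                        pre_event_gap: float = 10.0,
                        cytc_threshold: float = 0.15) -> StateFluxes:
    """Per-state fluxes from steady-state slopes before each addition.

    For each state the flux is minus the least-squares O2 slope over the
    last ``steady_window`` seconds ending ``pre_event_gap`` s before the
    next addition (or the end of the trace), converted from chamber
    nmol mL^-1 s^-1 to pmol s^-1 per mg wet fiber mass.  FCRs divide each
    state by the FCCP-uncoupled flux.  A cytochrome-c flux increase above
    ``cytc_threshold`` (fractional, over state3_CI) raises an
    outer-membrane integrity warning.
    """
    boundaries = [trace.time[0]]
    states = ["state4"]
    flags: list[str] = []
    for et, label in trace.events:
        state = _EVENT_TO_STATE.get(label)
        if state is None:
            flags.append(f"unknown_event:{label}")
            continue
        boundaries.append(et)
        states.append(state)
    boundaries.append(trace.time[-1] + 1e-9)

    for expected in RESPIROMETRY_STATE_ORDER:
        if expected not in states:
            flags.append(f"missing_state:{expected}")

    fluxes: dict[str, float] = {}
    for state, t0, t1 in zip(states, boundaries[:-1], boundaries[1:]):
        end = t1 - pre_event_gap if t1 < trace.time[-1] else t1
        start = max(t0, end - steady_window)
        mask = (trace.time >= start) & (trace.time <= end)
        if mask.sum() < 3:
            flags.append(f"too_few_points:{state}")
            fluxes[state] = float("nan")
            continue
        res = stats.linregress(trace.time[mask], trace.o2[mask])
        # nmol/mL/s -> pmol/s/mg
        fluxes[state] = (-res.slope * trace.chamber_volume_ml * 1000.0
                         / trace.fiber_mass)

    fccp = fluxes.get("fccp", float("nan"))
    fcr: dict[str, float] = {}
    for state, flux in fluxes.items():
        if state == "fccp":
            continue
        if not np.isfinite(fccp) or fccp <= 0:
            fcr[state] = float("nan")
        else:
            fcr[state] = flux / fccp
    if not np.isfinite(fccp) or fccp <= 0:
        flags.append("fcr_undefined")

    state3 = fluxes.get("state3_CI", float("nan"))
    cytc = fluxes.get("cytc", float("nan"))
    if np.isfinite(state3) and state3 > 0 and np.isfinite(cytc):
        cytc_increase = (cytc - state3) / state3
        if cytc_increase > cytc_threshold:
            warnings.warn(
                f"cytochrome-c flux increase {cytc_increase:.1%} exceeds "
                f"{cytc_threshold:.0%}: outer mitochondrial membrane "
                "integrity suspect", stacklevel=2)
            flags.append("membrane_integrity")
    else:
        cytc_increase = float("nan")
    return StateFluxes(fluxes, fcr, cytc_increase, flags)


def citrate_synthase_activity(time_min: np.ndarray,
                              absorbance_412: np.ndarray,
                              path_cm: float = 1.0,
                              dilution: float = 1.0,
                              tissue_mg_per_ml: float = 1.0,
                              extinction: float = DTNB_EXTINCTION_MM_CM,
                              ) -> float:
    """Citrate synthase activity (umol min^-1 g^-1 wet tissue).

    activity = (dA412/dt per min) / (extinction * path) * dilution
    / tissue concentration, with the absorbance slope from a least-squares
    line.  dA/(e*l) is mM min^-1 = umol min^-1 mL^-1 in the cuvette.
    """
    time_min = np.asarray(time_min, dtype=float)
    absorbance_412 = np.asarray(absorbance_412, dtype=float)
    if len(time_min) < 2:
        raise ValueError("need at least 2 absorbance points")
    for name, v in (("path_cm", path_cm), ("dilution", dilution),
                    ("tissue_mg_per_ml", tissue_mg_per_ml),
                    ("extinction", extinction)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    slope = stats.linregress(time_min, absorbance_412).slope
    if slope < -1e-12:
        raise ValueError("negative absorbance slope: TNB formation cannot "
                         "consume absorbance")
    rate_umol_per_min_per_ml = max(slope, 0.0) / (extinction * path_cm)
    return rate_umol_per_min_per_ml * dilution / (tissue_mg_per_ml / 1000.0)


def densitometry_normalize(band: float, actin: float) -> float:
    """Band intensity normalized to the actin loading control."""
    if actin <= 0:
        raise ValueError("actin intensity must be > 0")
    if band < 0:
        raise ValueError("band intensity must be >= 0")
    return band / actin


def ddpcr_frequency(counts: DropletCounts,
                    deletion_channel: str = "deletion",
                    total_channel: str = "total_mtDNA") -> dict:
    """Poisson quantification of droplet counts.

    Per channel: lambda = -ln(1 - k/n) copies per droplet, concentration
    lambda / droplet volume (copies/uL), binomial-propagated 95% CI on
    lambda.  If both the deletion and total-mtDNA channels are present, the
    mutation frequency is lambda_deletion / lambda_total.
    Saturated channels (k = n) are rejected.
    """
    n = counts.n_total
    out: dict = {"channels": {}}
    for channel, k in counts.n_positive.items():
        if k == n:
            raise ValueError(f"channel {channel!r} saturated "
                             "(all droplets positive)")
        p = k / n
        lam = -np.log1p(-p)
        se = np.sqrt(p / (n * (1.0 - p))) if k > 0 else 0.0
        vol_ul = counts.droplet_volume_nl * 1e-3
        out["channels"][channel] = {
            "n_positive": k,
            "fraction_positive": p,
            "lambda": float(lam),
            "lambda_se": float(se),
            "lambda_ci95": (float(max(lam - 1.96 * se, 0.0)),
                            float(lam + 1.96 * se)),
            "copies_per_ul": float(lam / vol_ul),
        }
    ch = out["channels"]
    if deletion_channel in ch and total_channel in ch:
        lam_tot = ch[total_channel]["lambda"]
        if lam_tot > 0:
            out["mutation_frequency"] = ch[deletion_channel]["lambda"] / lam_tot
        else:
            out["mutation_frequency"] = float("nan")
            out["flags"] = ["undefined_frequency:zero_total"]
    return out
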