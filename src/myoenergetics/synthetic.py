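"""Synthetic-data generation with known ground truth.

Everything the downstream pipeline consumes can be produced here: a fully
relaxed 31P reference spectrum, the dynamic 31P series through rest (2 min),
ischemia (11 min) and recovery (7 min), optical absorbance series mixing
oxy/deoxy hemoglobin and myoglobin reference spectra, a two-group cohort
table (body weights, treadmill run times, assay endpoints), closed-chamber
respirometry traces, and ddPCR droplet counts.

Signal model for 31P: each resonance is a Lorentzian (exponentially
decaying time-domain component) with area proportional to concentration;
the Pi resonance position encodes pH through the inverse of the
Henderson-Hasselbalch shift calibration.  Noise is additive iid Gaussian in
the frequency-domain spectrum, scaled so the resting PCr peak reaches the
requested SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (AcquisitionParams, DropletCounts, DynamicAcquisition,
                        OpticalSeries, ProtocolSpec, ReferenceLibrary,
                        RespirometryTrace, Spectrum)
from .mrs import inverse_ph

__all__ = [
    "TruthParams", "PeakModel", "StudyDesign", "EndpointSpec", "CohortTable",
    "simulate_fully_relaxed", "simulate_dynamic_timecourse",
    "simulate_optical_timecourse", "simulate_cohort", "simulate_respirometry",
    "simulate_droplets", "default_reference_library", "default_peaks",
    "pcr_truth", "ph_truth", "saturation_truth",
    "DEFAULT_DYNAMIC_SATURATION",
]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthParams:
    """Ground-truth physiology of one simulated hindlimb experiment.

    Defaults are literature-typical values for resting mouse distal hindlimb
    muscle; the phosphorus pools reproduce the creatine-kinase worked
    example (ATP 8.2 mM, PCr 32 mM, free creatine 10 mM, pH 7.0 gives free
    ADP of about 15 uM).
    """

    pcr_rest: float = 32.0          # mM
    pi_rest: float = 2.4            # mM
    atp: float = 8.2                # mM
    total_creatine: float = 42.0    # mM
    ph_rest: float = 7.0
    atpase_rest: float = 1.2        # mM ATP min^-1 (resting demand)
    k_recovery: float = 0.7         # min^-1 (PCr recovery rate constant)
    hb_sites: float = 1.2           # mM O2-binding sites
    mb: float = 0.4                 # mM
    o2_consumption: float = 0.25    # mM O2 min^-1 at rest
    snr: float = 25.0               # PCr peak SNR of one dynamic 31P spectrum
    optical_snr: float = 100.0      # peak-absorbance SNR of one optical frame
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pcr_rest", "pi_rest", "atp", "total_creatine",
                     "hb_sites", "mb"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("atpase_rest", "k_recovery", "o2_consumption", "snr",
                     "optical_snr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.pcr_rest > self.total_creatine:
            raise ValueError("pcr_rest cannot exceed total_creatine")
        if not 6.0 <= self.ph_rest <= 7.8:
            raise ValueError("ph_rest must lie in [6.0, 7.8]")

    @property
    def atpmax(self) -> float:
        """mM ATP min^-1 by the k x resting-PCr convention."""
        return self.k_recovery * self.pcr_rest

    @property
    def po_ratio(self) -> float:
        """ATP per O atom: ATPase / (2 x O2 consumption)."""
        return self.atpase_rest / (2.0 * self.o2_consumption)


@dataclass(frozen=True)
class PeakModel:
    """One Lorentzian resonance of the 31P signal model."""

    name: str
    center: float        # ppm relative to PCr
    linewidth: float     # Hz, FWHM
    area: float          # arbitrary units, proportional to concentration
    phase: float = 0.0   # rad

    def __post_init__(self) -> None:
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")


DEFAULT_LINEWIDTH_HZ = 15.0

# Apparent per-peak signal retention of the 45-degree short-delay dynamic
# acquisition relative to the fully relaxed one (partial T1 saturation).
DEFAULT_DYNAMIC_SATURATION = {"pi": 0.80, "pcr": 0.70, "gatp": 0.65,
                              "aatp": 0.65, "batp": 0.65}

_ATP_CENTERS = {"gatp": -2.48, "aatp": -7.52, "batp": -16.26}


def default_peaks(pcr: float, pi: float, atp: float, ph: float,
                  linewidth: float = DEFAULT_LINEWIDTH_HZ,
                  saturation: dict[str, float] | None = None,
                  ) -> list[PeakModel]:
    """Peak list for given concentrations; Pi position set by pH."""
    sat = saturation or {}
    peaks = [
        PeakModel("pcr", 0.0, linewidth, pcr * sat.get("pcr", 1.0)),
        PeakModel("pi", inverse_ph(ph), linewidth, pi * sat.get("pi", 1.0)),
    ]
    for name, center in _ATP_CENTERS.items():
        peaks.append(PeakModel(name, center, linewidth,
                               atp * sat.get(name, 1.0)))
    return peaks


def _fid_from_peaks(peaks: list[PeakModel],
                    acq: AcquisitionParams) -> np.ndarray:
    t = np.arange(acq.n_points) * acq.dwell_time
    fid = np.zeros(acq.n_points, dtype=complex)
    for p in peaks:
        f_hz = p.center * acq.spectrometer_freq  # MHz x ppm = Hz
        fid += p.area * np.exp((2j * np.pi * f_hz - np.pi * p.linewidth) * t
                               + 1j * p.phase)
    return fid


def _spectrum_from_peaks(peaks: list[PeakModel],
                         acq: AcquisitionParams) -> np.ndarray:
    """Noiseless zero-phase frequency-domain spectrum."""
    fid = _fid_from_peaks(peaks, acq)
    fid[0] *= 0.5
    return np.fft.fftshift(np.fft.fft(fid))


def _pcr_height(acq: AcquisitionParams, linewidth: float) -> float:
    """Real-spectrum peak height of a unit-area PCr resonance."""
    ref = _spectrum_from_peaks(
        [PeakModel("pcr", 0.0, linewidth, 1.0)], acq)
    return float(ref.real.max())


# ---------------------------------------------------------------------------
# Fully relaxed spectrum
# ---------------------------------------------------------------------------

def simulate_fully_relaxed(truth: TruthParams,
                           acq: AcquisitionParams | None = None,
                           snr: float | None = None,
                           linewidth: float = DEFAULT_LINEWIDTH_HZ,
                           rng: np.random.Generator | None = None,
                           ) -> Spectrum:
    """High-SNR reference spectrum under fully relaxed conditions.

    Peak areas are proportional to pi_rest, pcr_rest and atp; the Pi-PCr
    separation encodes ph_rest.  ``snr`` (default ``truth.snr`` scaled by
    sqrt(transients/4) relative to a dynamic acquisition) sets the PCr
    peak-height-to-noise-SD ratio; ``numpy.inf`` gives a noiseless spectrum.
    """
    acq = acq or AcquisitionParams.fully_relaxed()
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    if snr is None:
        # relative to a dynamic frame: more transients (sqrt averaging) and
        # no partial-saturation signal loss
        snr = (truth.snr * np.sqrt(acq.transients / 4.0)
               / DEFAULT_DYNAMIC_SATURATION["pcr"])
    peaks = default_peaks(truth.pcr_rest, truth.pi_rest, truth.atp,
                          truth.ph_rest, linewidth)
    intensity = _spectrum_from_peaks(peaks, acq)
    if np.isfinite(snr):
        sigma = truth.pcr_rest * _pcr_height(acq, linewidth) / snr
        intensity = intensity + (rng.normal(0, sigma, acq.n_points)
                                 + 1j * rng.normal(0, sigma, acq.n_points))
    return Spectrum(acq.ppm_axis(), intensity, acq, "rest", 0.0)


# ---------------------------------------------------------------------------
# Dynamic 31P time course
# ---------------------------------------------------------------------------

def pcr_truth(truth: TruthParams, protocol: ProtocolSpec,
              t: np.ndarray, pcr_floor: float = 1.0) -> np.ndarray:
    """Ground-truth PCr(t): flat at rest, linear decline under ischemia
    (floored), monoexponential return during recovery."""
    t = np.asarray(t, dtype=float)
    t_isch, t_rec = protocol.ischemia_start, protocol.recovery_start
    pcr = np.full_like(t, truth.pcr_rest)
    isch = (t >= t_isch) & (t < t_rec)
    pcr[isch] = np.maximum(
        truth.pcr_rest - truth.atpase_rest * (t[isch] - t_isch) / 60.0,
        pcr_floor)
    pcr_end = max(truth.pcr_rest
                  - truth.atpase_rest * protocol.ischemia_duration / 60.0,
                  pcr_floor)
    rec = t >= t_rec
    delta = truth.pcr_rest - pcr_end
    pcr[rec] = truth.pcr_rest - delta * np.exp(
        -truth.k_recovery * (t[rec] - t_rec) / 60.0)
    return pcr


def ph_truth(truth: TruthParams, protocol: ProtocolSpec, t: np.ndarray,
             ph_drift: float = 0.2) -> np.ndarray:
    """Ground-truth pH(t): linear acidification over ischemia (``ph_drift``
    units total), exponential return at the PCr recovery rate."""
    t = np.asarray(t, dtype=float)
    t_isch, t_rec = protocol.ischemia_start, protocol.recovery_start
    ph = np.full_like(t, truth.ph_rest)
    isch = (t >= t_isch) & (t < t_rec)
    ph[isch] = truth.ph_rest - ph_drift * (t[isch] - t_isch) \
        / protocol.ischemia_duration
    rec = t >= t_rec
    ph[rec] = truth.ph_rest - ph_drift * np.exp(
        -truth.k_recovery * (t[rec] - t_rec) / 60.0)
    return ph


def simulate_dynamic_timecourse(truth: TruthParams,
                                protocol: ProtocolSpec | None = None,
                                acq: AcquisitionParams | None = None,
                                snr: float | None = None,
                                ph_drift: float = 0.2,
                                pcr_floor: float = 1.0,
                                linewidth: float = DEFAULT_LINEWIDTH_HZ,
                                saturation: dict[str, float] | None = None,
                                rng: np.random.Generator | None = None,
                                ) -> DynamicAcquisition:
    """Dynamic 31P series through rest, ischemia and recovery.

    PCr is constant at rest, declines linearly at ``-atpase_rest`` during
    ischemia (floored at ``pcr_floor`` with a warning), and recovers
    monoexponentially at ``k_recovery``.  Pi mirrors PCr so the total
    phosphate pool is conserved; pH acidifies linearly by ``ph_drift`` over
    ischemia.  The 45-degree short-delay acquisition retains only a
    per-peak fraction of the fully relaxed signal (``saturation``).
    """
    protocol = protocol or ProtocolSpec()
    acq = acq or AcquisitionParams.dynamic()
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 1)
    snr = truth.snr if snr is None else snr
    saturation = dict(DEFAULT_DYNAMIC_SATURATION if saturation is None
                      else saturation)

    times = protocol.frame_times()
    if times.size == 0:
        raise ValueError("protocol shorter than one dynamic interval")
    depletion = truth.atpase_rest * protocol.ischemia_duration / 60.0
    if truth.pcr_rest - depletion < pcr_floor:
        warnings.warn("ischemia would drive PCr below the floor; "
                      f"flooring at {pcr_floor} mM", stacklevel=2)

    pcr = pcr_truth(truth, protocol, times, pcr_floor)
    pi = truth.pi_rest + (truth.pcr_rest - pcr)
    ph = ph_truth(truth, protocol, times, ph_drift)

    frames = np.empty((times.size, acq.n_points), dtype=complex)
    for i, t in enumerate(times):
        peaks = default_peaks(pcr[i], pi[i], truth.atp, ph[i], linewidth,
                              saturation)
        frames[i] = _spectrum_from_peaks(peaks, acq)
    if np.isfinite(snr):
        height = (truth.pcr_rest * saturation.get("pcr", 1.0)
                  * _pcr_height(acq, linewidth))
        sigma = height / snr
        frames += (rng.normal(0, sigma, frames.shape)
                   + 1j * rng.normal(0, sigma, frames.shape))
    labels = list(protocol.phase_of(times))
    return DynamicAcquisition(acq.ppm_axis(), frames, times, labels, acq)


# ---------------------------------------------------------------------------
# Optical time course
# ---------------------------------------------------------------------------

def _band(wl: np.ndarray, center: float, width: float,
          height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_reference_library(wl_min: float = 500.0, wl_max: float = 650.0,
                              step: float = 1.0) -> ReferenceLibrary:
    """Synthetic per-mM absorptivity spectra with distinct band structure.

    Smooth Gaussian-band curves standing in for oxy/deoxy Hb and Mb visible
    spectra: oxygenated species carry a split alpha/beta double band,
    deoxygenated species a single broader band, with the Mb bands offset a
    few nm from Hb so the two pigments are separable.  These are synthetic
    fixtures, not digitized literature spectra.
    """
    wl = np.arange(wl_min, wl_max + 0.5 * step, step)
    oxy_hb = _band(wl, 542, 9, 14.0) + _band(wl, 577, 8, 15.0)
    deoxy_hb = _band(wl, 555, 13, 13.0)
    oxy_mb = _band(wl, 544, 10, 13.0) + _band(wl, 582, 8, 14.0)
    deoxy_mb = _band(wl, 558, 14, 12.0)
    return ReferenceLibrary(wl, oxy_hb, deoxy_hb, oxy_mb, deoxy_mb)


def saturation_truth(truth: TruthParams, protocol: ProtocolSpec,
                     t: np.ndarray, s_hb0: float = 0.97, s_mb0: float = 0.90,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (S_Hb, S_Mb)(t).

    Both saturations scale down together during ischemia so the total bound
    O2 content s_hb*hb_sites + s_mb*mb falls at exactly ``o2_consumption``
    (floored at zero), then return exponentially during recovery.
    """
    t = np.asarray(t, dtype=float)
    total0 = s_hb0 * truth.hb_sites + s_mb0 * truth.mb
    if total0 <= 0:
        raise ValueError("no O2-carrying pigment")
    t_isch, t_rec = protocol.ischemia_start, protocol.recovery_start
    f = np.ones_like(t)
    isch = (t >= t_isch) & (t < t_rec)
    f[isch] = np.maximum(
        1.0 - truth.o2_consumption * (t[isch] - t_isch) / 60.0 / total0, 0.0)
    f_end = max(1.0 - truth.o2_consumption * protocol.ischemia_duration
                / 60.0 / total0, 0.0)
    rec = t >= t_rec
    f[rec] = 1.0 - (1.0 - f_end) * np.exp(
        -truth.k_recovery * (t[rec] - t_rec) / 60.0)
    return s_hb0 * f, s_mb0 * f


def simulate_optical_timecourse(truth: TruthParams,
                                protocol: ProtocolSpec | None = None,
                                refs: ReferenceLibrary | None = None,
                                interval: float = 2.0,
                                s_hb0: float = 0.97, s_mb0: float = 0.90,
                                baseline_scale: float = 0.5,
                                snr: float | None = None,
                                rng: np.random.Generator | None = None,
                                ) -> OpticalSeries:
    """Optical absorbance frames mixing the four pigment species.

    Each frame is S_Hb*hb*oxyHb + (1-S_Hb)*hb*deoxyHb + S_Mb*mb*oxyMb +
    (1-S_Mb)*mb*deoxyMb, plus a smooth quadratic scattering baseline with
    random per-frame coefficients, plus iid Gaussian noise.  Saturations
    outside [0, 1] are clipped with a warning.
    """
    protocol = protocol or ProtocolSpec()
    refs = refs or default_reference_library()
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 2)
    snr = truth.optical_snr if snr is None else snr

    times = np.arange(interval / 2.0, protocol.total_duration, interval)
    s_hb, s_mb = saturation_truth(truth, protocol, times, s_hb0, s_mb0)
    if np.any((s_hb < 0) | (s_hb > 1) | (s_mb < 0) | (s_mb > 1)):
        warnings.warn("saturations clipped to [0, 1]", stacklevel=2)
        s_hb, s_mb = np.clip(s_hb, 0, 1), np.clip(s_mb, 0, 1)

    wl = refs.wavelength
    u = (wl - wl.mean()) / (wl[-1] - wl[0])
    frames = (np.outer(s_hb * truth.hb_sites, refs.oxy_hb)
              + np.outer((1 - s_hb) * truth.hb_sites, refs.deoxy_hb)
              + np.outer(s_mb * truth.mb, refs.oxy_mb)
              + np.outer((1 - s_mb) * truth.mb, refs.deoxy_mb))
    if baseline_scale > 0:
        coef = rng.normal(0, baseline_scale, (times.size, 3))
        frames += (coef[:, [0]] + coef[:, [1]] * u + coef[:, [2]] * u ** 2)
    if np.isfinite(snr):
        sigma = float(np.max(refs.oxy_hb * truth.hb_sites)) / snr
        frames += rng.normal(0, sigma, frames.shape)
    labels = list(protocol.phase_of(times))
    return OpticalSeries(wl, frames, times, labels)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndpointSpec:
    """One per-animal assay endpoint: control distribution + treated effect."""

    control_mean: float
    sd: float
    effect: float = 0.0       # multiplicative fractional change in treated
    additive: bool = False    # if True, ``effect`` is added instead


def _default_endpoints() -> dict[str, EndpointSpec]:
    # Control means/SDs follow the study's printed summary values where
    # available; effects are the treated-vs-control fractional changes.
    return {
        "atpmax": EndpointSpec(696.2, 76.6, effect=-0.308),
        "pcr_atp": EndpointSpec(3.878, 0.1, effect=-0.164),
        "po": EndpointSpec(2.4, 0.2, effect=0.0),
        "cs_activity": EndpointSpec(1.0, 0.15, effect=0.0),
        "mutation_freq": EndpointSpec(2.0e-3, 5.0e-4, effect=0.0),
        "nfkb": EndpointSpec(0.053, 0.022, effect=0.717),
    }


@dataclass(frozen=True)
class StudyDesign:
    """Two-group (saline vs treated) six-week study design."""

    n_per_group: int = 10
    run_time_mean: float = 49.0       # min, baseline both groups
    run_time_sd: float = 16.8
    run_time_effect: float = -0.476   # fractional change, treated at 6wk
    run_time_followup_sd: float = 10.6
    weight_mean: float = 25.0         # g at day 0
    weight_between_sd: float = 1.5    # g, between animals
    weight_within_cv: float = 0.01    # day-to-day fractional noise
    dip_depth: float = 0.05           # treated transient weight loss
    dip_peak_day: int = 1
    dip_recovery_day: int = 25
    n_days: int = 42
    endpoints: dict[str, EndpointSpec] = field(
        default_factory=_default_endpoints)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be > 0")


@dataclass
class CohortTable:
    """Tidy per-animal study outcomes."""

    run_times: pd.DataFrame   # animal, group, timepoint, run_time_min, event
    weights: pd.DataFrame     # animal, group, day, weight_g
    endpoints: pd.DataFrame   # animal, group, timepoint, measure, value


def _dip_profile(days: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Fractional weight loss trajectory of the treated group: rises to
    ``dip_depth`` at ``dip_peak_day``, linearly resolves by
    ``dip_recovery_day``."""
    up = np.clip(days / max(design.dip_peak_day, 1e-9), 0, 1)
    down = np.clip((design.dip_recovery_day - days)
                   / max(design.dip_recovery_day - design.dip_peak_day, 1e-9),
                   0, 1)
    return design.dip_depth * np.minimum(up, down)


def simulate_cohort(design: StudyDesign | None = None,
                    rng: np.random.Generator | None = None) -> CohortTable:
    """Simulate the two-group cohort with stated Gaussian noise and effects."""
    design = design or StudyDesign()
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    n = design.n_per_group
    groups = ["saline"] * n + ["treated"] * n
    animals = [f"{g[0]}{i + 1:02d}" for i, g in enumerate(groups)]

    # treadmill run times: baseline and 6 weeks, failure always observed
    rt_rows = []
    for animal, group in zip(animals, groups):
        base = max(rng.normal(design.run_time_mean, design.run_time_sd), 1.0)
        if group == "treated":
            follow = max(rng.normal(
                design.run_time_mean * (1 + design.run_time_effect),
                design.run_time_followup_sd), 1.0)
        else:
            follow = max(rng.normal(design.run_time_mean,
                                    design.run_time_sd), 1.0)
        rt_rows.append((animal, group, "baseline", base, 1))
        rt_rows.append((animal, group, "6wk", follow, 1))
    run_times = pd.DataFrame(
        rt_rows, columns=["animal", "group", "timepoint",
                          "run_time_min", "event"])

    # daily body weights
    days = np.arange(design.n_days + 1)
    dip = _dip_profile(days.astype(float), design)
    wt_rows = []
    for animal, group in zip(animals, groups):
        w0 = rng.normal(design.weight_mean, design.weight_between_sd)
        traj = w0 * np.ones_like(days, dtype=float)
        if group == "treated":
            traj = traj * (1.0 - dip)
        traj *= 1.0 + rng.normal(0, design.weight_within_cv, days.size)
        wt_rows.extend((animal, group, int(d), float(w))
                       for d, w in zip(days, traj))
    weights = pd.DataFrame(
        wt_rows, columns=["animal", "group", "day", "weight_g"])

    # assay endpoints at 6 weeks
    ep_rows = []
    for animal, group in zip(animals, groups):
        for name, spec in design.endpoints.items():
            mean = spec.control_mean
            if group == "treated":
                mean = (mean + spec.effect if spec.additive
                        else mean * (1 + spec.effect))
            ep_rows.append((animal, group, "6wk", name,
                            float(rng.normal(mean, spec.sd))))
    endpoints = pd.DataFrame(
        ep_rows, columns=["animal", "group", "timepoint", "measure", "value"])
    return CohortTable(run_times, weights, endpoints)


# ---------------------------------------------------------------------------
# Respirometry and ddPCR
# ---------------------------------------------------------------------------

RESPIROMETRY_SEQUENCE = (
    ("state4", "GMP"),            # glutamate + pyruvate + malate present
    ("state3_CI", "ADP"),
    ("cytc", "cytochrome_c"),
    ("state3_CI_CII", "succinate"),
    ("fccp", "FCCP"),
)


def simulate_respirometry(fluxes: dict[str, float],
                          fiber_mass: float = 2.0,
                          chamber_volume_ml: float = 2.0,
                          o2_start: float = 220.0,
                          segment_duration: float = 180.0,
                          sample_interval: float = 2.0,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> RespirometryTrace:
    """Piecewise-linear closed-chamber O2 trace.

    ``fluxes`` maps state name (state4, state3_CI, cytc, state3_CI_CII,
    fccp) to O2 flux in pmol s^-1 mg^-1; each state occupies one segment
    of ``segment_duration`` seconds, entered at the corresponding
    substrate/uncoupler addition.  The chamber O2 slope of a state is
    -flux * fiber_mass / (volume * 1000) nmol mL^-1 s^-1.
    """
    rng = np.random.default_rng(seed)
    states = [s for s, _ in RESPIROMETRY_SEQUENCE if s in fluxes]
    if not states:
        raise ValueError("no recognised states in fluxes")
    n_seg = len(states)
    total = n_seg * segment_duration
    time = np.arange(0.0, total + sample_interval / 2, sample_interval)
    o2 = np.empty_like(time)
    level = o2_start
    events = []
    labels = dict(RESPIROMETRY_SEQUENCE)
    for j, state in enumerate(states):
        t0 = j * segment_duration
        if j > 0:
            events.append((t0, labels[state]))
        slope = -fluxes[state] * fiber_mass / (chamber_volume_ml * 1000.0)
        mask = (time >= t0) & (time <= t0 + segment_duration + 1e-9)
        o2[mask] = level + slope * (time[mask] - t0)
        level = level + slope * segment_duration
    if noise_sd > 0:
        o2 = o2 + rng.normal(0, noise_sd, o2.shape)
    return RespirometryTrace(time, o2, events, fiber_mass, chamber_volume_ml)


def simulate_droplets(lambda_target: float | dict[str, float],
                      n_droplets: int,
                      seed: int = 0,
                      droplet_volume_nl: float = 0.85) -> DropletCounts:
    """Binomial droplet counts: positives ~ Bin(n, 1 - exp(-lambda))."""
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    lam = (lambda_target if isinstance(lambda_target, dict)
           else {"target": float(lambda_target)})
    rng = np.random.default_rng(seed)
    positives = {}
    for channel, value in lam.items():
        if value < 0:
            raise ValueError(f"lambda for {channel!r} must be >= 0")
        p = 1.0 - np.exp(-value)
        positives[channel] = int(rng.binomial(n_droplets, p))
    return DropletCounts(n_droplets, positives, droplet_volume_nl)
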