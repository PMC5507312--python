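"""Core containers shared across the spectroscopy and assay modules.

Conventions
-----------
* Chemical shift is in ppm with phosphocreatine (PCr) referenced to 0 ppm;
  the ppm axis of a stored spectrum is strictly increasing.
* Concentrations are mM unless a field name says otherwise; fluxes are
  mM min^-1; time is seconds from the start of the acquisition.
* Protocol phases are labelled ``rest``, ``ischemia``, ``recovery``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PHASES = ("rest", "ischemia", "recovery")

# pH calibration of the Pi-PCr chemical-shift difference (configurable
# literature-standard defaults; see mrs.compute_ph).
PH_PKA = 6.77
PH_DELTA_ACID = 3.23  # ppm, fully protonated H2PO4- limit
PH_DELTA_BASE = 5.70  # ppm, fully deprotonated HPO4^2- limit

# Creatine-kinase / adenylate-kinase equilibrium constants at 0.6 mM Mg2+
# (literature-standard defaults, configurable).
K_CK = 1.66e9  # M^-1
K_AK = 1.05    # dimensionless

# Nominal 31P chemical shifts relative to PCr = 0 ppm.  Pi moves with pH;
# the value below is its position at the pKa midpoint.
PEAK_CENTERS_PPM = {
    "pi": 0.5 * (PH_DELTA_ACID + PH_DELTA_BASE),
    "pcr": 0.0,
    "gatp": -2.48,
    "aatp": -7.52,
    "batp": -16.26,
}

# Integration / fitting windows (ppm) around each peak; non-overlapping and
# wide enough to cover the pH-driven Pi excursion.
DEFAULT_WINDOWS = {
    "pi": (3.6, 5.9),
    "pcr": (-0.7, 0.7),
    "gatp": (-3.2, -1.8),
    "aatp": (-8.2, -6.8),
    "batp": (-17.0, -15.6),
}

PEAK_NAMES = tuple(DEFAULT_WINDOWS)


def _require_positive(value: float, name: str) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-acquire parameters of a 31P acquisition.

    Defaults correspond to the fully relaxed reference acquisition
    (long interpulse delay so areas are unbiased by T1 saturation).
    """

    n_points: int = 4096
    sweep_width: float = 10_000.0   # Hz
    transients: int = 32
    flip_angle: float = 90.0        # degrees
    interpulse_delay: float = 25.0  # s
    line_broadening: float = 0.0    # Hz, exponential apodization
    spectrometer_freq: float = 242.9  # MHz (31P at 14 T)

    def __post_init__(self) -> None:
        _require_positive(self.sweep_width, "sweep_width")
        _require_positive(self.spectrometer_freq, "spectrometer_freq")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.n_points & (self.n_points - 1):
            warnings.warn("n_points is not a power of two; FFT is slower",
                          stacklevel=2)

    @classmethod
    def fully_relaxed(cls, **kw) -> "AcquisitionParams":
        return cls(**kw)

    @classmethod
    def dynamic(cls, **kw) -> "AcquisitionParams":
        """45 degree flip, 4 transients, 1.5 s delay (one spectrum / 6 s)."""
        defaults = dict(transients=4, flip_angle=45.0, interpulse_delay=1.5)
        defaults.update(kw)
        return cls(**defaults)

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.sweep_width

    @property
    def spectrum_duration(self) -> float:
        """Wall-clock seconds consumed by one (multi-transient) spectrum."""
        return self.transients * self.interpulse_delay

    def ppm_axis(self) -> np.ndarray:
        freq = np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_time))
        return freq / self.spectrometer_freq


@dataclass
class Spectrum:
    """A frequency-domain 31P spectrum on an increasing ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray            # complex
    params: AcquisitionParams
    phase_label: str | None = None   # protocol phase
    time: float = 0.0                # s from acquisition start
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=complex)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have the same shape")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")

    @property
    def real(self) -> np.ndarray:
        return self.intensity.real

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), self.params,
                        self.phase_label, self.time, list(self.flags))


@dataclass
class DynamicAcquisition:
    """A time series of spectra sharing one ppm axis and acquisition."""

    ppm: np.ndarray
    spectra: np.ndarray              # (n_frames, n_points) complex
    times: np.ndarray                # s, frame mid-times
    phase_labels: list[str]
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=complex)
        self.times = np.asarray(self.times, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (frames x points)")
        if len(self.times) != self.spectra.shape[0]:
            raise ValueError("times must match the number of frames")
        if len(self.phase_labels) != self.spectra.shape[0]:
            raise ValueError("phase_labels must match the number of frames")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def frame(self, i: int) -> Spectrum:
        return Spectrum(self.ppm, self.spectra[i], self.params,
                        self.phase_labels[i], float(self.times[i]))


@dataclass(frozen=True)
class ProtocolSpec:
    """Rest / ischemia / recovery timing of the dynamic experiment."""

    rest_duration: float = 120.0      # s
    ischemia_duration: float = 660.0  # s
    recovery_duration: float = 420.0  # s
    dynamic_interval: float = 6.0     # s per dynamic 31P spectrum

    def __post_init__(self) -> None:
        for name in ("rest_duration", "ischemia_duration",
                     "recovery_duration", "dynamic_interval"):
            _require_positive(getattr(self, name), name)

    @property
    def ischemia_start(self) -> float:
        return self.rest_duration

    @property
    def recovery_start(self) -> float:
        return self.rest_duration + self.ischemia_duration

    @property
    def total_duration(self) -> float:
        return self.recovery_start + self.recovery_duration

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (self.ischemia_start, self.recovery_start, self.total_duration)

    def phase_of(self, t: float | np.ndarray):
        """Phase label(s) for time(s) ``t`` in seconds."""
        t = np.asarray(t, dtype=float)
        labels = np.where(
            t < self.ischemia_start, "rest",
            np.where(t < self.recovery_start, "ischemia", "recovery"))
        return labels if labels.ndim else str(labels)

    def frame_times(self, interval: float | None = None) -> np.ndarray:
        """Mid-times of consecutive frames covering the whole protocol."""
        dt = interval if interval is not None else self.dynamic_interval
        n = int(np.floor(self.total_duration / dt))
        return (np.arange(n) + 0.5) * dt


@dataclass
class OpticalSeries:
    """Wavelength-indexed absorbance frames over time."""

    wavelength: np.ndarray           # nm, increasing
    frames: np.ndarray               # (n_times, n_wavelengths)
    times: np.ndarray                # s
    phase_labels: list[str]

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.frames.shape != (len(self.times), len(self.wavelength)):
            raise ValueError("frames must be (n_times, n_wavelengths)")


@dataclass(frozen=True)
class ReferenceLibrary:
    """Per-mM absorptivity spectra of the four pigment species."""

    wavelength: np.ndarray
    oxy_hb: np.ndarray
    deoxy_hb: np.ndarray
    oxy_mb: np.ndarray
    deoxy_mb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        for name in ("oxy_hb", "deoxy_hb", "oxy_mb", "deoxy_mb"):
            if np.asarray(getattr(self, name)).shape != wl.shape:
                raise ValueError(f"{name} must share the wavelength grid")


@dataclass
class SaturationSeries:
    """Inferred Hb and Mb O2 saturations with per-frame diagnostics."""

    times: np.ndarray
    s_hb: np.ndarray                 # fraction in [0, 1]
    s_mb: np.ndarray
    residual: np.ndarray             # relative spectral reconstruction residual
    clipped: np.ndarray              # bool, prediction left [0, 1]
    flagged: np.ndarray              # bool, frame unusable (e.g. no signal)
    phase_labels: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PigmentConcentrations:
    """Tissue pigment content; hemoglobin expressed per O2-binding site."""

    hb_sites: float = 1.2  # mM O2-binding sites (4 per tetramer)
    mb: float = 0.4        # mM

    def __post_init__(self) -> None:
        if self.hb_sites < 0 or self.mb < 0:
            raise ValueError("pigment concentrations must be >= 0")


@dataclass
class PeakQuantification:
    """Peak areas/centers from a fully relaxed spectrum, plus ratios."""

    areas: dict[str, float]
    centers: dict[str, float]
    pi_over_atp: float
    pcr_over_atp: float
    flags: list[str] = field(default_factory=list)


@dataclass
class FluxResult:
    """Resting and maximal fluxes from one ischemia-recovery experiment."""

    atpase_rest: float               # mM ATP min^-1
    o2_rest: float                   # mM O2 min^-1
    atpmax: float                    # mM ATP min^-1
    k_recovery: float                # min^-1
    po_ratio: float                  # ATP per O atom
    pcr_rest: float                  # mM
    diagnostics: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class RespirometryTrace:
    """Closed-chamber O2 trace with substrate-addition annotations."""

    time: np.ndarray                 # s
    o2: np.ndarray                   # nmol mL^-1
    events: list[tuple[float, str]]  # (time s, label), ordered
    fiber_mass: float                # mg wet
    chamber_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.time.shape != self.o2.shape:
            raise ValueError("time and o2 must have the same shape")
        _require_positive(self.fiber_mass, "fiber_mass")
        _require_positive(self.chamber_volume_ml, "chamber_volume_ml")
        t0, t1 = self.time[0], self.time[-1]
        for et, label in self.events:
            if not (t0 <= et <= t1):
                raise ValueError(f"event {label!r} at {et} s outside trace")
        if any(self.events[i][0] >= self.events[i + 1][0]
               for i in range(len(self.events) - 1)):
            raise ValueError("events must be strictly ordered in time")


@dataclass(frozen=True)
class DropletCounts:
    """ddPCR droplet totals and per-channel positives."""

    n_total: int
    n_positive: dict[str, int]
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        _require_positive(self.droplet_volume_nl, "droplet_volume_nl")
        for channel, k in self.n_positive.items():
            if not 0 <= k <= self.n_total:
                raise ValueError(
                    f"channel {channel!r}: positives {k} outside [0, n_total]")


__all__ = [name for name in dir() if not name.startswith("_")]
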