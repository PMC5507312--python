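"""Plain-text readers and writers for every artefact of the pipeline.

All formats are CSV/JSON so fixtures diff cleanly: spectra as
(ppm, real, imag) CSV with a JSON acquisition sidecar, dynamic series as a
directory of frame CSVs with an index manifest, optical series as a wide
CSV plus a times sidecar, cohort tables as tidy CSVs, fluxes and reports
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (AcquisitionParams, DynamicAcquisition, OpticalSeries,
                        Spectrum)
from .synthetic import CohortTable

__all__ = [
    "write_spectrum", "read_spectrum", "write_dynamic", "read_dynamic",
    "write_optical", "read_optical", "write_cohort", "read_cohort",
    "write_json", "read_json", "validate_inputs",
]


def _acq_to_dict(params: AcquisitionParams) -> dict:
    return {
        "n_points": params.n_points, "sweep_width_Hz": params.sweep_width,
        "transients": params.transients, "flip_angle_deg": params.flip_angle,
        "interpulse_delay_s": params.interpulse_delay,
        "line_broadening_Hz": params.line_broadening,
        "spectrometer_freq_MHz": params.spectrometer_freq,
        "units": {"axis": "ppm", "time": "s"},
    }


def _acq_from_dict(d: dict) -> AcquisitionParams:
    return AcquisitionParams(
        n_points=d["n_points"], sweep_width=d["sweep_width_Hz"],
        transients=d["transients"], flip_angle=d["flip_angle_deg"],
        interpulse_delay=d["interpulse_delay_s"],
        line_broadening=d.get("line_broadening_Hz", 0.0),
        spectrometer_freq=d["spectrometer_freq_MHz"])


def write_spectrum(spec: Spectrum, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"ppm": spec.ppm, "real": spec.intensity.real,
                  "imag": spec.intensity.imag}).to_csv(csv_path, index=False)
    meta = _acq_to_dict(spec.params)
    meta.update({"phase_label": spec.phase_label, "time_s": spec.time,
                 "flags": spec.flags})
    write_json(meta, csv_path.with_suffix(".json"))


def read_spectrum(csv_path: str | Path) -> Spectrum:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = read_json(csv_path.with_suffix(".json"))
    return Spectrum(df["ppm"].to_numpy(),
                    df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
                    _acq_from_dict(meta), meta.get("phase_label"),
                    meta.get("time_s", 0.0), list(meta.get("flags", [])))


def write_dynamic(acq: DynamicAcquisition, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for i in range(len(acq)):
        name = f"frame_{i:04d}.csv"
        pd.DataFrame({"ppm": acq.ppm, "real": acq.spectra[i].real,
                      "imag": acq.spectra[i].imag}
                     ).to_csv(out_dir / name, index=False)
        frames.append({"file": name, "time_s": float(acq.times[i]),
                       "phase": acq.phase_labels[i]})
    write_json({"acquisition": _acq_to_dict(acq.params), "frames": frames},
               out_dir / "manifest.json")


def read_dynamic(in_dir: str | Path) -> DynamicAcquisition:
    in_dir = Path(in_dir)
    manifest = read_json(in_dir / "manifest.json")
    params = _acq_from_dict(manifest["acquisition"])
    spectra, times, labels, ppm = [], [], [], None
    for entry in manifest["frames"]:
        df = pd.read_csv(in_dir / entry["file"])
        ppm = df["ppm"].to_numpy()
        spectra.append(df["real"].to_numpy() + 1j * df["imag"].to_numpy())
        times.append(entry["time_s"])
        labels.append(entry["phase"])
    return DynamicAcquisition(ppm, np.array(spectra), np.array(times),
                              labels, params)


def write_optical(series: OpticalSeries, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    data = {"wavelength_nm": series.wavelength}
    for i in range(len(series.times)):
        data[f"t{i:04d}"] = series.frames[i]
    pd.DataFrame(data).to_csv(csv_path, index=False)
    write_json({"times_s": [float(t) for t in series.times],
                "phases": list(series.phase_labels),
                "units": {"wavelength": "nm", "absorbance": "AU"}},
               csv_path.with_suffix(".json"))


def read_optical(csv_path: str | Path) -> OpticalSeries:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = read_json(csv_path.with_suffix(".json"))
    wl = df["wavelength_nm"].to_numpy()
    frames = df.drop(columns=["wavelength_nm"]).to_numpy().T
    return OpticalSeries(wl, frames, np.array(meta["times_s"]),
                         list(meta["phases"]))


def write_cohort(table: CohortTable, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.run_times.to_csv(out_dir / "run_times.csv", index=False)
    table.weights.to_csv(out_dir / "weights.csv", index=False)
    table.endpoints.to_csv(out_dir / "endpoints.csv", index=False)


def read_cohort(in_dir: str | Path) -> CohortTable:
    in_dir = Path(in_dir)
    return CohortTable(
        pd.read_csv(in_dir / "run_times.csv"),
        pd.read_csv(in_dir / "weights.csv"),
        pd.read_csv(in_dir / "endpoints.csv"))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(path: str | Path) -> list[dict]:
    """Schema checks for a file or directory of pipeline inputs.

    Returns an itemized list of violations ({"file", "level", "message"});
    an empty list means everything checked out.  Unknown file types are
    reported as warnings, not errors.
    """
    path = Path(path)
    violations: list[dict] = []
    targets = sorted(path.rglob("*.csv")) if path.is_dir() else [path]
    for f in targets:
        try:
            _validate_one(f, violations)
        except Exception as exc:  # malformed files are violations, not crashes
            violations.append({"file": str(f), "level": "error",
                               "message": f"unreadable: {exc}"})
    return violations


def _validate_one(f: Path, violations: list[dict]) -> None:
    df = pd.read_csv(f)
    cols = set(df.columns)

    def err(msg, level="error"):
        violations.append({"file": str(f), "level": level, "message": msg})

    if {"ppm", "real", "imag"} <= cols:
        if not np.all(np.diff(df["ppm"]) > 0):
            err("ppm axis not strictly increasing")
        sidecar = f.with_suffix(".json")
        if f.name != "manifest.json" and not sidecar.exists():
            if not (f.parent / "manifest.json").exists():
                err("missing acquisition metadata sidecar", "warning")
        elif sidecar.exists():
            meta = read_json(sidecar)
            if "units" not in meta:
                err("metadata missing units field", "warning")
    elif "wavelength_nm" in cols:
        if not np.all(np.diff(df["wavelength_nm"]) > 0):
            err("wavelength grid not strictly increasing")
        if not f.with_suffix(".json").exists():
            err("missing optical times sidecar", "warning")
    elif {"time", "o2"} <= cols or {"time_s", "o2_nmol_ml"} <= cols:
        tcol = "time" if "time" in cols else "time_s"
        if not np.all(np.diff(df[tcol]) > 0):
            err("respirometry time not strictly increasing")
    elif {"animal", "group"} <= cols:
        if df["group"].nunique() < 2:
            err("cohort table has fewer than two groups", "warning")
        if df.isna().any().any():
            err("cohort table contains missing values", "warning")
    else:
        err(f"unrecognized schema: columns {sorted(cols)}", "warning")
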