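"""Simulate the full study's raw inputs with known ground truth.

Generates, under results/simulated/: the two-group cohort table (weights,
treadmill run times, assay endpoints), one animal's fully relaxed 31P
standard and dynamic ischemia-recovery series, its optical absorbance
series, a respirometry trace, and ddPCR droplet counts.  Downstream
scripts consume these files unchanged.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from myoenergetics import io
from myoenergetics.synthetic import (StudyDesign, TruthParams,
                                     simulate_cohort,
                                     simulate_dynamic_timecourse,
                                     simulate_droplets, simulate_fully_relaxed,
                                     simulate_optical_timecourse,
                                     simulate_respirometry)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path,
                    default=Path("results") / "simulated")
args = parser.parse_args()
out = args.out
out.mkdir(parents=True, exist_ok=True)

truth = TruthParams(seed=args.seed)
(out / "truth.json").write_text(json.dumps({
    "pcr_rest_mM": truth.pcr_rest, "pi_rest_mM": truth.pi_rest,
    "atp_mM": truth.atp, "total_creatine_mM": truth.total_creatine,
    "ph_rest": truth.ph_rest, "atpase_rest_mM_min": truth.atpase_rest,
    "k_recovery_per_min": truth.k_recovery,
    "atpmax_mM_min": truth.atpmax, "po_ratio": truth.po_ratio,
    "hb_sites_mM": truth.hb_sites, "mb_mM": truth.mb,
    "o2_consumption_mM_min": truth.o2_consumption}, indent=2))

io.write_spectrum(simulate_fully_relaxed(truth), out / "standard.csv")
io.write_dynamic(simulate_dynamic_timecourse(truth), out / "dynamic")
io.write_optical(simulate_optical_timecourse(truth), out / "optical.csv")
io.write_cohort(simulate_cohort(StudyDesign(seed=args.seed)), out / "cohort")

trace = simulate_respirometry({"state4": 10.0, "state3_CI": 40.0,
                               "cytc": 42.0, "state3_CI_CII": 80.0,
                               "fccp": 100.0}, noise_sd=0.1, seed=args.seed)
pd.DataFrame({"time": trace.time, "o2": trace.o2}).to_csv(
    out / "respirometry.csv", index=False)
io.write_json({"events": trace.events, "fiber_mass_mg": trace.fiber_mass,
               "chamber_volume_ml": trace.chamber_volume_ml},
              out / "respirometry.json")

droplets = simulate_droplets({"deletion": 0.003, "total_mtDNA": 1.5},
                             20_000, seed=args.seed)
io.write_json({"n_total": droplets.n_total,
               "n_positive": droplets.n_positive,
               "droplet_volume_nl": droplets.droplet_volume_nl},
              out / "droplets.json")

print(f"wrote simulated study inputs to {out}")
print(f"  ground-truth ATPmax = {truth.atpmax:.2f} mM/min, "
      f"P/O = {truth.po_ratio:.2f}")
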