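"""Orchestration: configuration, single-experiment quantification, and the
end-to-end study run (simulate -> quantify -> fluxes -> statistics).

``quantify_experiment`` runs the whole spectroscopy chain for one animal:
fully relaxed standard, dynamic 31P series, block summing, fit-to-standard,
concentration calibration, optical saturations, O2 content and fluxes.
``run_end_to_end`` simulates a two-group cohort, quantifies a subset of
animals through the spectroscopy chain, runs the companion assays and the
group statistics, and writes a deterministic report whose hash depends only
on the seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, bioenergetics, mrs, oximetry, stats, synthetic
from .datatypes import (AcquisitionParams, PigmentConcentrations,
                        ProtocolSpec)
from .io import write_json
from .synthetic import StudyDesign, TruthParams

__all__ = ["RunConfig", "quantify_experiment", "run_end_to_end",
           "config_hash", "report_hash"]

logger = logging.getLogger("myoenergetics")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end study run."""

    seed: int = 0
    n_mrs_per_group: int = 3        # animals per group through spectroscopy
    block: int = 3                  # dynamic spectra summed per block
    snr: float = 25.0               # dynamic PCr SNR
    treated_k_effect: float = -0.308   # fractional k_recovery change
    treated_pcr_effect: float = -0.10  # fractional resting PCr change
    animal_cv: float = 0.05         # between-animal truth variability
    welch: bool = True
    holm: bool = False              # family-wise Holm correction of endpoints
    design_seed_offset: int = 1000

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def report_hash(report: dict) -> str:
    payload = json.dumps(report, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def quantify_experiment(truth: TruthParams,
                        protocol: ProtocolSpec | None = None,
                        block: int = 3,
                        snr: float | None = None,
                        noiseless: bool = False,
                        sat_model: oximetry.SaturationModel | None = None,
                        rng: np.random.Generator | None = None) -> dict:
    """Full spectroscopy chain for one simulated animal.

    With ``noiseless=True`` the simulation runs without noise or scattering
    baselines, dynamic spectra are not block-summed, and the saturation
    model is trained on the deterministic baseline-free mixture grid (rank
    2, so 2 latent components); this is the exact-recovery configuration.
    Returns metabolites and O2-content frames, the flux result, and the
    ground truth for comparison.
    """
    protocol = protocol or ProtocolSpec()
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    conc = PigmentConcentrations(truth.hb_sites, truth.mb)
    refs = synthetic.default_reference_library()
    if noiseless:
        snr = np.inf
        block = 1

    standard = synthetic.simulate_fully_relaxed(
        truth, AcquisitionParams.fully_relaxed(),
        snr=np.inf if noiseless else None, rng=rng)
    dyn = synthetic.simulate_dynamic_timecourse(
        truth, protocol, snr=snr, rng=rng)
    summed = mrs.sum_dynamic(dyn, block)
    squant = mrs.integrate_relaxed(standard)
    fits = mrs.fit_to_standard(standard, summed)
    metabolites = mrs.calibrate_concentrations(
        fits, squant, atp_reference=truth.atp,
        total_creatine=truth.total_creatine)

    optical = synthetic.simulate_optical_timecourse(
        truth, protocol, refs, snr=snr,
        baseline_scale=0.0 if noiseless else 0.5, rng=rng)
    if sat_model is None:
        if noiseless:
            sat_model = oximetry.train_saturation_model(
                refs, conc, n_components=2, n_baseline_draws=0, noise_sd=0.0)
        else:
            sat_model = oximetry.train_saturation_model(refs, conc)
    sats = oximetry.predict_saturations(sat_model, optical)
    o2_content = oximetry.compute_o2_content(sats, conc)

    flux = bioenergetics.full_flux_analysis(metabolites, o2_content, protocol)
    return {"standard_quant": squant, "metabolites": metabolites,
            "saturations": sats, "o2_content": o2_content, "flux": flux,
            "truth": truth, "sat_model": sat_model}


def _comparison_dict(c: stats.GroupComparison) -> dict:
    return {"estimate": c.estimate, "p_value": c.p_value, "n": list(c.n),
            "method": c.method, "summaries": c.summaries, "flags": c.flags}


def _endpoint_stats(cohort: synthetic.CohortTable, welch: bool,
                    holm: bool = False) -> dict:
    out = {}
    for measure, sub in cohort.endpoints.groupby("measure"):
        a = sub[sub["group"] == "saline"]["value"].to_numpy()
        b = sub[sub["group"] == "treated"]["value"].to_numpy()
        entry = {"t_test": _comparison_dict(stats.unpaired_t(a, b, welch)),
                 "saline": stats.boxplot_summary(a),
                 "treated": stats.boxplot_summary(b)}
        pooled = np.concatenate([a, b])
        entry["grubbs_outlier_index"] = stats.grubbs_test(pooled)
        out[str(measure)] = entry
    if holm:
        names = sorted(out)
        adjusted = stats.holm_correction(
            [out[n]["t_test"]["p_value"] for n in names])
        for name, p_adj in zip(names, adjusted):
            out[name]["t_test"]["p_holm"] = float(p_adj)
    return out


def _cohort_statistics(cohort: synthetic.CohortTable, welch: bool,
                       holm: bool = False) -> dict:
    rt = cohort.run_times
    report: dict = {}
    for group in ("saline", "treated"):
        base = rt[(rt["group"] == group)
                  & (rt["timepoint"] == "baseline")]["run_time_min"]
        follow = rt[(rt["group"] == group)
                    & (rt["timepoint"] == "6wk")]["run_time_min"]
        lr = stats.logrank(base.to_numpy(), follow.to_numpy())
        frac = stats.fraction_change(base.to_numpy(), follow.to_numpy())
        report[f"run_time_{group}"] = {
            "logrank_baseline_vs_6wk": _comparison_dict(lr),
            "fraction_change": stats.boxplot_summary(frac),
        }
    base = rt[rt["timepoint"] == "baseline"].set_index("animal")
    follow = rt[rt["timepoint"] == "6wk"].set_index("animal")
    frac_all = stats.fraction_change(
        base["run_time_min"].to_numpy(), follow["run_time_min"].to_numpy())
    groups = base["group"].to_numpy()
    report["fraction_change_between_groups"] = _comparison_dict(
        stats.unpaired_t(frac_all[groups == "saline"],
                         frac_all[groups == "treated"], welch))
    wt = stats.weight_trajectory_model(cohort.weights)
    report["weight_model"] = {
        "interaction_F": wt["interaction_F"],
        "interaction_p": wt["interaction_p"],
        "n_per_group": wt["n_per_group"],
        "within_day_p": {d: c.p_value for d, c in wt["within_day"].items()},
    }
    report["endpoints"] = _endpoint_stats(cohort, welch, holm)
    return report


def _assay_demonstrations(seed: int) -> dict:
    """Deterministic companion-assay computations on simulated inputs."""
    fluxes_truth = {"state4": 10.0, "state3_CI": 40.0, "cytc": 42.0,
                    "state3_CI_CII": 80.0, "fccp": 100.0}
    trace = synthetic.simulate_respirometry(fluxes_truth, noise_sd=0.1,
                                            seed=seed + 11)
    state = assays.respirometry_states(trace)
    droplets = synthetic.simulate_droplets(
        {"deletion": 0.003, "total_mtDNA": 1.5}, n_droplets=20_000,
        seed=seed + 12)
    ddpcr = assays.ddpcr_frequency(droplets)
    t = np.linspace(0, 3, 31)
    cs = assays.citrate_synthase_activity(
        t, 0.2 + 0.136 * t, path_cm=1.0, dilution=10.0,
        tissue_mg_per_ml=50.0)
    return {
        "respirometry": {"fluxes": state.fluxes, "fcr": state.fcr,
                         "cytc_increase": state.cytc_increase,
                         "truth": fluxes_truth, "flags": state.flags},
        "ddpcr": ddpcr,
        "citrate_synthase_umol_min_g": cs,
        "densitometry_example": assays.densitometry_normalize(1.2, 0.8),
    }


def run_end_to_end(config: RunConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Simulate the study, quantify it, and assemble the report."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    handler = None
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(Path(out_dir) / "run.log", mode="w")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    logger.info("run_end_to_end seed=%d config_hash=%s", config.seed,
                config_hash(config))

    stage = "cohort"
    try:
        logger.info("stage=%s", stage)
        design = StudyDesign(seed=config.seed + config.design_seed_offset)
        cohort = synthetic.simulate_cohort(design)
        cohort_stats = _cohort_statistics(cohort, config.welch, config.holm)

        stage = "spectroscopy"
        logger.info("stage=%s n_per_group=%d", stage, config.n_mrs_per_group)
        if config.n_mrs_per_group < 1:
            raise ValueError("n_mrs_per_group must be >= 1")
        base_truth = TruthParams(seed=config.seed)
        refs = synthetic.default_reference_library()
        conc = PigmentConcentrations(base_truth.hb_sites, base_truth.mb)
        sat_model = oximetry.train_saturation_model(
            refs, conc, rng=np.random.default_rng(config.seed + 77))
        mrs_rows = []
        for g_idx, group in enumerate(("saline", "treated")):
            for i in range(config.n_mrs_per_group):
                jitter = 1.0 + config.animal_cv * rng.standard_normal(3)
                k = base_truth.k_recovery * jitter[0]
                atpase = base_truth.atpase_rest * jitter[1]
                pcr = base_truth.pcr_rest * jitter[2]
                if group == "treated":
                    k *= 1.0 + config.treated_k_effect
                    pcr *= 1.0 + config.treated_pcr_effect
                truth = dataclasses.replace(
                    base_truth, k_recovery=float(k),
                    atpase_rest=float(atpase),
                    pcr_rest=float(min(pcr, base_truth.total_creatine)),
                    snr=config.snr,
                    seed=config.seed + 100 * (g_idx + 1) + i)
                res = quantify_experiment(truth, block=config.block,
                                          sat_model=sat_model)
                flux = res["flux"]
                mrs_rows.append({
                    "animal": f"{group[0]}{i + 1:02d}", "group": group,
                    "truth_atpase": truth.atpase_rest,
                    "truth_o2": truth.o2_consumption,
                    "truth_k": truth.k_recovery,
                    "truth_atpmax": truth.atpmax,
                    "truth_po": truth.po_ratio,
                    "est_atpase": flux.atpase_rest,
                    "est_o2": flux.o2_rest,
                    "est_k": flux.k_recovery,
                    "est_atpmax": flux.atpmax,
                    "est_po": flux.po_ratio,
                })
        mrs_table = pd.DataFrame(mrs_rows)
        if config.n_mrs_per_group >= 2:
            atpmax_cmp = _comparison_dict(stats.unpaired_t(
                mrs_table[mrs_table["group"] == "saline"]["est_atpmax"],
                mrs_table[mrs_table["group"] == "treated"]["est_atpmax"],
                config.welch))
        else:
            atpmax_cmp = None  # a t test needs >= 2 animals per group

        stage = "assays"
        logger.info("stage=%s", stage)
        assay_report = _assay_demonstrations(config.seed)
    except Exception as exc:
        logger.error("stage=%s failed: %s", stage, exc)
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "cohort": cohort_stats,
        "mrs": {"per_animal": mrs_table.to_dict(orient="records"),
                "atpmax_group_t": atpmax_cmp},
        "assays": assay_report,
    }
    report["report_hash"] = report_hash(report)
    logger.info("report_hash=%s", report["report_hash"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_json(report, out_dir / "report.json")
        mrs_table.to_csv(out_dir / "flux_truth_vs_estimate.csv", index=False)
        from .io import write_cohort
        write_cohort(cohort, out_dir / "cohort")
    if handler is not None:
        logger.removeHandler(handler)
        handler.close()
    return report
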