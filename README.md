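# myoenergetics

In vivo skeletal-muscle bioenergetics from combined ³¹P magnetic-resonance
and optical spectroscopy through an ischemia–recovery protocol, with the
companion wet-lab assay computations and the cohort-level statistics of a
two-group (saline vs. treated) mouse study — all driven by a synthetic-data
generator with known ground truth.

## Who this is for

Researchers quantifying muscle mitochondrial function in vivo: the package
turns raw dynamic ³¹P spectra and optical absorbance series acquired over
rest (2 min), ischemia (11 min) and recovery (7 min) into metabolite
concentrations, pH, free ADP, O₂ saturations and the four headline fluxes,
and runs the group statistics a chemotherapy-late-effects (or aging,
exercise, …) study needs. Because no raw spectra of this kind are public,
the package ships a first-class simulator that emulates the whole
acquisition with known truth, so every estimator is validated by parameter
recovery.

## The science in brief

* **³¹P-MRS.** Peak areas of a fully relaxed spectrum (32 transients, 25 s
  interpulse delay) give resting Pi/ATP and PCr/ATP; dynamic spectra
  (45° flip, 1.5 s delay, summed in blocks of 3) are quantified by
  fit-to-standard: each frame is fit as scaled, shift-adjusted peak
  templates extracted from the standard. The HPLC ATP concentration is the
  internal reference for absolute mM. pH comes from the Pi–PCr chemical
  shift, pH = pKₐ + log₁₀((δ−δ_HA)/(δ_A−δ)) with pKₐ = 6.77, δ_HA = 3.23,
  δ_A = 5.70 ppm; free ADP from creatine-kinase equilibrium,
  [ADP] = [ATP][Cr]/([PCr][H⁺]·K_CK), K_CK = 1.66×10⁹ M⁻¹ at 0.6 mM Mg²⁺.
* **Optical oximetry.** Second derivatives of absorbance spectra (to kill
  scattering baselines) are mapped to Hb and Mb O₂ saturations by a partial
  least squares model trained on synthetic reference mixtures; bound O₂
  content is S_Hb·[Hb sites] + S_Mb·[Mb].
* **Fluxes.** Resting ATPase = −d[PCr]/dt and resting O₂ consumption =
  −d[O₂]/dt during early ischemia (least-squares slopes); ATPmax = k·PCr_rest
  from the monoexponential PCr recovery constant k; P/O = ATPase/(2·O₂ flux)
  per oxygen atom.
* **Assays.** Respirometry state fluxes and flux control ratios (state /
  FCCP-uncoupled) with the cytochrome-c membrane-integrity check; citrate
  synthase activity from the 412 nm DTNB slope (ε = 13.6 mM⁻¹cm⁻¹);
  densitometry normalization to actin; ddPCR copies per droplet
  λ = −ln(1−positive fraction) and mutation frequency λ_del/λ_total.
* **Statistics.** Welch t tests, Mantel–Cox log-rank on treadmill
  time-to-exhaustion (exact permutation p for ≤8 per arm), a split-plot
  repeated-measures model for percent body-weight change, box-plot
  summaries, and a Grubbs outlier test.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (from the repository root):

```bash
python analysis/01_simulate_study.py --seed 0
python analysis/02_quantify_mrs.py
python analysis/03_oximetry.py
python analysis/04_fluxes.py
python analysis/05_assays.py
python analysis/06_group_stats.py
```

Representative output of `04_fluxes.py` for seed 0 (single noisy animal at
the default SNR of 25 per dynamic spectrum):

```
  ATPase (mM/min): estimate 1.157 vs truth 1.200 (-3.6%)
  O2 flux (mM/min): estimate 0.250 vs truth 0.250 (-0.0%)
  k (1/min): estimate 0.619 vs truth 0.700 (-11.6%)
  ATPmax (mM/min): estimate 19.590 vs truth 22.400 (-12.5%)
  P/O: estimate 2.314 vs truth 2.400 (-3.6%)
```

i.e. the pipeline recovers the resting O₂ consumption almost exactly, the
PCr-derived fluxes within single-animal noise (across 100 replicates the
mean absolute errors are 4–6%; noiselessly all five fluxes are exact to
at least six significant digits). `06_group_stats.py` prints the group
comparisons, e.g. the treated group's log-rank p for baseline vs. 6-week
run times and the group-by-day interaction p for body weight.

The same pipeline is available as a CLI (`myoenergetics simulate|
quantify-mrs|oximetry|energetics|assays|stats|run-all`) and as a library
(`myoenergetics.pipeline.quantify_experiment`, `run_end_to_end`).

## Layout

```
src/myoenergetics/   library: synthetic, mrs, oximetry, bioenergetics,
                     assays, stats, io, pipeline, cli
analysis/            numbered study drivers (thin, narrative)
scripts/             acceptance recomputation
tests/               pytest suite incl. acceptance properties
docs/methods.md      models, parameters, defaults, limitations
```
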