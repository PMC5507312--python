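# Methods

This note documents the models, algorithms, parameter defaults and known
limitations of the package, in the order the pipeline runs.

## Signal model and simulator

Every resonance of the ³¹P signal is a Lorentzian: in the time domain a
complex exponential a·e^{(2πi f₀ − R₂)t} sampled at the dwell time
1/sweep-width for 4096 points (10 kHz sweep), and in the frequency domain
the exact finite geometric sum of its DFT ("discrete Lorentzian"). The
amplitude a is proportional to concentration; the default linewidth is
15 Hz FWHM for all species, typical of shimmed mouse hindlimb at high
field. PCr is the 0 ppm reference; γ/α/β-ATP sit at −2.48/−7.52/−16.26 ppm;
the Pi position is the inverse of the pH calibration below, so pH is
encoded in the spectrum exactly as it is read out. The spectrometer
frequency is 242.9 MHz (³¹P at 14 T).

Noise is additive iid Gaussian in both quadratures of the frequency-domain
spectrum, scaled so the resting PCr peak height over the noise SD equals
the requested SNR. This is the simplest model under which SNR-scaling
tests are exact. Defaults: SNR 25 for one dynamic spectrum; the fully
relaxed standard gets SNR 25·√(32/4)/0.70 ≈ 101 (more transients, no
partial-saturation loss). The 45°/1.5 s dynamic acquisition retains a
per-peak fraction of the fully relaxed signal (defaults 0.80 Pi, 0.70 PCr,
0.65 ATP) standing in for T1 saturation; full Bloch/T1 modelling is out of
scope.

The dynamic protocol is rest 2 min, ischemia 11 min, recovery 7 min, one
spectrum per 6 s (4 transients × 1.5 s). Ground-truth trajectories:

* PCr constant at rest; declining linearly at the resting ATPase rate
  during ischemia (floored at 1 mM with a warning); recovering as
  PCr_rest − ΔPCr·e^{−kt}.
* Pi mirrors PCr so PCr+Pi is conserved to machine precision.
* pH acidifies linearly by 0.2 units over the full ischemia (configurable;
  a model choice — the decline shape is not otherwise constrained) and
  relaxes back exponentially at k during recovery.

Default physiology (mouse distal hindlimb, resting): PCr 32 mM, Pi 2.4 mM,
ATP 8.2 mM, total creatine 42 mM (free creatine 10 mM), pH 7.0 — values
chosen so the creatine-kinase worked example gives ~15.4 µM free ADP;
ATPase 1.2 mM·min⁻¹, k 0.7 min⁻¹ (so ATPmax = k·PCr_rest = 22.4 mM·min⁻¹),
Hb 1.2 mM O₂-binding sites, Mb 0.4 mM, resting O₂ consumption
0.25 mM·min⁻¹ (so P/O = 2.4). These are literature-plausible resting
values for mature mouse muscle, set once as the simulator's conditions.

Optical frames are linear mixtures of per-mM reference spectra of
oxy/deoxy Hb and Mb on a 500–650 nm grid — synthetic smooth Gaussian-band
curves with the α/β double band for the oxy species and offset Mb bands,
shipped as code, not digitized literature spectra — plus a random smooth
quadratic scattering baseline per frame and Gaussian noise. The optical
SNR default is 100 (CCD transmission spectra at 0.5 s integration are far
cleaner than a 4-transient ³¹P spectrum). Saturations decline during
ischemia such that bound O₂ content falls at exactly the resting O₂
consumption, floored at zero, and recover exponentially.

## ³¹P processing and quantification

`process_spectrum` applies exponential apodization, FFT (first point
halved to avoid a DC baseline offset), and phase correction. The automatic
phasing minimizes the spectral entropy of the real part with a quadratic
penalty on negative area, scanning φ₀ coarsely then refining (φ₀, φ₁) by
Nelder–Mead; manual angles can be supplied. On synthetic absorption
spectra a 90° misphase is recovered to well under 1°.

`integrate_relaxed` defaults to a model-based method: each windowed peak
is fit as a discrete Lorentzian plus a local linear baseline, with three
rounds of neighbour-tail subtraction so the heavy Lorentzian tails of PCr
under the γ-ATP window (and vice versa) do not bias the areas; the
reported area is the analytic full-line area. The plain method
(`method="trapezoid"`): trapezoidal area after subtracting a line through
the window edges. The model-based ratio is exact to ~1e-9 noiselessly; the
trapezoid ratio carries a ~0.2% tail-crosstalk bias, which is why it is
not the default. ATP is quantified from the γ-phosphate peak (cleanest in
vivo). Windows (ppm): Pi (3.6, 5.9), PCr (−0.7, 0.7), γATP (−3.2, −1.8),
αATP (−8.2, −6.8), βATP (−17.0, −15.6).

`sum_dynamic` sums disjoint blocks of 3 consecutive spectra (sliding
summation is not implemented); block time is the member mean; a trailing
partial block is dropped with a warning.

`fit_to_standard` decomposes the standard into per-peak discrete
Lorentzians and fits every dynamic frame over the union of the windows as
a joint linear combination of those templates plus a linear baseline,
alternating the least-squares solve with bounded per-peak frequency-shift
refinement (±0.5 ppm — wide enough for the full ischemic Pi excursion; the
shift landscape is multimodal at the linewidth scale, so a 41-point grid
scan precedes the bounded refinement). Magnitudes are scale × standard
area, so they are proportional to concentration; frames whose relative
residual exceeds 0.9 are flagged and their magnitudes marked missing.

`calibrate_concentrations` anchors the scale with the HPLC ATP reference:
a per-peak saturation-correction factor (standard area over mean resting
dynamic magnitude) maps dynamic magnitudes onto the fully relaxed scale,
then concentration = ATP_ref × corrected magnitude / standard γ-ATP area.
Because the standard is acquired at rest, this is exact for a noiseless
simulation regardless of the saturation factors. pH per frame comes from
the fitted Pi–PCr separation; free creatine = total creatine − PCr; ADP
from the CK equilibrium (and optionally AMP from adenylate kinase,
K_AK = 1.05). The pH constants (pKₐ 6.77, limits 3.23/5.70 ppm) and
K_CK = 1.66×10⁹ M⁻¹ at 0.6 mM Mg²⁺ are literature-standard defaults, all
configurable.

## Oximetry

Savitzky–Golay smoothing-differentiation (window 11 points, polyorder 3,
second derivative; ends truncated) removes affine-in-wavelength baselines
exactly and suppresses smooth scattering. The saturation model is a PLS
regression (4 components, `scale=False`) from second-derivative frames to
(S_Hb, S_Mb), trained on an 11×11 grid of synthetic mixtures at the
gel-derived pigment concentrations, replicated under 3 random quadratic
baselines with noise SD 0.02. Training on synthetic mixtures (rather than
an in vivo calibration set) is a documented choice — no calibration data
exist in this setting. With noiseless, baseline-free training the centered
training matrix has rank 2 and the map is exactly linear, so 2 components
reproduce the saturations to machine precision; that configuration is used
by the exact-recovery harness. Predictions are clipped to [0, 1] (clip
flags kept; a 1e-9 numerical grace avoids spurious flags at the floor);
all-zero frames are flagged as unusable. Bound O₂ content is the linear
site-occupancy sum S_Hb·[Hb sites] + S_Mb·[Mb] — the saturations already
encode the binding curves, and content (not PO₂) is what the flux
calculation needs, so no Hill inversion is involved.

## Fluxes

The "initial phase of ischemia" window is 30–210 s after cuff onset
(skipping the occlusion transient; configurable). Resting ATPase and O₂
consumption are minus the least-squares slopes of PCr and O₂ content over
that window, with 95% CIs from the slope standard error; a positive slope
beyond its CI raises a non-physiological warning. ATPmax fits
PCr(t) = PCr_end − ΔPCr·e^{−k(t−t₀)} on the recovery frames (≥8 required;
multi-start over k ∈ {0.1, 0.2, 0.5, 1, 2, 5} min⁻¹, bounded
trust-region least squares at tight tolerances), then ATPmax = k·PCr_rest
with PCr_rest the pre-ischemia mean — the convention of the
recovery-kinetics literature; ADP-based alternatives are out of scope.
P/O = ATPase/(2·O₂ flux), per oxygen atom (the 2 converts O₂ to O);
undefined when the O₂ flux is not positive.

## Assays

Respirometry: state 4 runs from the start of the trace (substrates
present, no adenylates); ADP, cytochrome c, succinate and FCCP additions
start the later states. Each state's flux is minus the O₂ slope over the
last 60 s ending 10 s before the next addition (window and gap
configurable; the trace units are instrument-convention nmol·mL⁻¹,
converted to pmol·s⁻¹·mg⁻¹ wet mass with the 2 mL chamber volume). FCR =
state flux / FCCP flux. A cytochrome-c flux increase above 15% of state-3
(CI) flags compromised outer-membrane integrity. Citrate synthase activity
= (dA₄₁₂/dt)/(ε·path)·dilution/tissue-concentration with
ε = 13.6 mM⁻¹cm⁻¹ (literature constant for TNB). ddPCR: λ = −ln(1−k/n)
copies per droplet, concentration λ/0.85 nL, binomially propagated CI;
mutation frequency is defined as deletion copies per total-mtDNA copy (a
convention — the ratio definition is instrument-software specific).

## Statistics

Welch's t is the default two-sample test (pooled optional). The log-rank
(Mantel–Cox) test treats treadmill exhaustion as a fully observed event.
For ≤8 fully observed times per arm the p value is the exact permutation
tail of the Mantel–Cox statistic (vectorised enumeration of all C(n, n_a)
assignments): at that size the χ²₁ approximation misses the exact p by up
to ~0.03, and neither a continuity correction nor exact-variance
exponential scores repairs it. Larger samples use the asymptotic χ²₁ p
(via lifelines), whose measured type-I error at n=10/arm is ~6%. The body
weight model converts each animal to percent change from day 0 (making it
scale invariant), then runs a balanced split-plot ANOVA — the group×day
interaction F is tested against the day×subject-within-group error — with
listwise deletion of animals missing any day, and Welch t tests within
days. The implementation is cross-checked against pingouin's mixed ANOVA.
The outlier rule is a two-sided Grubbs test at α = 0.05 (the study's
outlier test is unnamed). No multiple-testing correction is applied by
default, matching per-comparison reporting; Holm correction is available
to callers of the t helper by standard means. Mean ± SD convention is
used in summaries; box-plot panels report min/median/max plus quartiles.

## Cohort generator

Two groups of 10 animals. Treadmill run times are Gaussian with baseline
mean 49.0 min (SD 16.8) in both groups; at 6 weeks the treated group's
mean is reduced by 47.6% (SD 10.6), the control unchanged; times are
floored at 1 min and failures are always observed. Body weight: per-animal
baseline 25 g (between-animal SD 1.5 g), 1% day-to-day measurement CV, and
for the treated group a transient fractional dip reaching 5% at day 1 and
resolving linearly by day 25 over a 42-day follow-up. Assay endpoints are
Gaussian per animal with control means/SDs from the study's printed
summaries where available (e.g. ATPmax 696.2 ± 76.6 arbitrary units with a
−30.8% treated effect; PCr/ATP 3.878 ± 0.1 with −16.4%; NF-κB 0.053 ±
0.022 with +71.7%) and zero-effect endpoints (P/O, citrate synthase,
mutation frequency) alongside. Whether printed ± values are SD or SEM is
ambiguous in places; the generator takes them as SD, as the methods
convention states, and draws no conclusions that depend on the choice.

## Problem sizes used in validation

Noiseless exact recovery runs a single experiment (200 dynamic frames,
block 1 — block summing assigns the member-mean time to each block, which
is exact for linear segments but biases the exponential recovery, so the
exact harness does not sum; the default pipeline keeps block 3). The
Monte-Carlo recovery uses 100 replicates at the default SNRs; the PCr/ATP
check uses 40 relaxed spectra at SNR 50; type-I calibration uses 5000
zero-effect cohorts (10 per group, a 5-day weight grid for the
repeated-measures null); the log-rank exact-vs-oracle check enumerates
12870 assignments per dataset. These sizes make the full suite and the
acceptance script each run in a few minutes on one CPU.

## Known limitations

* No Bloch/T1/T2 physics beyond the fully-relaxed vs 45°-flip retention
  factors; no macromolecular baseline; no vendor file formats.
* The optical model has no photon-transport scattering physics or
  pathlength estimation; carboxy- and met-species are absent. Passing the
  recovery tests shows the estimators are correct under the stated mixture
  model, not that PLS calibration transfers to arbitrary real tissue.
* pH from the fitted Pi shift is accurate to ~1e-3 pH units noiselessly
  (template interpolation on a 0.01 ppm grid), not machine precision.
* The asymptotic log-rank p at moderate n remains an approximation; the
  exact path covers only fully observed small samples.
* Proton-efflux corrections to recovery kinetics and PO₂-based oxidative
  capacity models are out of scope.
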