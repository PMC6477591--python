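# Methods

This note records the models, assumptions, parameter choices and
numerical decisions behind the package. Nothing here is an empirical
claim about real animals; every number is either a design parameter of
the synthetic generator or a property computed by the code.

## Study design model

Four arms: `control`, `lu` (radionuclide therapy), `lu_a1m`
(therapy + α1-microglobulin) and `a1m` (protein alone). Animals are
sacrificed at 6, 12 or 24 weeks; default group sizes are 9 per arm and
time point, with the deviations 7 (`lu`, 12 wk), 10 (`lu`, 24 wk) and
6/8/9 for controls at 6/12/24 wk. Imaging animals get 2 sections × (6
cortex + 3 medulla) = 18 subsections; cortex subsections 0–3 are tubular
and 4–5 glomerular.

Per-animal heterogeneity in the foci endpoint is a Gamma(shape = 16)
multiplier on the arm's nominal positive fraction (mean 1, CV 25%).
Nominal cortical fractions are 0.005 (control/a1m), 0.06 (`lu`) and
0.025 (`lu_a1m`).

All randomness flows from one master seed through
`numpy.random.SeedSequence([master, stage, arm, animal])`, where stage
tags are 1 = tiles, 2 = scores, 3 = biomarkers, 4 = survival. Derived
seeds therefore never repeat across stages or animals, and any script
seed below 2³¹ is valid.

## Image model and its limitations

Tiles are 512×512 at 0.5 µm/px: flat-disk nuclei (radius 6–9 px,
intensity 0.7) and flat-disk foci (radius 1.5–2.5 px, intensity 0.8,
optional multiplicative jitter), convolved with a Gaussian PSF
(σ = 1 px), plus Gaussian background (0.08 ± 0.02) and optional Poisson
shot noise (500 photons at unit intensity). Nuclei are placed with a
hard-core constraint (centre distance ≥ r₁ + r₂ + 2 px; after 10,000
failed attempts the generator raises rather than silently under-filling).
Foci are placed fully inside their nucleus and mutually separated by
≥ 2 px.

These gaps make the noise-free case exactly solvable: rasterised nuclei
are disjoint even under 8-connectivity, every focus lies within one
nucleus mask, and every planted focus (area ≥ 9 px) clears the 4-px
minimum area — so noise-free detection must reproduce the planted areas
and flags with zero mismatches, which the acceptance suite checks.

Known simplifications: no intensity gradients or vignetting, no
out-of-focus light, no touching/overlapping nuclei, no autofluorescence
texture, circular nuclei only. The segmentation therefore faces an
easier task than real tissue; the recovery tolerances (±3 percentage
points) should be read as validating the code path, not as an expected
field accuracy.

## Foci quantification

DAPI: fixed threshold 0.35 → binary fill → Euclidean distance transform
→ `peak_local_max` (min distance 7 px) → watershed → discard regions
< 20 px. γH2AX: threshold 0.40, 8-connected components within each
nucleus mask, keep components ≥ 4 px. A nucleus is positive with ≥ 1
qualifying focus (a total-area criterion is available as an alternative).
Subsections with fewer than 103 nuclei are rejected outright; the
percent-positive is 100·n_pos/n_nuclei and animals contribute unweighted
means over their valid subsections.

Threshold calibration minimises Σ|n_pos,auto − n_pos,manual| over a user
grid (after optionally tuning the nucleus threshold by |Δn_nuclei|);
ties resolve to the lower threshold. Calibration tiles need
heterogeneous focus intensities to be informative — with a single
planted intensity every threshold below it has zero loss, which is why
the generator exposes `focus_intensity_jitter`.

## Histopathology

Eight lesion types (cortical/medullary atrophy and fibrosis, glomerular,
cortical tubular, cortical inflammatory, collecting-duct findings),
ordinal grades 0–4, per-animal total 0–32. Grades are treated as ordinal
throughout: arm comparisons use Kruskal–Wallis with Dunn post hoc.
Glomerulus counts are modelled as Poisson and compared with ANOVA/Tukey.

## Group statistics

- **Restricted reporting.** Omnibus tests and the multiplicity
  adjustment use the full four-arm family; only the three pairs of
  interest are reported (control–irradiated, control–irradiated+protein,
  irradiated–irradiated+protein).
- **ROUT adaptation (one-sample).** Residuals from the median; robust
  scale RSDR = 68.27th percentile of |residuals| × n/(n−1); t-ratios with
  n−1 df; step-down testing from the most extreme residual with
  α_i = Q(n−rank)/n. This step-down (rather than a Benjamini–Hochberg
  step-up) is what gives the method its sensitivity to a single gross
  outlier: measured on 1,000 clean n = 10 Gaussian samples the false-flag
  rate is below 1%, and a +10 SD planted outlier is caught in more than
  99% of replicates.
- **Dunn post hoc** is implemented directly (tie-corrected pooled
  variance, Holm adjustment over the three reported pairs) because no
  dependency in the stack provides it.
- **Degenerate inputs** (zero variance everywhere) raise rather than
  return NaN; the replicated-study helper treats an all-identical
  endpoint as untestable and therefore non-significant.

## Survival

A closed vocabulary of necropsy findings drives classification: swollen
or pathological liver/kidney/spleen findings at death or unscheduled
termination mark a radiation-related death (event); weight loss, skin
lesions, swollen joints and general decline mark humane-endpoint
censorings; scheduled sacrifices are always censored. The Kaplan–Meier
estimator and the log-rank test are hand-implemented (events precede
censorings at tied times; hypergeometric variance; p from χ² with 1 df)
and cross-checked against `lifelines` and a permutation null in the
tests. Times are whole weeks.

## Dosimetry

`D = Ã·S` with Ã from trapezoid integration of the sampled
time–activity curve plus an analytic tail `A_last/λ_eff` when a
mono-exponential tail is declared. λ_eff = λ_phys + λ_bio with
t½(phys) = 6.73 d. The S-factor is an input (typically from Monte Carlo
on a mouse phantom), never computed here. Numerical note: trapezoid
error on a mono-exponential is ~(λh)²/12 per unit area, so matching the
closed form at 10⁻⁶ relative requires dense sampling (the tests use
5,000–6,000 points over ten effective half-lives); coarse sampling grids
carry ~10⁻⁴-level integration error and rely on the analytic tail for
the remainder.

## Pipeline

`run_study` executes foci → histopathology → biomarkers → survival →
dosimetry in fixed order, wraps any stage failure in a `StageError`
naming the stage, and returns ~17 tidy tables with provenance (seed,
package version, config hash) and a SHA-256 content hash. The imaging
stage can run in `render` mode (full image synthesis + quantification)
or `ground_truth` mode (planted counts only); both modes use the same
placement plan and seeds, so the planted counts are identical — the
fast mode is what makes 100-replicate cohort studies tractable.

## Limitations

- The generator's effect sizes and hazards are plausible but arbitrary;
  power statements in the tests refer to the synthetic model only.
- Biomarker distributions are Gaussian by construction; the
  nonparametric branch is exercised on ordinal and rank-preserving
  transforms, not on heavy-tailed data.
- The log-rank p-value uses the χ² approximation; at very small n it can
  deviate from the exact permutation null by a few hundredths (the
  tests bound this at 0.06).
- Image rendering is the computational bottleneck (~0.1 s per 512² tile);
  fully rendered cohorts take minutes, not seconds.
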