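# Methods

## Dose model

Voxel doses are made comparable across fractionation schedules with the
linear-quadratic biologically effective dose, `BED = D·(1 + d/(α/β))`, where
`d = D/N` is the per-voxel dose per fraction under an `N`-fraction schedule
and α/β (Gy) is the late-reacting-tissue sensitivity parameter (default
3 Gy, the conventional assumption for late rectal toxicity; the sensitivity
module re-runs everything at other values, 2 Gy by default alongside 3).
Overall-treatment-time differences between schedules are assumed not to
affect late rectal bleeding, so time factors are ignored.

The package operates on differential DVHs rather than voxel grids. Because
BED is strictly increasing in dose for fixed (N, α/β), transforming the bin
dose axis is exactly equivalent to voxelwise conversion followed by
re-histogramming; bin volumes are untouched and total volume is conserved
exactly (tested).

### DVH conventions and metric definitions

* Bins are point masses at strictly increasing representative doses;
  cumulative inputs are converted on read (`# dvh_kind:` metadata line in
  the CSV).
* `V_D`: inclusive rule — the summed volume of bins with dose ≥ D, as a
  percentage of total volume. No sub-bin interpolation: with point-mass
  bins the straddling bin either counts or does not.
* `D_xcm3`: linear interpolation of the cumulative absolute-volume curve
  between adjacent cumulative points; `x` above the hottest bin's cumulative
  volume returns the maximum bin dose, `x` equal to the organ volume the
  minimum; `x` beyond the organ volume is an error. The two metrics are
  mutually consistent within one bin's volume (property-tested).
* `gEUD(n) = (Σ v_i·D_i^{1/n})^n` with relative volumes `v_i`; evaluated in
  log space (log-sum-exp), so small volume exponents (large `1/n`) cannot
  overflow. `n = 1` is the mean dose; `n → 0` approaches the maximum dose.
* Internal math is at full precision; one-decimal values (e.g. the 111.9 Gy
  threshold label) are presentation rounding only.

### Prescription-BED crossover

Setting the prescription BEDs of two schedules equal gives
`α/β = (D_a·d_a − D_b·d_b)/(D_b − D_a)`; for 78 Gy/39 fx vs 64.6 Gy/19 fx
this is 4.7 Gy (one decimal). Equal total doses with unequal fraction sizes
have no positive solution (returned as `None`); identical schedules are an
error.

## Endpoint and eligibility

Grade ≥2 late rectal bleeding within a 60-month horizon is scored as a
logical OR of two sources: any case-report-form record of medication or
intervention for rectal bleeding, or patient-reported bleeding —
"moderate" at ≥2 *distinct* visits or "severe" at ≥1 visit (the distinct-
visit reading of the ≥2 rule is our choice; the four-level scale is
none/little/moderate/severe). Events after a clinical recurrence are
excluded, and a hemorrhoid-attribution flag (manual adjudication supplied
as input, never inferred) vetoes the event. Missing questionnaires are
non-informative. Eligibility mirrors a trial analysis set: ≥12 months
follow-up, no recurrence before month 12, at least one toxicity evaluation
after month 12, and an available DVH; exclusions are logged with reasons.

## Model development

Candidates are exactly one dose metric (five standard choices: V at the BED
of 70 Gy physical, gEUD n = 0.1 and 0.2, D_0.1cm3, D_2cm3) plus ABD_SURG
and HYPOTREAT. Logistic fits are Newton/IRLS maximum likelihood
(statsmodels, tolerance 1e-10, max 100 iterations); quasi-separation is
flagged when any standardized coefficient exceeds 20 and treated as
non-convergence. Backward elimination removes, at each step, the predictor
whose removal lowers AIC the most, stopping when no removal lowers AIC;
ties remove the later-listed candidate (order: dose metric, ABD_SURG,
HYPOTREAT), so the dose metric is maximally protected; non-converged
submodels score AIC = +∞. The accepted-step AIC sequence is non-increasing
by construction (tested).

Retention of HYPOTREAT after elimination is the schedule-independence
criterion: a retained indicator means the BED-based metric did not explain
the between-arm difference, and the metric is disqualified under that α/β.

### Shrinkage

The uniform shrinkage factor is the mean, over 300 bootstrap resamples, of
the calibration slope obtained by refitting the *full* procedure (selection
included — a configuration switch `reselect=False` refits the original
retained set instead) on the resample and regressing the original outcomes
on that model's linear predictor. Degenerate resamples (single outcome
class, non-convergence, intercept-only) are excluded and counted. Slopes
are multiplied by the factor (so OR_final = OR^s) and the intercept is
re-estimated by ML with the shrunk linear predictor as fixed offset, which
restores mean predicted probability = observed prevalence (tested to 1e-6).

## Validation

AUC uses the rank-based Mann–Whitney formulation (ties count ½); the Brier
score is the mean squared error on the 0/1 outcome. Calibration slope is
the coefficient of a free logistic fit of outcomes on logit(p̂); the
calibration intercept comes from the same regression with the slope fixed
at 1 (logit as offset). The integrated calibration index (ICI) is the mean
absolute gap between a loess calibration curve and the identity at each
predicted value; the loess is local-linear with tricube weights, span 0.75
by default (configurable and recorded in the report; the span is a design
choice — no standard value exists for calibration curves), no robustness
iterations, clipped to [0, 1]; constant predictions degenerate to the
outcome mean.

Optimism correction is Harrell's bootstrap: per resample, rerun the
modeling procedure, measure performance on the resample and on the original
data; corrected = apparent − mean(optimism) over usable resamples, with
intercept-only and non-converged resamples excluded and counted (an error
if they exceed half). The 95% CI is the percentile interval of the
per-resample corrected values, with ICI clipped at zero. `B = 0` reports
apparent values only. Quintile calibration tables/plots (mean predicted vs
observed with SD bars plus the loess curve) are optional artifacts.

A caveat established during development: for the four plug-in measures a
data-independent model has exactly zero expected optimism, but the ICI
re-estimates its smoother on every dataset, and a bootstrap resample (~63%
distinct points) yields a rougher curve, so even a fixed model shows a
small positive ICI optimism (~0.01 at n = 400, span 0.75). This is
smoother bias, not overfitting, and sets the resolution floor of
ICI comparisons.

## Synthetic cohorts

The generator emulates a two-arm randomized trial: arm assignment
Bernoulli(0.5) between 39 × 2 Gy and 19 × 3.4 Gy; prior abdominal surgery
Bernoulli(0.20); rectal volume log-normal (median 60 cm³, log-sd 0.3); the
relative cumulative DVH is 1 up to a knee at 35% of prescription, then a
logistic fall-off whose midpoint is set by a Beta(2, 4) per-patient
overlap parameter (midpoint 45–95% of prescription) and a uniform width
(4–12% of prescription), truncated at 1.05 × prescription, binned at
0.5 Gy. Outcomes are Bernoulli draws from a logistic truth on a BED metric
(default gEUD(n=0.1) at α/β = 3) with OR 1.08/Gy for dose and 1.88 for
surgery — the scale reported for EUD-based bleeding models — and the
intercept calibrated by root-finding so the expected prevalence is 14%.
Visits are synthesized so the endpoint scorer reproduces the drawn outcome
exactly: ~87% of events get a CRF intervention flag, ~13% are
questionnaire-only (one severe or two moderate reports), mirroring the
published split between scoring routes. Presets: `hypro-like` (n = 656),
`null`, `overfit` (n = 200, events-per-variable < 10), `low-alphabeta`
(truth at α/β = 1.5).

What the generator does *not* emulate: real 3D dose distributions (no
anatomical correlation between DVH shape and covariates), center effects,
visit non-compliance and missingness patterns, or an outcome process other
than the assumed logistic truth. Passing tests therefore demonstrate that
the pipeline recovers a known truth and that its machinery is correct —
not that any particular published coefficient generalizes.

## Problem sizes and numerical choices

Simulation-based tests use n = 5000 cohorts for coefficient recovery
(within 3 Monte-Carlo SEs) and 20 seeded replicates for the
schedule-elimination rate (a truly null indicator survives AIC elimination
with probability ≈ P(χ²₁ > 2) ≈ 0.157, so elimination in ≥80% of seeds is
the expected behavior, not a certainty of each seed). Optimism experiments
use 100–200 resamples; shrinkage consistency uses n = 40 000 with strong
effects. All randomness flows through a single seeded numpy Generator per
run; identical (preset, seed) reproduces cohort files, model JSON and
reports byte-for-byte. Sensitivity-grid cells derive their RNG from
(seed, α/β, metric), making cells reproducible in isolation and the grid
permutation-invariant.

## Known limitations

* DICOM dose/structure parsing is out of scope; inputs are DVH CSVs.
* Only uniform (not penalized or Firth) shrinkage is implemented.
* The α/β grid tests schedule-independence; it does not estimate α/β with
  a confidence interval.
* With a synthetic truth tied to one metric, *mismatched* metrics
  legitimately retain the schedule indicator once n is large — retention
  rates across a grid are therefore generator-relative, not universal.
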