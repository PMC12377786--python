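# Methods

## Problem setting

Electronic health records (EHRs) often carry diagnosis labels that disagree
with a laboratory-confirmed clinical registry. For gestational diabetes
(GDM) this discordance is asymmetric: a substantial miss rate on true cases
(labels absent from the EHR) against a small false-alarm rate on non-cases.
`gdmsim` implements a three-step study of what such label noise does to a
risk-prediction pipeline: (1) quantify agreement between the two label
sources, (2) compare models trained on the noisy versus the validated
labels, (3) sweep simulated class-conditional noise through the training and
test sets separately.

Because real maternity EHR extracts are private, all experiments run on a
synthetic cohort whose generator is a first-class, tested component.

## Synthetic cohort generator

Each record is one pregnancy with five clinical numerics (age, BMI, systolic
and diastolic blood pressure, parity), five categoricals (ethnicity with 8
levels, occupation skill level with 5, and binary family history of
diabetes, prior GDM, other endocrine problems), and enough standard-normal
"filler" columns to pad the design to 79 features — the width of a typical
booking-visit extract. Defaults (means, SDs, category frequencies) are the
published marginals of a validated antenatal cohort; category probabilities
are taken from the published subgroup counts normalised exactly rather than
from rounded percentages.

**Marginal fidelity by moment matching.** Numeric features are truncated
normals with physiological bounds (age ≥ 18 per eligibility, BMI in
[14, 60], pressures in plausible ranges). Naively truncating
N(mean, SD) biases the marginal — the BMI lower bound alone shifts the mean
by ≈ +0.15 — so the parent normal's location and scale are solved (2-D
root-finding on the truncated moments) such that the *truncated*
distribution has exactly the declared mean and SD. Parity (mean 0.9,
SD 1.1, non-negative integer) has coefficient of variation > 1, which no
truncated normal above zero can reach; it is drawn instead from a
moment-matched negative binomial, the natural over-dispersed count model.
Features are sampled independently; the generator's only dependence
structure is the outcome model below. This keeps the generator auditable but
means passing tests say nothing about feature-correlation effects in real
data.

**Latent outcome model.** The true risk is a logistic model: standardised
numerics and category indicators enter with a fixed log-odds preset
(largest weights on prior GDM ≈ 2.8, family history ≈ 1.0, BMI ≈ 0.9 per
SD, ethnicity contrasts up to 1.3; all filler weights zero). The intercept
is calibrated by bisection so the cohort-mean risk equals the target
prevalence (default 10.5%) to within 1e-4; with all coefficients zero this
reduces to logit(prevalence) exactly. Coefficient magnitudes were fixed
once, by simulation, so a logistic model refit on a fresh 30,000-record
cohort discriminates at held-out ROC AUC ≈ 0.81–0.83 — the regime of
published first-trimester GDM models — and are not a tuning surface.

**Year structure.** Records are spread uniformly over 2018–2022 by default.
Under-ascertainment episodes are modelled as a per-year multiplier on the
*label* probability (`P(label=1) = true_risk × multiplier`), not as a
feature shift: screening disruption suppresses diagnoses without changing
who is at risk. The 2020 preset uses multiplier 0.69, reproducing a
7.7%-vs-11.2% style dip (a ~31% relative reduction). `true_risk` always
remains the inverse-logit of the linear predictor.

## Label processes

Noise at random (NAR) flips an **exact count** per class:
`round(fn_rate × #positives)` positives to 0 and `round(fp_rate ×
#negatives)` negatives to 1 (round half away from zero), drawn uniformly
without replacement from the *original* classes, so no record flips twice
and the two passes commute. Exact counts rather than per-record Bernoulli
flips make downstream checks deterministic: the confusion matrix of
(observed vs truth) recovers the realized flip fractions exactly. The
defaults (FNR 14.3%, FPR 2.3%) are the discordance measured between the
motivating EHR and its registry.

The validated view (`val`) is defined only where truth and observed agree —
the records a chart-review validation retains. Grid cells derive their RNG
seed from `SeedSequence((base_seed, fn_index, fp_index))`, so any single
cell is reproducible in isolation.

## Agreement metrics

Confusion counts, TPR/FPR/TNR/FNR, composition shares, both prevalences,
accuracy, precision, recall, F1 and Cohen κ
(`κ = (p_o − p_e)/(1 − p_e)` with marginal chance agreement `p_e`) are
computed at full precision; rounding to presentation precision happens only
in the report writer. Any statistic with a zero denominator is reported as
an explicit `None` marker, never as silent NaN. Stratified reports emit one
row per year, a pooled row, and "All minus <year>" rows for excluded years
(a generic exclude-stratum option motivated by the 2020 disruption).

## Modeling pipeline

* **Split**: 70/30, stratified on the reference label (at ~10% prevalence an
  unstratified 30% split is noticeably noisy), with 2020 excluded by
  default. Test size is `round(test_fraction × n)`.
* **Preprocessing**: one-hot encoding with the first (lexicographically
  smallest) category dropped and z-scoring with train-set moments; unseen
  test categories encode as all zeros, zero-variance numerics transform
  to 0. Fitted state is train-only.
* **Model**: ridge-penalised logistic regression with pinned
  "library-default" hyperparameters (C = 1.0, tol = 1e-4, max 1000 lbfgs
  iterations), recorded in run metadata — "defaults" drift across library
  versions, pins do not. Convergence failures are recorded, not raised.
* **ROC AUC** is the Mann–Whitney statistic via midranks (ties credited
  0.5); **average precision** is the step-wise precision-recall sum over
  descending unique thresholds with ties grouped and no interpolation. Both
  are implemented definitionally and cross-checked in the test suite
  against brute-force enumeration (and scikit-learn) on small fuzz
  instances.
* **AUC confidence interval**: label-stratified percentile bootstrap, 2000
  resamples by default, seeded. A bootstrap is assumption-free and
  reproducible; DeLong would be a reasonable alternative.
* **Calibration**: probabilities are clipped to [1e-6, 1 − 1e-6] before the
  logit. The slope is the coefficient of an unpenalised logistic regression
  of outcomes on logit(p); the intercept comes from the intercept-only
  model with logit(p) as a fixed offset (calibration-in-the-large) — the
  standard recalibration convention for clinical prediction models.
  Reliability curves use 10 equal-frequency bins (stable counts under
  skewed risk), ties to the lower bin, empty bins omitted.
* **Three-arm experiment** (one shared split): train on observed labels /
  evaluate on the validated test subset; train on validated labels (train
  agreement rows only) / same evaluation; and the validated-trained model
  evaluated against observed labels on the full test set. The third arm is
  what isolates test-label noise. A k-fold CV utility is provided as a
  robustness check but is not a headline arm.

## Noise grids

Both arms share the same split and base seed, so their (0, 0) cells equal
the clean pipeline bit-for-bit. The train arm corrupts the validated
training labels per cell (10 × 10 default grid → 100 refits, preprocessing
refit per cell — inert, since labels never enter preprocessing, but
faithful to a per-cell pipeline) and always scores on the untouched clean
test set; it also records the metrics on the noisy training labels
themselves, since a heat map captioned "on the training set" can mean
either. The test arm fits once on clean labels and re-scores fixed
predictions against corrupted test labels. Cells whose corrupted labels
collapse to a single class are flagged undefined and skipped, not fatal.

**Analytic oracle.** For test-label noise the expected AUC has a closed
form: with prevalence π, the noisy positive class is a mixture of true
positives (weight π(1 − fn)) and flipped negatives ((1 − π)fp); writing
a = P(true positive | noisy positive) and b = P(true positive | noisy
negative),

    AUC_noisy = ab·½ + a(1−b)·AUC_clean + (1−a)b·(1−AUC_clean) + (1−a)(1−b)·½.

This is strictly decreasing in the FP rate for AUC_clean > ½ and explains
the marked AUC drop under FP noise at low prevalence (a collapses quickly).
The corresponding noisy prevalence π(1 − fn) + (1 − π)fp is exactly the AP
of a random ranker on the noisy labels, which is why AP *rises* again at
high FP noise: class-balance inflation lifts the floor above the clean AP —
a property of the metric, not of the model.

## Problem sizes and numerical choices

Tests and the acceptance script run the experiments at scales chosen to
make the statistical claims decidable while keeping a full run comfortably
under a coffee break: cohorts of 4,000–20,000 for pipeline tests, 30,000
for refit discrimination, 50,000 for calibration recovery, 100,000-point
simulations for the mixture-oracle checks, and the full 10 × 10 train grid
at 20,000 records. Statistical assertions use 3-sigma binomial or
Hanley–McNeil bands (4-sigma where many comparisons are simultaneous).
Intercept bisection brackets [−60, 60] with at most 200 steps; truncated-
normal moment matching requires residuals below 1e-6.

## Limitations

The generator emulates marginals, a known latent risk model, and
class-conditional noise — it does not emulate feature correlations, repeat
pregnancies per patient, longitudinal visit structure, missingness, or
feature-dependent (non-random) label errors. Real-data headline values
(e.g. a specific AUC or AP on a private cohort) are therefore mirrored
qualitatively, not reproduced. Only logistic regression ships; the
evaluation API accepts any scorer, but tree ensembles and boosting models
are out of scope.
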