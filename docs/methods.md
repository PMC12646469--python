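# Methods

This note records the models, numerical choices and open design decisions
behind `hivefit`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Cohort schema and binarization

A cohort is a patient × feature table with 22 predictors in a fixed order
(20 binary supplement/lifestyle/clinical indicators, an integer oocyte
count, integer age) and a binary embryo-transfer outcome. The column order
is part of the on-disk contract because downstream feature masks are
index-based. Binary columns are strictly {0, 1}; missing values are rejected
rather than imputed, since the modelling pipeline has no imputation stage.

The active-ingredient binarization maps raw intake records (patient ×
product × ingredient amount) to per-ingredient flags: flag = 1 iff the
patient's total daily amount reaches 100% of the ingredient's daily
requirement. Amounts are **summed across products** before thresholding by
default — this matches the "meets all daily needs" semantics and makes the
operator monotone (adding a record can never clear a flag); a stricter
`per_product` policy (some single product must meet the requirement alone)
is retained behind a flag. Unknown ingredients are excluded with a warning;
a unit mismatch against the requirement table is an error, since silently
comparing mg to µg would corrupt flags.

Summary tables use the sample (n−1) SD convention, reported as 0 for a
single row.

## Synthetic cohort generator

The generator emulates the *marginal* structure of the study cohort; it is
the ground truth against which selection and evaluation are tested.

* **Binary indicators** are independent Bernoulli draws at the published
  prevalences (e.g. working status 0.72, DHA 0.72, melatonin 0.006).
* **Age** is a truncated normal (mean 34.36, SD 4.58) on [24, 43], rounded
  to integer years. The (mean, SD) are the parent-normal parameters; the
  published bounds are enforced exactly.
* **Oocyte count** is over-dispersed (printed SD 9.81 ≫ mean 7.58 rules out
  Poisson), so it is modelled as a negative binomial truncated to [0, 58].
  Truncation pulls both moments down, so the *untruncated* (mean, variance)
  are calibrated by a two-parameter least-squares solve on the exact
  truncated pmf moments until the post-truncation mean and SD equal the
  printed 7.58 and 9.81 (to 1e−6 in distribution). Sampling draws directly
  from the renormalized pmf over {0, …, 58}, which is exact and fast.
* **Outcome**: P(success) = σ(β₀ + z′β) with z the predictors standardized
  under the marginal spec (binary features by √(p(1−p)), counts by their
  calibrated moments), so planted effect sizes are comparable across binary
  and count features. With β = 0 the intercept is the closed form
  logit(target); otherwise β₀ is found by a bracketing root search on a
  fixed Monte-Carlo draw of the linear predictor (monotone in β₀, hence
  deterministic for a fixed seed). The default target prevalence is 0.38.

Features are independent by default — the source material gives only
marginals. Real clinical data has correlation structure (supplement use
clusters, age relates to oocyte yield); passing tests on independent
marginals therefore demonstrates correctness of the machinery, not
performance on real cohorts.

## The bee colony optimizer

Canonical three-phase ABC, minimizing. Fitness is 1/(1+f) for f ≥ 0 and
1+|f| otherwise (the standard transform). Choices worth recording:

* **Abandonment parameter 0.01** is read as a fraction of the
  n_sources × max_iterations trial budget — a raw limit of 0.01 trials is
  meaningless for an integer counter — giving limit = max(1, ⌊0.01·15·30 +
  0.5⌋) = 5 at the defaults (round half up). An explicit integer override
  is accepted.
* **Greedy selection** keeps the strictly better of source and candidate;
  elitist global-best tracking is on by default, so the best-so-far
  trajectory is monotone for every seed.
* **At most one scout** per iteration (the source with the highest
  over-limit trial count) is re-initialized uniformly.
* **Binary-mask encoding**: positions live in [0,1]ᵈ and decode by
  thresholding at 0.5 with a closed lower boundary (a coordinate exactly at
  the threshold maps to 1). An all-zero mask is infeasible and receives the
  largest finite float as a sentinel objective, so it is never preferred
  and is quickly abandoned.
* **Budget accounting**: raw objective calls per run are bounded by
  n_sources × (2·max_iterations + 1) + one scout per iteration; mask
  objectives are additionally memoized, since one-coordinate moves often
  leave the decoded mask unchanged.

On piecewise-constant mask objectives the continuous encoding can converge
prematurely: when all sources agree on a coordinate the move term
φ(xᵢⱼ − xₖⱼ) vanishes and only scout injections restore diversity. In
practice the colony needs roughly 50–60 iterations at 15 sources to recover
a planted 8-bit mask reliably; the oracle-equivalence checks in the test
suite size their budgets accordingly (the d = 10 check runs at exactly the
3·2ᵈ evaluation budget, where the iteration count is large enough for
reliable recovery). This is a known limitation of threshold decoding, noted
rather than patched with non-canonical operators.

A parameter-sensitivity protocol (`sensitivity_grid`) reports mean ± SD of
the best objective over seeds across a (n_sources, iterations, abandonment)
grid.

## Hybrid model stages

* **L1 selection** uses liblinear lasso-penalized logistic regression at
  C = 1/strength; the mask is the exact nonzero-coefficient support. An
  empty mask is returned flagged infeasible; the model stage falls back to
  all-ones with a warning. The feature set documented for the original
  study (omega-3, folic acid, CoQ10, B12, C, B6, D, phytoalexin, selenium,
  zinc, dietician support) ships as a named fixture mask for tests and
  warm starts.
* **ABC mask search** scores a mask by 1 − mean inner stratified-CV score
  (default F1, k = 3) of the base learner on the masked features, with
  SMOTE applied inside inner training folds only. Inner folds are fixed
  once per search, so all masks are compared on identical partitions.
  Inner k = 3 rather than 5 keeps the ≈ 900-evaluation search affordable;
  outer evaluation keeps k = 5. The search covers the full feature space,
  with the L1 subset warm-starting one food source.
* **Resampling order** (genuinely open design point): within an outer
  training fold, the mask search runs on the raw fold (its inner folds
  handle balancing), while the L1 selection and the final base-learner fit
  use the SMOTE-balanced fold. This keeps every synthetic row derived from
  training rows only, which the harness asserts on every call.
* **Base learners** use library defaults (recorded in the run manifest);
  the source material prints no hyperparameters. SVM probabilities come
  from a logistic link fitted on training decision-function scores, so
  calibration metrics are computable for all 12 grid cells. Labels
  threshold probability at 0.5.
* The stage-2 coupling is strictly select-then-fit (no stacking of LR
  probabilities); an alternative continuous mode in which ABC optimizes LR
  coefficients directly is deliberately **not** the default, because the
  stage naming (ABC-LR-⟨classifier⟩) and the grid structure imply
  mask search with classifier fitness.

## Evaluation harness

Stratified 5-fold CV; per fold the *entire* pipeline (selection and search
included) sees only the training portion, and test folds contain only
original rows (asserted by index bookkeeping). SMOTE is the classic
nearest-neighbor interpolation (k = 5 neighbors by default, auto-shrunk
with a warning for tiny minorities; a single-member minority is an error).
k = n is honored as a leave-one-out partition, the one boundary where
per-fold stratification is vacuous.

Metrics follow the confusion-count definitions exactly; a zero denominator
yields an explicit NaN with a reason code and is excluded from fold
averages with an exclusion count — never silently 0. Both fold-averaged and
pooled-count views are first-class, since the two can legitimately
disagree. Brier, ROC-AUC (trapezoidal) and PR-AUC (step interpolation) are
computed on pooled out-of-fold probabilities; calibration uses 10
equal-width bins. The paired-fold t test is the classical df = k−1
construction with a t-quantile CI; zero-variance differences produce an
exact-tie report rather than a crash. An optional stratified holdout
(33/162 test fraction) is provided, but CV is the primary protocol. A
deliberately wrong SMOTE-before-split harness exists solely so tests can
demonstrate the optimism it induces.

The comparison report lists one row per (stage, base) cell — 12 at the
defaults — with percentages rounded to two decimals, grouped by stage, the
best row flagged, and failed cells isolated to their row.

## Local explanations

Perturbation: binary features resample uniformly from {0,1} (symmetric
coverage; prevalence-based sampling by flag), continuous features get
Gaussian jitter at the cohort SD; proximity weight exp(−d²/width²) on
SD-normalized Euclidean distance, default width 0.75·√p. The surrogate is
ridge-stabilized (α = 1e−8) weighted least squares on the top-K features
screened by absolute weighted covariance — screening rather than forward
selection, for determinism. Fidelity is the weighted R²; a constant model
short-circuits to zero weights with fidelity 1. Masked-out features are
excluded from the surrogate, so their reported weight is exactly 0.
Whether explanations should probe probabilities or hard labels was open;
probabilities are used, as they carry strictly more information.

## Problem sizes and known limitations

Tests run the grid at n = 200 and generator-fidelity checks at n = 10⁵;
support-recovery simulations use n = 2000 over 20 seeds. These sizes were
chosen as the smallest at which the respective statistical properties are
stable. The abstract of the motivating study counts 21 predictors while its
cohort table lists 22 predictor rows plus the outcome; the package models
all 22 and notes the discrepancy rather than resolving it. Performance
numbers published for the private cohort are not reproduction targets
anywhere in the package: with marginals-only synthetic data there is no
reason the same accuracies should re-occur, and the tests assert structure,
calibration and recovery properties instead.
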