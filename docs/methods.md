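# Methods

This note documents the statistical procedures implemented in `ruleout`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-cohort generator does and does not emulate.

## Problem setting

The package implements the development procedure for a *rule-out* diagnostic
test for obstructive coronary artery disease (CAD): a classifier on tabular
per-subject signal features whose decision threshold is tuned for high
sensitivity, so that a negative result can confidently exclude disease in a
low-prevalence symptomatic population. The development data it is designed
around have three structural difficulties that drive every design choice:

1. **many features, few subjects** — a large engineered-feature library
   against roughly a thousand subjects, so univariate screening must shrink
   the feature space before any model is fit;
2. **sex–disease confounding** — females are heavily over-represented among
   controls (~64.5%) and under-represented among cases (~26.7%), so an
   unconstrained learner can use sex as a proxy for disease;
3. **no held-out test set** — the low number of diseased women makes a
   single hold-out split wasteful, so performance is estimated from
   out-of-fold (OOF) predictions instead.

## Synthetic cohort generator

`CohortSpec`/`generate_cohort` produce cohorts with the statistical
structure the pipeline assumes, so every stage is testable without clinical
data.

* **Classes and sex.** Defaults: 641 diseased, 513 non-diseased; sex drawn
  Bernoulli per class (female fraction 0.267 in CAD+, 0.645 in CAD−).
* **Covariates** are sampled independently given class. Continuous age
  (55 ± 12 vs 64.9 ± 9.6 years) and BMI (31.3 ± 6.6 vs 30.9 ± 6.2) are
  class-conditional Gaussians, with `age_ge_65` / `bmi_ge_30` derived by
  thresholding. Binary risk factors (hypertension, diabetes,
  hyperlipidemia) are parameterised by a control-class baseline rate and a
  disease log-odds shift, with defaults matching the study population's
  demographics (e.g. hypertension 60.0% vs 78.6%). Only marginals are
  emulated; no covariate–covariate correlation structure is imposed because
  none is documented.
* **Features.** Each feature belongs to one of six physiological categories
  (arterial compliance, conduction, perfusion, repolarization, perfusion
  response, atrial structure) and one ground-truth role:
  * *linear*: standardized mean shift `linear_effect` (default d = 0.8)
    between classes;
  * *inverse*: shift −`linear_effect`;
  * *nonlinear*: equal means, disease-class variance multiplied by
    `nonlinear_effect` (default 4.0) — detectable by mutual information,
    invisible to a t-test;
  * *null*: identically distributed in both classes.
  The default library is 120 features (per category: 3 linear, 2 nonlinear,
  1 inverse, 14 null), a desk-scale analogue of a large feature library in
  which most features carry no signal. Features are independent by default;
  an optional equicorrelation (`feature_correlation`) adds a shared Gaussian
  factor per subject. An optional `missing_rate` plants NaNs to exercise
  downstream validation (all modelling stages reject missing values).
* **Subject roles.** With `n_screen_only_neg > 0` the generator adds a
  control pool tagged `feature_selection_only` (with an exactly balanced sex
  split so a balanced screening draw is always feasible) and reserves the
  intended-use controls for modelling — mirroring a design where screening
  controls never enter training. The OOF engine enforces the tags.
* **Determinism.** All streams derive from `seed` via named
  `SeedSequence` spawn keys; identical spec + seed gives a bit-identical
  cohort.

**What passing tests do and do not show.** The generator reproduces the
study's *marginal* structure (class sizes, sex imbalance, covariate
confounding, heterogeneous feature effects) but not its joint structure:
real signal features are correlated within and across categories, effect
sizes vary continuously rather than in three discrete tiers, and label noise
(imperfect adjudication) is absent. With 36 independent informative features
at d = 0.8 the default cohort is far more separable than clinical data —
end-to-end runs therefore demonstrate that the machinery is correct (no
leakage, calibration holds, weighting works), not that clinical
discrimination of any particular level would be achieved.

## Feature screening

Screening runs on a sex-balanced subset only: `per_cell` (default 104)
subjects drawn without replacement from each sex×class cell, i.e. 416
subjects in the default configuration. Three univariate tests are applied to
every feature; a feature is kept if it passes *any* of them. No
multiple-testing correction is applied across features — the thresholds are
deliberately per-feature, with strictness pushed into each test's bound.

* **t-test**: Welch's two-sample test, pass at p < 0.01. Welch is used
  because equal variances are not assumed (nonlinear features explicitly
  violate them). Two constant equal classes are assigned p = 1.
* **ROC-AUC**: rank (Mann–Whitney) AUC with ties counted half; a 95%
  percentile bootstrap interval from 1000 within-class resamples. Pass when
  the lower bound exceeds 0.52, or when the upper bound is below 0.48 (the
  inverse-predictivity branch, mirrored symmetrically).
* **Mutual information**: the feature is discretized into 10
  equal-frequency bins; plug-in MI against the label is divided by its mean
  over 200 label permutations, so the ratio is 1 in expectation under
  independence. The pass bound is a lower confidence limit of this ratio
  above 1.2, from a within-class bootstrap of the numerator (the
  permutation-null mean is a property of the sampling design and is held
  fixed across resamples). Because resampling subjects within class inflates
  plug-in MI even under independence, the bootstrap distribution is
  recentred on the observed MI (standard bootstrap bias correction) before
  the percentile bound is taken; without this correction the screen passes
  ~13% of pure-noise features at n = 208/208, with it essentially none,
  while power against equal-mean variance-ratio-4 features remains ~100%.

Resample counts (1000 bootstrap, 200 permutation) give stable second-digit
bounds at n = 416. Bootstrap/permutation streams are seeded per feature from
the config seed and the feature's column position, so results do not depend
on evaluation order. Features passing only the inverse-AUC branch are *not*
sign-flipped before modelling; the learners can represent the inversion
themselves.

## Out-of-fold bagged ensemble

Both base learners treat the task as regression on {0, 1} labels, so their
scores are commensurable and can be averaged:

* **Elastic net** — l1+l2-penalized linear regression, `l1_ratio` 0.5, with
  the penalty strength chosen by 3-fold cross-validation *inside each
  training split* (no test-fold leakage); features are standardized on the
  training split because the penalty is scale-sensitive. A fixed penalty can
  be configured instead, which is much faster for large banks.
* **Random forest** — 500 trees by default, squared-error splits, minimum
  leaf size 5, √p features per split. The forest sees raw features (it is
  scale-invariant).

One *stacked model* is the arithmetic mean of the two predictions. Training
uses per-subject sample weights `N / (4 n_cell)` over the four sex×disease
cells, recomputed on each training split, so every cell contributes equal
total weighted mass and sex cannot be exploited as a disease proxy.
Weighting can be disabled (`use_sample_weights=False`) for ablation.

The OOF engine runs stratified 5-fold cross-validation for 100 iterations
(defaults), drawing a fresh seeded fold split each iteration. Each iteration
yields one naive prediction per subject — from the single model whose
training excluded it — and five stored models; the per-subject OOF score is
the mean across iterations, and all k × n_iterations models (500 at
defaults) are retained in the `ModelBank`. New subjects are scored by
compressing all bank members' predictions with the **median** (the mean is
available behind `bank_compression` for comparison; the median is the
default because it is the more specific of the two documented reducers and
is robust to stray members).

## Cut-point calibration

Per sex, the cut point is the largest observed diseased score `t` such that
the fraction of diseased subjects with score ≥ t still meets the target
sensitivity (0.90 default) — the most specific threshold compatible with the
rule-out constraint; candidates are restricted to observed diseased scores.
Cut points are selected on the OOF scores of the full modelling cohort and
subtracted from the scores, so zero separates test-negative from
test-positive for both sexes. A score exactly at the cut counts as
test-positive (inclusive boundary): with ties at the cut this preserves the
"at least target sensitivity" guarantee.

## Evaluation suite

* 2×2 confusion table; sensitivity TP/(TP+FN), specificity TN/(TN+FP).
* Diagnostic odds ratio (TP·TN)/(FP·FN) with a log-normal Wald 95% CI
  (SE = √(1/TP+1/FP+1/FN+1/TN)); zero cells raise unless a 0.5 continuity
  correction is requested explicitly.
* Rank ROC-AUC, combined and per sex, on the zeroed scores.
* NPV as a function of prevalence:
  NPV(p) = spec·(1−p) / (spec·(1−p) + (1−sens)·p) — strictly decreasing in
  p for 0 < sens < 1. The default curve is evaluated at 3.8% (the
  prevalence implied by a 10% referral rate × 38% catheterization yield),
  10%, 20% and 30%.
* Subgroup table (sex, risk-factor strata): n, sensitivity, specificity,
  with undefined rates reported as absent plus the reason.
* Confounder-adjusted odds ratios: maximum-likelihood multivariate logistic
  regression of disease status on test-positivity plus covariates, with
  exponentiated coefficients, Wald 95% CIs and p-values, sorted descending.
  Wald intervals are asymptotic — parameter-recovery simulations here use
  n = 1000 per replicate, where coverage is stably at its nominal level.
  Under (quasi-)complete separation the MLE does not exist; the function
  raises and a Firth (Jeffreys-prior) bias-reduced fit is available as
  `penalized=True`, which `performance_report` falls back to automatically.
  Separation is a live concern precisely because the planted synthetic
  signal is strong.
* Category importance: permutation importance (mean drop in ensemble
  ROC-AUC over `n_perm` shuffles of one feature column) summed per
  physiological category, negative sums floored at zero, normalized to
  shares summing to 1. For tractability a seeded subsample of `max_models`
  bank members (default 50) is scored instead of the full 500-model
  ensemble; with the median reducer the subsample tracks the full bank
  closely.
* EN–RF diagnostic: Pearson correlation of the two base learners' OOF
  scores — a check that the stack combines two related but non-redundant
  views of the data.

## Numerical and reporting conventions

Percentages are displayed at 0 decimal places and odds ratios at 2 in the
text report; full precision is retained internally and in JSON output.
Fold assignments, model seeds, bootstrap, permutation and subsampling
streams all derive from the stage seed through named spawn keys, making
every result reproducible bit-for-bit from (config, seed).

## Problem sizes in the test-suite and acceptance script

The bundled acceptance script runs the full default cohort
(1154 subjects, 120 features) with the full 500-model bank but 100 trees
per forest and internal-CV elastic nets, which completes in a few minutes
on one core; the statistical test-suite exercises scale-free properties
(model counts, leakage, calibration, weighting) on smaller cohorts and
banks, with replicate counts chosen so each property check has comfortable
margin over its binomial sampling noise.

## Known limitations

* The generator's independence assumptions (features given role, covariates
  given class) understate the redundancy of real signal features; screening
  recall/false-selection rates on synthetic data will be optimistic.
* The elastic net is the linear (regression) variant, not logistic; scores
  are therefore not probabilities and may leave [0, 1]. Calibration by cut
  point makes this immaterial for test positivity.
* Permutation importance on a model-subsample is an approximation to
  full-bank importance.
* MCC, AUC-PR, F1 and DeLong AUC intervals are not implemented.
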