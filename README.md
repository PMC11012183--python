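# ruleout

Development pipeline for machine-learned **rule-out diagnostic tests** on
tabular clinical features — built for the setting of a point-of-care CAD
(coronary artery disease) test, where a classifier on engineered signal
features must be tuned so that a *negative* result confidently excludes
disease in a low-prevalence symptomatic population, with equal performance
across sexes.

The package is aimed at biostatisticians and ML engineers developing or
auditing diagnostic algorithms on case/control cohorts with three familiar
difficulties: far more candidate features than subjects, strong sex–disease
confounding, and no affordable held-out test set.

## What it implements

Given a cohort (feature matrix *X*, binary disease label *y*, binary sex
*s*, clinical covariates):

1. **Univariate triple-test screening** on a sex-balanced subset (default
   104 subjects per sex×class cell): a feature survives if it passes any of
   - Welch t-test at *p* < 0.01,
   - 95% bootstrap lower bound of the rank ROC-AUC > 0.52 (or upper bound
     < 0.48 for inversely predictive features),
   - 95% bootstrap lower bound of permutation-normalized mutual
     information > 1.2 (ratio = 1 ⇔ independence).
2. **Out-of-fold (OOF) bagged ensemble**: stratified 5-fold
   cross-validation repeated 100 iterations; each fold trains a *stack*
   ½(EN + RF) of an elastic-net regression and a random-forest regressor on
   {0,1} labels, with sample weights *N*/(4·n_cell) equalizing the four
   sex×disease cells. Every subject's OOF score is the mean of its naive
   (own-fold-excluded) predictions; all 500 models are kept, and new
   subjects are scored by the **median** over the bank.
3. **Per-sex cut points** at a target sensitivity (default 90%): the most
   specific threshold meeting the sensitivity constraint, subtracted from
   the scores so 0 separates test-negative from test-positive.
4. **Evaluation**: 2×2 table, sensitivity/specificity, per-sex and combined
   ROC-AUC, diagnostic odds ratio (TP·TN)/(FP·FN) with log-normal CI,
   confounder-adjusted odds ratios by multivariate logistic regression
   (Firth fallback under separation), NPV(p) = spec(1−p)/(spec(1−p)+(1−sens)p)
   across prevalences, subgroup tables, and permutation feature importance
   grouped by physiological category.

A synthetic-cohort generator (`CohortSpec`/`generate_cohort`) reproduces
the statistical structure this design assumes — class sizes 641/513, 26.7%
vs 64.5% female, confounded covariates, and a feature library with linear,
nonlinear (equal-mean/unequal-variance), inverse, and null features in six
physiological categories — so the whole pipeline is testable end to end.
See `docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
import ruleout as r

cohort = r.generate_cohort(r.CohortSpec(seed=0))        # 1154 subjects, 120 features
model = r.RuleOutModel(
    cohort,
    screen_config=r.ScreenConfig(seed=0),
    train_config=r.TrainConfig(n_iterations=10, rf_n_trees=100, seed=0),
    target_sensitivity=0.90,
)
results = model.fit()
print(results.summary())
```

```
            Rule-Out Test Development Results
==============================================================
subjects (modelling):        1154
features screened:           120
features selected:           36
models in bank:              50 (5 folds x 10 iterations)
bank compression:            median
target sensitivity:          90%
--------------------------------------------------------------
cut points (raw score):
  male        0.632   sens 90%  spec 99%
  female      0.615   sens 90%  spec 100%
--------------------------------------------------------------
sensitivity:                 90%
specificity:                 100%
ROC-AUC combined:            1.00
ROC-AUC female / male:       1.00 / 1.00
odds ratio:                  2344.11 (95% CI 570.73-9627.84)
EN-RF Pearson r:             0.97
==============================================================
```

Reading the output: screening kept 36 of 120 features (the generator plants
36 informative ones); each sex is calibrated to exactly 90% sensitivity on
its own OOF scores, at different raw cut points — the sex-specific
thresholds that, together with cell weighting, keep the rule-out profile
equal across sexes. Because the default synthetic signal is strong and the
features independent, specificity and AUC are near-perfect — far above what
clinical data yield; the run demonstrates the machinery, not clinical
performance. The NPV curve is the rule-out quantity of interest:

```python
report = results.performance_report()
for p, npv in sorted(report.npv_curve.items()):
    print(f"prevalence {100*p:5.1f}%  ->  NPV {100*npv:.2f}%")
```

```
prevalence   3.8%  ->  NPV 99.61%
prevalence  10.0%  ->  NPV 98.92%
prevalence  20.0%  ->  NPV 97.59%
prevalence  30.0%  ->  NPV 95.94%
```

New subjects are scored through the stored bank:
`results.predict(X_new, sex=sex_new)` returns raw, zeroed, and binary test
results; `results.plot_roc()` and `results.plot_score_distributions()`
reproduce the standard development figures.

A command-line interface mirrors the library
(`ruleout simulate | screen | train | calibrate | evaluate | run`), driven
by a YAML config; `ruleout run --config cfg.yaml` executes everything and
writes every intermediate artifact plus a manifest with config, seed,
library versions and checksums.

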