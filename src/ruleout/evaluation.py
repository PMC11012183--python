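"""Performance, confounder and interpretability analyses for a rule-out test.

Covers the 2x2 confusion table with sensitivity/specificity, the diagnostic
odds ratio with a log-normal confidence interval, rank ROC-AUC, negative
predictive value as a function of disease prevalence (the quantity that makes
a rule-out test useful in low-prevalence populations), subgroup performance
tables, confounder-adjusted odds ratios from multivariate logistic
regression, permutation feature importance aggregated by physiological
category, and the EN-vs-RF score correlation diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve

from ._rng import child_rng
from .cohort import Cohort
from .ensemble import ModelBank, predict_bank

__all__ = [
    "Confusion",
    "confusion_and_rates",
    "odds_ratio",
    "roc_auc",
    "npv_at_prevalence",
    "implied_prevalence",
    "subgroup_report",
    "adjusted_odds_ratios",
    "category_importance",
    "model_correlation",
    "PerformanceReport",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def confusion_and_rates(test_result, label) -> tuple[Confusion, float, float]:
    """2x2 counts plus sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP)."""
    test_result = np.asarray(test_result).astype(int)
    label = np.asarray(label).astype(int)
    if test_result.shape != label.shape:
        raise ValueError("test_result and label must have the same length")
    if len(np.unique(label)) < 2:
        raise ValueError("both disease classes must be present")
    conf = Confusion(
        tp=int(((test_result == 1) & (label == 1)).sum()),
        fp=int(((test_result == 1) & (label == 0)).sum()),
        fn=int(((test_result == 0) & (label == 1)).sum()),
        tn=int(((test_result == 0) & (label == 0)).sum()),
    )
    return conf, conf.tp / conf.n_pos, conf.tn / conf.n_neg


def odds_ratio(conf: Confusion, confidence: float = 0.95, continuity: bool = False) -> tuple[float, float, float]:
    """Diagnostic odds ratio (TPxTN)/(FPxFN) with a log-normal Wald CI.

    A zero cell raises unless ``continuity`` adds 0.5 to every cell.
    """
    cells = np.array([conf.tp, conf.fp, conf.fn, conf.tn], dtype=float)
    if continuity:
        cells = cells + 0.5
    if (cells == 0).any():
        raise ValueError("odds ratio undefined with a zero cell (pass continuity=True to correct)")
    tp, fp, fn, tn = cells
    est = (tp * tn) / (fp * fn)
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2)
    se = np.sqrt((1 / cells).sum())
    log_or = np.log(est)
    return float(est), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def roc_auc(scores, label) -> float:
    """Mann-Whitney AUC (ties counted half); equals the trapezoidal ROC area."""
    label = np.asarray(label).astype(int)
    if len(np.unique(label)) < 2:
        raise ValueError("both disease classes must be present")
    return float(roc_auc_score(label, np.asarray(scores, dtype=float)))


def roc_coordinates(scores, label) -> pd.DataFrame:
    """Empirical ROC curve coordinates (for CSV export / plotting)."""
    fpr, tpr, thr = roc_curve(np.asarray(label).astype(int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def npv_at_prevalence(sensitivity: float, specificity: float, prevalence: float) -> float:
    """NPV = spec(1-p) / (spec(1-p) + (1-sens)p); 0 on a zero denominator."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    num = specificity * (1.0 - prevalence)
    den = num + (1.0 - sensitivity) * prevalence
    if den == 0:
        return 0.0
    return num / den


def implied_prevalence(referral_rate: float, catheterization_yield: float) -> float:
    """Disease prevalence in the full symptomatic population implied by a
    referral funnel: the fraction referred onward times the fraction of those
    confirmed diseased (e.g. 10% referred x 38% confirmed = 3.8%)."""
    if not 0.0 <= referral_rate <= 1.0 or not 0.0 <= catheterization_yield <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    return referral_rate * catheterization_yield


def subgroup_report(test_result, label, subgroups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-subgroup n, sensitivity and specificity.

    Rates undefined within a subgroup (no positives / no negatives) are
    reported as NaN with the reason in the ``note`` column.
    """
    test_result = np.asarray(test_result).astype(int)
    label = np.asarray(label).astype(int)
    rows = []
    for name, mask in subgroups.items():
        mask = np.asarray(mask).astype(bool)
        if mask.sum() == 0:
            raise ValueError(f"subgroup {name!r} is empty")
        t, y = test_result[mask], label[mask]
        notes = []
        if (y == 1).any():
            sens = float((t[y == 1] == 1).mean())
        else:
            sens, notes = np.nan, notes + ["no positives"]
        if (y == 0).any():
            spec = float((t[y == 0] == 0).mean())
        else:
            spec, notes = np.nan, notes + ["no negatives"]
        rows.append(
            {"subgroup": name, "n": int(mask.sum()), "sensitivity": sens, "specificity": spec, "note": "; ".join(notes)}
        )
    return pd.DataFrame(rows).set_index("subgroup")


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Returns ``(beta, cov)``. Estimates stay finite under (quasi-)complete
    separation, which defeats the ordinary MLE.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        # hat-matrix diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov


def adjusted_odds_ratios(
    test_result,
    label,
    covariates: pd.DataFrame,
    confidence: float = 0.95,
    penalized: bool = False,
) -> pd.DataFrame:
    """Confounder-adjusted odds ratios via multivariate logistic regression.

    Fits disease status on test-positivity plus covariates by maximum
    likelihood; reports the exponentiated coefficient, Wald CI and Wald
    p-value per predictor, sorted by descending odds ratio. Raises on
    separation / non-convergence, advising the Firth-penalized refit
    (``penalized=True``), whose estimates remain finite under separation.
    """
    y = np.asarray(label).astype(int)
    X = pd.DataFrame({"test_positive": np.asarray(test_result).astype(int)})
    X = pd.concat([X, covariates.reset_index(drop=True)], axis=1).astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Xc = sm.add_constant(X, prepend=True)
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2)
    if penalized:
        beta, cov = _firth_logit(Xc.to_numpy(), y)
        se = np.sqrt(np.diag(cov))
        params = pd.Series(beta, index=Xc.columns)
        se = pd.Series(se, index=Xc.columns)
        out = pd.DataFrame(
            {
                "odds_ratio": np.exp(params),
                "ci_lower": np.exp(params - z * se),
                "ci_upper": np.exp(params + z * se),
                "p_value": 2 * norm.sf(np.abs(params / se)),
            }
        ).drop(index="const")
        return out.sort_values("odds_ratio", ascending=False)
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as err:  # PerfectSeparationError and friends
        raise ValueError(
            "logistic fit failed (possible separation); retry with penalized=True (Firth)"
        ) from err
    if not fit.mle_retvals.get("converged", True):
        raise ValueError(
            "logistic fit did not converge (possible separation); retry with penalized=True (Firth)"
        )
    alpha = 1.0 - confidence
    ci = fit.conf_int(alpha=alpha)
    out = pd.DataFrame(
        {
            "odds_ratio": np.exp(fit.params),
            "ci_lower": np.exp(ci[0]),
            "ci_upper": np.exp(ci[1]),
            "p_value": fit.pvalues,
        }
    ).drop(index="const")
    return out.sort_values("odds_ratio", ascending=False)


def category_importance(
    bank: ModelBank,
    cohort: Cohort,
    n_perm: int = 5,
    seed: int = 0,
    *,
    max_models: int | None = 50,
) -> tuple[pd.Series, pd.Series]:
    """Permutation feature importance aggregated by physiological category.

    Per-feature importance is the mean drop in ensemble ROC-AUC over
    ``n_perm`` independent shuffles of that feature column; category
    importance sums member features and is normalized to proportions summing
    to one (negative sums floored at zero before normalizing). For large
    banks a seeded subsample of ``max_models`` stacks is scored instead of
    the full ensemble.

    Returns ``(category_share, per_feature_importance)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fids = list(bank.feature_ids)
    missing = [f for f in fids if f not in cohort.feature_meta.index]
    if missing:
        raise ValueError(f"features without category metadata: {missing[:5]}")
    rng = child_rng(seed, "category_importance")

    eval_bank = bank
    if max_models is not None and len(bank) > max_models:
        take = rng.choice(len(bank), size=max_models, replace=False)
        eval_bank = ModelBank(
            models=[bank.models[i] for i in sorted(take)],
            feature_ids=bank.feature_ids,
            config=bank.config,
        )

    idx = cohort.modelling_eligible()
    X = cohort.features.loc[idx, fids]
    y = cohort.label.loc[idx].to_numpy().astype(int)
    base_auc = roc_auc(predict_bank(eval_bank, X), y)

    importances = pd.Series(0.0, index=fids)
    X_np = X.to_numpy(dtype=float)
    for j, fid in enumerate(fids):
        drops = []
        for _ in range(n_perm):
            Xp = X_np.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base_auc - roc_auc(predict_bank(eval_bank, Xp), y))
        importances[fid] = float(np.mean(drops))

    cats = cohort.feature_meta.loc[fids, "category"]
    cat_sums = importances.groupby(cats).sum().clip(lower=0.0)
    total = cat_sums.sum()
    share = cat_sums / total if total > 0 else cat_sums * 0.0
    return share.sort_values(ascending=False), importances


def model_correlation(en_scores, rf_scores) -> float:
    """Pearson correlation between the two base learners' score vectors."""
    a = np.asarray(en_scores, dtype=float)
    b = np.asarray(rf_scores, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need two equal-length score vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance score vector")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PerformanceReport:
    """Bundle of all evaluation outputs for one calibrated algorithm."""

    confusion: Confusion
    sensitivity: float
    specificity: float
    roc_auc_combined: float
    roc_auc_by_sex: dict[str, float]
    odds_ratio: tuple[float, float, float]
    npv_curve: dict[float, float]
    subgroup_table: pd.DataFrame
    adjusted_or_table: pd.DataFrame | None
    category_share: pd.Series | None
    en_rf_correlation: float
    cut_points: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confusion": self.confusion.as_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_auc_combined": self.roc_auc_combined,
            "roc_auc_by_sex": self.roc_auc_by_sex,
            "odds_ratio": {
                "estimate": self.odds_ratio[0],
                "ci_lower": self.odds_ratio[1],
                "ci_upper": self.odds_ratio[2],
            },
            "npv_curve": {str(k): v for k, v in self.npv_curve.items()},
            "subgroups": json.loads(self.subgroup_table.to_json(orient="index")),
            "adjusted_odds_ratios": (
                json.loads(self.adjusted_or_table.to_json(orient="index"))
                if self.adjusted_or_table is not None
                else None
            ),
            "category_share": (self.category_share.to_dict() if self.category_share is not None else None),
            "en_rf_correlation": self.en_rf_correlation,
            "cut_points": self.cut_points,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def text_report(self) -> str:
        c = self.confusion
        lines = [
            "Rule-out test performance",
            "=" * 60,
            f"2x2 table          CAD+    CAD-",
            f"  test-positive  {c.tp:6d}  {c.fp:6d}",
            f"  test-negative  {c.fn:6d}  {c.tn:6d}",
            f"sensitivity: {100 * self.sensitivity:.0f}%   specificity: {100 * self.specificity:.0f}%",
            f"ROC-AUC (combined): {self.roc_auc_combined:.2f}",
        ]
        for name, auc in self.roc_auc_by_sex.items():
            lines.append(f"ROC-AUC ({name}): {auc:.2f}")
        est, lo, hi = self.odds_ratio
        lines.append(f"odds ratio: {est:.2f} (95% CI {lo:.2f}-{hi:.2f})")
        lines.append(f"EN-RF Pearson r: {self.en_rf_correlation:.2f}")
        if self.cut_points:
            cp = "  ".join(f"{k}: {v:.3f}" for k, v in self.cut_points.items())
            lines.append(f"cut points: {cp}")
        lines.append("")
        lines.append("NPV by prevalence:")
        for p, npv in sorted(self.npv_curve.items()):
            lines.append(f"  prevalence {100 * p:5.1f}%  ->  NPV {100 * npv:.2f}%")
        return "\n".join(lines)
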