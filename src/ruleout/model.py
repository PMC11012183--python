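"""Model/Results interface for rule-out algorithm development.

:class:`RuleOutModel` wraps a :class:`~ruleout.cohort.Cohort` together with
screening, training and calibration settings; :meth:`RuleOutModel.fit` runs
the full development procedure — balanced-subset triple-test feature
screening, repeated stratified out-of-fold training of the bagged EN + RF
stack, and per-sex cut-point selection at the target sensitivity — and
returns a :class:`RuleOutResults` carrying the selected features, the model
bank, the OOF scores, the cut points, and the evaluation suite, with a
``summary()`` table in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CutPoints, apply_cut_points, fit_cut_points
from .cohort import Cohort
from .ensemble import ModelBank, OofResult, TrainConfig, predict_bank, run_oof
from .evaluation import (
    PerformanceReport,
    adjusted_odds_ratios,
    category_importance,
    confusion_and_rates,
    model_correlation,
    npv_at_prevalence,
    odds_ratio,
    roc_auc,
    subgroup_report,
)
from .screening import ScreenConfig, ScreenResult, build_balanced_subset, select_features

__all__ = ["RuleOutModel", "RuleOutResults"]

DEFAULT_PREVALENCES = (0.038, 0.10, 0.20, 0.30)


class RuleOutModel:
    """Rule-out diagnostic test development model.

    Parameters
    ----------
    cohort : Cohort
        Subject-level data (features, disease label, sex, covariates,
        feature metadata, subject roles).
    screen_config : ScreenConfig, optional
        Thresholds and resampling sizes for the univariate triple screen.
        ``None`` skips screening and models every feature.
    train_config : TrainConfig
        OOF / ensemble hyperparameters.
    target_sensitivity : float
        Per-sex sensitivity at which cut points are calibrated.
    """

    def __init__(
        self,
        cohort: Cohort,
        screen_config: ScreenConfig | None = ScreenConfig(),
        train_config: TrainConfig = TrainConfig(),
        target_sensitivity: float = 0.90,
    ) -> None:
        self.cohort = cohort
        self.screen_config = screen_config
        self.train_config = train_config
        self.target_sensitivity = target_sensitivity

    @classmethod
    def from_dataframes(
        cls,
        features: pd.DataFrame,
        label: pd.Series,
        sex: pd.Series,
        covariates: pd.DataFrame | None = None,
        feature_meta: pd.DataFrame | None = None,
        **kwargs,
    ) -> "RuleOutModel":
        """Build a model straight from aligned dataframes.

        ``feature_meta`` defaults to a single 'uncategorized' category with
        role 'null' (unknown ground truth) for every feature.
        """
        if covariates is None:
            covariates = pd.DataFrame(index=features.index)
        if feature_meta is None:
            feature_meta = pd.DataFrame(
                {"category": "uncategorized", "role": "null"}, index=features.columns
            )
            feature_meta.index.name = "feature_id"
        cohort = Cohort(
            features=features,
            label=label,
            sex=sex,
            covariates=covariates,
            feature_meta=feature_meta,
        )
        return cls(cohort, **kwargs)

    @classmethod
    def from_csv(cls, directory, **kwargs) -> "RuleOutModel":
        from .cohort import read_cohort

        return cls(read_cohort(directory), **kwargs)

    def fit(self, seed: int | None = None) -> "RuleOutResults":
        """Run screening, OOF ensemble training and cut-point calibration."""
        cohort = self.cohort
        screen_result = None
        if self.screen_config is not None:
            cfg = self.screen_config
            if seed is not None:
                from dataclasses import replace

                cfg = replace(cfg, seed=seed)
            subset = build_balanced_subset(cohort, cfg.per_cell, seed=cfg.seed)
            screen_result = select_features(cohort, subset, cfg)
            selected = screen_result.selected or list(cohort.features.columns)
        else:
            selected = list(cohort.features.columns)

        tcfg = self.train_config
        if seed is not None:
            from dataclasses import replace

            tcfg = replace(tcfg, seed=seed)
        bank, oof = run_oof(cohort, selected, tcfg)

        idx = oof.oof_score.index
        cut_points = fit_cut_points(
            oof.oof_score.to_numpy(),
            cohort.label.loc[idx].to_numpy(),
            cohort.sex.loc[idx].to_numpy(),
            target=self.target_sensitivity,
        )
        return RuleOutResults(
            model=self,
            screen_result=screen_result,
            selected_features=selected,
            bank=bank,
            oof=oof,
            cut_points=cut_points,
        )


@dataclass
class RuleOutResults:
    """Fitted rule-out algorithm: selected features, model bank, OOF scores,
    per-sex cut points, and the evaluation suite."""

    model: RuleOutModel
    screen_result: ScreenResult | None
    selected_features: list[str]
    bank: ModelBank
    oof: OofResult
    cut_points: CutPoints
    _cache: dict = field(default_factory=dict, repr=False)

    # -- core derived quantities -------------------------------------------

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    @property
    def eval_index(self) -> pd.Index:
        return self.oof.oof_score.index

    def zeroed_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(zeroed score, test result) over the modelling cohort."""
        idx = self.eval_index
        return apply_cut_points(
            self.oof.oof_score.to_numpy(),
            self.cohort.sex.loc[idx].to_numpy(),
            self.cut_points,
        )

    def predict(self, features: pd.DataFrame, sex=None) -> pd.DataFrame:
        """Score new subjects through the bagged ensemble.

        Returns raw bank scores; when ``sex`` is given, also zeroed scores
        and the binary test result.
        """
        raw = predict_bank(self.bank, features)
        out = pd.DataFrame({"score": raw}, index=features.index)
        if sex is not None:
            zeroed, result = apply_cut_points(raw, np.asarray(sex), self.cut_points)
            out["zeroed_score"] = zeroed
            out["test_result"] = result
        return out

    # -- evaluation ---------------------------------------------------------

    def performance_report(
        self,
        prevalences=DEFAULT_PREVALENCES,
        include_adjusted_or: bool = True,
        include_category_importance: bool = False,
        importance_kwargs: dict | None = None,
    ) -> PerformanceReport:
        idx = self.eval_index
        label = self.cohort.label.loc[idx].to_numpy()
        sex = self.cohort.sex.loc[idx].to_numpy()
        zeroed, test_result = self.zeroed_scores()

        conf, sens, spec = confusion_and_rates(test_result, label)
        auc_combined = roc_auc(zeroed, label)
        auc_by_sex = {
            "female": roc_auc(zeroed[sex == 1], label[sex == 1]),
            "male": roc_auc(zeroed[sex == 0], label[sex == 0]),
        }
        or_est = odds_ratio(conf)
        npv_curve = {p: npv_at_prevalence(sens, spec, p) for p in prevalences}

        subgroups = {"all": np.ones(len(idx), bool), "female": sex == 1, "male": sex == 0}
        for cov in ("age_ge_65", "diabetes", "hypertension", "hyperlipidemia", "bmi_ge_30"):
            if cov in self.cohort.covariates.columns:
                vals = self.cohort.covariates.loc[idx, cov].to_numpy().astype(int)
                if vals.sum() and (1 - vals).sum():
                    subgroups[cov] = vals == 1
                    subgroups[f"not_{cov}"] = vals == 0
        sub_table = subgroup_report(test_result, label, subgroups)

        adj = None
        if include_adjusted_or:
            cov_cols = [
                c
                for c in ("age_ge_65", "diabetes", "hypertension", "hyperlipidemia")
                if c in self.cohort.covariates.columns
            ]
            design = self.cohort.covariates.loc[idx, cov_cols].copy()
            design["male"] = (sex == 0).astype(int)
            try:
                adj = adjusted_odds_ratios(test_result, label, design)
            except ValueError:
                # (quasi-)separation: fall back to the Firth penalized fit
                adj = adjusted_odds_ratios(test_result, label, design, penalized=True)

        share = None
        if include_category_importance:
            share, _ = category_importance(self.bank, self.cohort, **(importance_kwargs or {}))

        return PerformanceReport(
            confusion=conf,
            sensitivity=sens,
            specificity=spec,
            roc_auc_combined=auc_combined,
            roc_auc_by_sex=auc_by_sex,
            odds_ratio=or_est,
            npv_curve=npv_curve,
            subgroup_table=sub_table,
            adjusted_or_table=adj,
            category_share=share,
            en_rf_correlation=self.en_rf_correlation(),
            cut_points={("female" if k == 1 else "male"): v for k, v in self.cut_points.threshold_by_sex.items()},
        )

    def en_rf_correlation(self) -> float:
        return model_correlation(self.oof.en_oof_score.to_numpy(), self.oof.rf_oof_score.to_numpy())

    def category_importance(self, **kwargs) -> tuple[pd.Series, pd.Series]:
        return category_importance(self.bank, self.cohort, **kwargs)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        report = self._cache.setdefault("report", self.performance_report(include_adjusted_or=False))
        n_screen = len(self.screen_result.table) if self.screen_result is not None else 0
        lines = [
            "            Rule-Out Test Development Results",
            "=" * 62,
            f"subjects (modelling):        {len(self.eval_index)}",
            f"features screened:           {n_screen}",
            f"features selected:           {len(self.selected_features)}",
            f"models in bank:              {len(self.bank)} "
            f"({self.bank.config.k_folds} folds x {self.bank.config.n_iterations} iterations)",
            f"bank compression:            {self.bank.config.bank_compression}",
            f"target sensitivity:          {self.cut_points.target_sensitivity:.0%}",
            "-" * 62,
            "cut points (raw score):",
        ]
        for sx, thr in sorted(self.cut_points.threshold_by_sex.items()):
            name = "female" if sx == 1 else "male"
            ach = self.cut_points.achieved[sx]
            lines.append(
                f"  {name:<8s} {thr:8.3f}   sens {ach['sensitivity']:.0%}  spec {ach['specificity']:.0%}"
            )
        lines += [
            "-" * 62,
            f"sensitivity:                 {report.sensitivity:.0%}",
            f"specificity:                 {report.specificity:.0%}",
            f"ROC-AUC combined:            {report.roc_auc_combined:.2f}",
            f"ROC-AUC female / male:       {report.roc_auc_by_sex['female']:.2f} / {report.roc_auc_by_sex['male']:.2f}",
            f"odds ratio:                  {report.odds_ratio[0]:.2f} "
            f"(95% CI {report.odds_ratio[1]:.2f}-{report.odds_ratio[2]:.2f})",
            f"EN-RF Pearson r:             {report.en_rf_correlation:.2f}",
            "=" * 62,
        ]
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_roc(self, ax=None):
        from .plotting import plot_roc

        return plot_roc(self, ax=ax)

    def plot_score_distributions(self, ax=None, zeroed: bool = True):
        from .plotting import plot_score_distributions

        return plot_score_distributions(self, ax=ax, zeroed=zeroed)
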