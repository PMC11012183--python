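"""Synthetic cohorts with the statistical structure of a CAD rule-out study.

The generator emulates a case/control tabular dataset the way it arrives for
diagnostic-test development: a numeric feature matrix per subject, a binary
disease label (CAD+ = 1), a binary sex covariate (female = 1) whose frequency
is strongly confounded with the label, clinical risk-factor covariates with
class-conditional distributions, and a feature library whose members are
linearly predictive, nonlinearly predictive (equal means, unequal spread),
inversely predictive, or pure noise, organised into six named physiological
categories.

Defaults reflect the intended-use cohort of the study this pipeline was built
around: 641 diseased and 513 non-diseased subjects, 26.7% female among CAD+
versus 64.5% among CAD-, and risk-factor rates that differ by class (age,
hypertension, diabetes, hyperlipidemia confounded; BMI not).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from ._rng import child_rng

__all__ = [
    "CATEGORIES",
    "FEATURE_ROLES",
    "FeatureCounts",
    "BinaryCovariate",
    "ContinuousCovariate",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "cohort_summary",
    "write_cohort",
    "read_cohort",
]

#: The six physiological feature categories of the signal library.
CATEGORIES = (
    "arterial_compliance",
    "conduction",
    "perfusion",
    "repolarization",
    "perfusion_response",
    "atrial_structure",
)

FEATURE_ROLES = ("linear", "nonlinear", "inverse", "null")

#: Allowed subject usages: screening only, modelling only, or both.
SUBJECT_ROLES = ("feature_selection_only", "train_validate", "both")


@dataclass(frozen=True)
class FeatureCounts:
    """How many features of each ground-truth role a category contains."""

    linear: int = 3
    nonlinear: int = 2
    inverse: int = 1
    null: int = 14

    def __post_init__(self) -> None:
        for role in FEATURE_ROLES:
            if getattr(self, role) < 0:
                raise ValueError(f"negative feature count for role {role!r}")

    @property
    def total(self) -> int:
        return self.linear + self.nonlinear + self.inverse + self.null


@dataclass(frozen=True)
class BinaryCovariate:
    """Class-confounded Bernoulli covariate.

    ``baseline_rate`` is the frequency among non-diseased subjects and
    ``log_odds`` the log-odds shift associated with disease, so the frequency
    among diseased subjects is ``expit(logit(baseline_rate) + log_odds)``.
    """

    baseline_rate: float
    log_odds: float = 0.0

    @property
    def rate_neg(self) -> float:
        return self.baseline_rate

    @property
    def rate_pos(self) -> float:
        return float(expit(logit(self.baseline_rate) + self.log_odds))


@dataclass(frozen=True)
class ContinuousCovariate:
    """Gaussian covariate with class-conditional mean/SD, optionally
    thresholded into a derived binary indicator (e.g. age >= 65)."""

    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    threshold: float | None = None
    threshold_name: str | None = None


def _default_covariates() -> dict[str, BinaryCovariate | ContinuousCovariate]:
    # Class-conditional parameters matching the study's demographics table.
    def _beta(p_neg: float, p_pos: float) -> float:
        return float(logit(p_pos) - logit(p_neg))

    return {
        "age": ContinuousCovariate(55.0, 12.0, 64.9, 9.6, threshold=65.0, threshold_name="age_ge_65"),
        "bmi": ContinuousCovariate(31.3, 6.6, 30.9, 6.2, threshold=30.0, threshold_name="bmi_ge_30"),
        "hypertension": BinaryCovariate(0.600, _beta(0.600, 0.786)),
        "diabetes": BinaryCovariate(0.158, _beta(0.158, 0.345)),
        "hyperlipidemia": BinaryCovariate(0.526, _beta(0.526, 0.766)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_pos, n_neg
        Diseased / non-diseased subject counts in the intended-use cohort.
    female_frac_pos, female_frac_neg
        Class-conditional probability that a subject is female.
    features_per_category
        Map category name -> :class:`FeatureCounts`; defaults to the six
        physiological categories with 20 features each (3 linear, 2 nonlinear,
        1 inverse, 14 null).
    linear_effect
        Standardized between-class mean shift (Cohen's d) of linear features;
        inverse features use ``-linear_effect``.
    nonlinear_effect
        Variance ratio (diseased over non-diseased) of nonlinear features;
        their means are equal, so a t-test is blind to them.
    covariate_effects
        Map covariate name -> :class:`BinaryCovariate` or
        :class:`ContinuousCovariate`.
    noise_sd
        Residual standard deviation of features in the non-diseased class.
    feature_correlation
        Optional equicorrelation among feature residuals (shared Gaussian
        factor per subject); 0 means independent features.
    missing_rate
        Optional fraction of feature cells set to NaN (downstream stages
        reject missing values; this exists to exercise their validation).
    n_screen_only_neg
        Extra non-diseased subjects tagged ``feature_selection_only`` (drawn
        with a balanced sex split), emulating a screening-only control set
        that must never enter model training.
    seed
        Generation seed; identical spec + seed gives a bit-identical cohort.
    """

    n_pos: int = 641
    n_neg: int = 513
    female_frac_pos: float = 0.267
    female_frac_neg: float = 0.645
    features_per_category: Mapping[str, FeatureCounts] = field(
        default_factory=lambda: {c: FeatureCounts() for c in CATEGORIES}
    )
    linear_effect: float = 0.8
    nonlinear_effect: float = 4.0
    covariate_effects: Mapping[str, BinaryCovariate | ContinuousCovariate] = field(
        default_factory=_default_covariates
    )
    noise_sd: float = 1.0
    feature_correlation: float = 0.0
    missing_rate: float = 0.0
    n_screen_only_neg: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0 or self.n_screen_only_neg < 0:
            raise ValueError("subject counts must be non-negative")
        for name, frac in (
            ("female_frac_pos", self.female_frac_pos),
            ("female_frac_neg", self.female_frac_neg),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.nonlinear_effect <= 0:
            raise ValueError("nonlinear_effect (variance ratio) must be positive")
        if not self.features_per_category:
            raise ValueError("at least one feature category is required")

    @property
    def n_features(self) -> int:
        return sum(fc.total for fc in self.features_per_category.values())

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@dataclass
class Cohort:
    """Per-subject data for one study cohort.

    Attributes
    ----------
    features : pandas.DataFrame
        Subjects x features, numeric; index is the subject id.
    label : pandas.Series
        1 = diseased (CAD+), 0 = non-diseased.
    sex : pandas.Series
        1 = female, 0 = male.
    covariates : pandas.DataFrame
        Clinical covariates (continuous and 0/1 indicator columns).
    feature_meta : pandas.DataFrame
        Indexed by feature id with columns ``category`` and ``role``.
    role : pandas.Series
        Allowed usage per subject: ``feature_selection_only``,
        ``train_validate`` or ``both``.
    """

    features: pd.DataFrame
    label: pd.Series
    sex: pd.Series
    covariates: pd.DataFrame
    feature_meta: pd.DataFrame
    role: pd.Series | None = None

    def __post_init__(self) -> None:
        n = len(self.features)
        if self.role is None:
            self.role = pd.Series("both", index=self.features.index, name="role")
        for name, obj in (
            ("label", self.label),
            ("sex", self.sex),
            ("covariates", self.covariates),
            ("role", self.role),
        ):
            if len(obj) != n:
                raise ValueError(f"{name} has {len(obj)} rows, features has {n}")
            if not obj.index.equals(self.features.index):
                raise ValueError(f"{name} index does not match features index")
        if self.features.index.has_duplicates:
            raise ValueError("duplicate subject ids")
        if not set(np.unique(self.label)) <= {0, 1}:
            raise ValueError("label must be binary 0/1")
        if not set(np.unique(self.sex)) <= {0, 1}:
            raise ValueError("sex must be binary 0/1")
        bad_roles = set(self.role.unique()) - set(SUBJECT_ROLES)
        if bad_roles:
            raise ValueError(f"unknown subject roles: {sorted(bad_roles)}")
        missing_meta = self.features.columns.difference(self.feature_meta.index)
        if len(missing_meta):
            raise ValueError(f"features without metadata: {list(missing_meta)[:5]}")
        bad = set(self.feature_meta["role"].unique()) - set(FEATURE_ROLES)
        if bad:
            raise ValueError(f"unknown feature roles: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def screening_eligible(self) -> pd.Index:
        """Subjects allowed into feature selection."""
        return self.features.index[self.role != "train_validate"]

    def modelling_eligible(self) -> pd.Index:
        """Subjects allowed into model training / internal validation."""
        return self.features.index[self.role != "feature_selection_only"]

    def subset(self, index: pd.Index) -> "Cohort":
        return Cohort(
            features=self.features.loc[index],
            label=self.label.loc[index],
            sex=self.sex.loc[index],
            covariates=self.covariates.loc[index],
            feature_meta=self.feature_meta,
            role=self.role.loc[index],
        )


def _feature_table(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    for cat, counts in spec.features_per_category.items():
        for role in FEATURE_ROLES:
            for j in range(getattr(counts, role)):
                rows.append({"category": cat, "role": role, "within": j})
    meta = pd.DataFrame(rows)
    meta["feature_id"] = [
        f"{r.category}__{r.role}_{r.within:02d}" for r in meta.itertuples()
    ]
    return meta.set_index("feature_id").drop(columns="within")


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort from ``spec``; bit-reproducible for fixed seed."""
    n_intended = spec.n_pos + spec.n_neg
    n = n_intended + spec.n_screen_only_neg
    if spec.n_pos == 0 and spec.n_neg == 0:
        raise ValueError("cohort must contain at least one subject")

    meta = _feature_table(spec)
    label = np.concatenate(
        [np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg + spec.n_screen_only_neg, dtype=int)]
    )
    # With a dedicated screening-only control pool, intended-use controls are
    # reserved for modelling (mirroring a design where the modelling controls
    # never enter feature selection); without one, everyone is dual-use.
    neg_role = "train_validate" if spec.n_screen_only_neg else "both"
    role = np.array(
        ["both"] * spec.n_pos
        + [neg_role] * spec.n_neg
        + ["feature_selection_only"] * spec.n_screen_only_neg,
        dtype=object,
    )

    rng_sex = child_rng(spec.seed, "sex")
    sex = np.empty(n, dtype=int)
    sex[: spec.n_pos] = rng_sex.random(spec.n_pos) < spec.female_frac_pos
    sex[spec.n_pos : n_intended] = rng_sex.random(spec.n_neg) < spec.female_frac_neg
    if spec.n_screen_only_neg:
        # Screening-only controls carry an exactly balanced sex split so that a
        # balanced per-cell draw is always feasible from this pool.
        half = spec.n_screen_only_neg // 2
        extra = np.zeros(spec.n_screen_only_neg, dtype=int)
        extra[:half] = 1
        sex[n_intended:] = rng_sex.permutation(extra)

    # Feature residuals: standard normal, optionally equicorrelated.
    rng_feat = child_rng(spec.seed, "features")
    p = spec.n_features
    resid = rng_feat.standard_normal((n, p))
    if spec.feature_correlation > 0:
        rho = spec.feature_correlation
        common = rng_feat.standard_normal((n, 1))
        resid = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * resid

    X = resid * spec.noise_sd
    pos = label == 1
    d = spec.linear_effect * spec.noise_sd
    for j, (fid, row) in enumerate(meta.iterrows()):
        if row["role"] == "linear":
            X[pos, j] += d
        elif row["role"] == "inverse":
            X[pos, j] -= d
        elif row["role"] == "nonlinear":
            X[pos, j] *= np.sqrt(spec.nonlinear_effect)

    if spec.missing_rate > 0:
        rng_miss = child_rng(spec.seed, "missing")
        X[rng_miss.random((n, p)) < spec.missing_rate] = np.nan

    # Covariates: independent given class.
    rng_cov = child_rng(spec.seed, "covariates")
    cov_cols: dict[str, np.ndarray] = {}
    for name, cv in spec.covariate_effects.items():
        if isinstance(cv, BinaryCovariate):
            rate = np.where(pos, cv.rate_pos, cv.rate_neg)
            cov_cols[name] = (rng_cov.random(n) < rate).astype(int)
        elif isinstance(cv, ContinuousCovariate):
            mean = np.where(pos, cv.mean_pos, cv.mean_neg)
            sd = np.where(pos, cv.sd_pos, cv.sd_neg)
            vals = rng_cov.standard_normal(n) * sd + mean
            cov_cols[name] = vals
            if cv.threshold is not None:
                cov_cols[cv.threshold_name or f"{name}_ge_{cv.threshold:g}"] = (
                    vals >= cv.threshold
                ).astype(int)
        else:
            raise TypeError(f"unsupported covariate spec for {name!r}: {type(cv)}")

    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")
    return Cohort(
        features=pd.DataFrame(X, index=ids, columns=meta.index),
        label=pd.Series(label, index=ids, name="label"),
        sex=pd.Series(sex, index=ids, name="sex"),
        covariates=pd.DataFrame(cov_cols, index=ids),
        feature_meta=meta,
        role=pd.Series(role, index=ids, name="role"),
    )


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Demographics-and-disease table: per-class summaries with p-values.

    Continuous covariates are summarised as mean +/- SD and compared with
    Welch's t-test; categorical covariates (including sex) as percentages
    compared with a chi-square test of the 2x2 contingency table.
    """
    y = cohort.label.to_numpy()
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("cohort_summary requires both classes to be present")

    rows = []
    rows.append(
        {
            "characteristic": "n_subjects",
            "cad_neg": float((y == 0).sum()),
            "cad_pos": float((y == 1).sum()),
            "kind": "count",
            "p_value": np.nan,
        }
    )

    def add_categorical(name: str, values: np.ndarray) -> None:
        tab = pd.crosstab(values, y)
        if tab.shape == (2, 2):
            _, pval, _, _ = stats.chi2_contingency(tab.to_numpy())
        else:
            pval = np.nan
        rows.append(
            {
                "characteristic": name,
                "cad_neg": 100.0 * values[y == 0].mean(),
                "cad_pos": 100.0 * values[y == 1].mean(),
                "kind": "percent",
                "p_value": pval,
            }
        )

    def add_continuous(name: str, values: np.ndarray) -> None:
        a, b = values[y == 0], values[y == 1]
        _, pval = stats.ttest_ind(b, a, equal_var=False)
        rows.append(
            {
                "characteristic": name,
                "cad_neg": a.mean(),
                "cad_pos": b.mean(),
                "cad_neg_sd": a.std(ddof=1),
                "cad_pos_sd": b.std(ddof=1),
                "kind": "mean_sd",
                "p_value": pval,
            }
        )

    add_categorical("female", cohort.sex.to_numpy())
    for name in cohort.covariates.columns:
        vals = cohort.covariates[name].to_numpy()
        if set(np.unique(vals[~np.isnan(vals.astype(float))])) <= {0.0, 1.0}:
            add_categorical(name, vals.astype(float))
        else:
            add_continuous(name, vals.astype(float))

    return pd.DataFrame(rows).set_index("characteristic")


# ---------------------------------------------------------------------------
# CSV interchange: features.csv, subjects.csv, feature_meta.csv

def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": directory / "features.csv",
        "subjects": directory / "subjects.csv",
        "feature_meta": directory / "feature_meta.csv",
    }
    cohort.features.to_csv(paths["features"])
    subjects = pd.concat([cohort.label, cohort.sex, cohort.role, cohort.covariates], axis=1)
    subjects.to_csv(paths["subjects"])
    cohort.feature_meta.to_csv(paths["feature_meta"])
    return paths


def read_cohort(directory: str | Path, allow_missing: bool = False) -> Cohort:
    """Load a cohort from the three-CSV interchange layout, validating it.

    Raises ``ValueError`` on missing feature values (with per-column counts),
    non-binary labels, or duplicate subject ids, unless ``allow_missing``.
    """
    directory = Path(directory)
    features = pd.read_csv(directory / "features.csv", index_col="subject_id")
    features.columns.name = "feature_id"
    subjects = pd.read_csv(directory / "subjects.csv", index_col="subject_id")
    # keep_default_na: the feature role "null" is a value, not a missing cell
    meta = pd.read_csv(directory / "feature_meta.csv", index_col="feature_id", keep_default_na=False)

    if features.index.has_duplicates:
        dupes = features.index[features.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids in features.csv: {dupes[:5]}")
    if not allow_missing:
        na_counts = features.isna().sum()
        na_counts = na_counts[na_counts > 0]
        if len(na_counts):
            detail = ", ".join(f"{c}: {int(k)}" for c, k in na_counts.items())
            raise ValueError(f"missing feature values ({detail})")
    label = subjects["label"]
    if not set(label.unique()) <= {0, 1}:
        raise ValueError(f"label column is not binary 0/1: values {sorted(label.unique())}")
    role = subjects["role"] if "role" in subjects else None
    cov = subjects.drop(columns=[c for c in ("label", "sex", "role") if c in subjects])
    return Cohort(
        features=features,
        label=label,
        sex=subjects["sex"],
        covariates=cov,
        feature_meta=meta,
        role=role,
    )
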