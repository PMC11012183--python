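"""Univariate triple-test feature screening on a sex-balanced subset.

Each candidate feature is assessed on a balanced subset (equal numbers of
females and males within each disease class) by three independent univariate
tests, and survives screening if it passes at least one:

* **t-test** — Welch two-sample t-test, pass when p < 0.01. Detects linear
  (mean-shift) separation, the kind a linear model exploits.
* **ROC-AUC** — rank AUC with a 95% percentile-bootstrap confidence interval,
  resampling subjects with replacement within class. Pass when the lower
  bound exceeds 0.52, or — for inversely predictive features — when the upper
  bound falls below 0.48.
* **mutual information** — histogram MI between the discretized feature and
  the label, normalized by its mean under label permutation so that 1.0 means
  independence. Pass when the 95% bootstrap lower bound of that ratio exceeds
  1.2. Detects distributional differences (e.g. unequal spread) with equal
  means, which the t-test cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .cohort import Cohort

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "build_balanced_subset",
    "screen_t",
    "screen_auc",
    "screen_mi",
    "select_features",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and resampling sizes for the triple screen."""

    p_threshold: float = 0.01
    auc_lower_bound: float = 0.52
    auc_inverse_bound: float = 0.48
    mi_ratio_bound: float = 1.2
    confidence: float = 0.95
    n_bootstrap: int = 1000
    n_permutation: int = 200
    mi_bins: int = 10
    per_cell: int = 104
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not self.auc_inverse_bound < 0.5 < self.auc_lower_bound:
            raise ValueError("need auc_inverse_bound < 0.5 < auc_lower_bound")
        if self.mi_ratio_bound <= 1.0:
            raise ValueError("mi_ratio_bound must exceed 1 (1.0 means independence)")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.per_cell < 2:
            raise ValueError("per_cell must be >= 2")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


class TTestResult(NamedTuple):
    p_value: float
    passed: bool


class AucResult(NamedTuple):
    auc_point: float
    lower_ci: float
    upper_ci: float
    passed: bool


class MiResult(NamedTuple):
    mi_ratio: float
    mi_ratio_lower_ci: float
    passed: bool


@dataclass
class ScreenResult:
    """Per-feature statistics, pass flags, and the selected feature list."""

    table: pd.DataFrame
    selected: list[str]
    combo_counts: dict[str, int]
    config: ScreenConfig
    subset_index: pd.Index = field(repr=False, default=None)

    def __post_init__(self) -> None:
        any_pass = self.table[["pass_t", "pass_auc", "pass_mi"]].any(axis=1)
        if list(self.table.index[any_pass]) != list(self.selected):
            raise ValueError("selected list inconsistent with pass flags")
        if sum(self.combo_counts.values()) != len(self.selected):
            raise ValueError("combo_counts do not sum to |selected|")

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_json_sidecar(self, path) -> None:
        import dataclasses
        import json

        payload = {
            "config": dataclasses.asdict(self.config),
            "n_selected": len(self.selected),
            "combo_counts": self.combo_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_balanced_subset(cohort: Cohort, per_cell: int = 104, seed: int = 0) -> pd.Index:
    """Sample ``per_cell`` subjects without replacement from each sex-by-class
    cell among screening-eligible subjects.

    Returns the subject index of the balanced subset (``4 * per_cell`` ids).
    Raises ``ValueError`` naming the first deficient cell.
    """
    eligible = cohort.screening_eligible()
    sex = cohort.sex.loc[eligible]
    label = cohort.label.loc[eligible]
    rng = child_rng(seed, "balanced_subset")
    chosen: list[np.ndarray] = []
    for lab, sx, name in [
        (0, 1, "female CAD-"),
        (0, 0, "male CAD-"),
        (1, 1, "female CAD+"),
        (1, 0, "male CAD+"),
    ]:
        cell = eligible[(label == lab) & (sex == sx)]
        if len(cell) < per_cell:
            raise ValueError(
                f"cell '{name}' has only {len(cell)} screening-eligible subjects, "
                f"need per_cell={per_cell}"
            )
        take = rng.choice(len(cell), size=per_cell, replace=False)
        chosen.append(cell.to_numpy()[np.sort(take)])
    return pd.Index(np.concatenate(chosen), name=eligible.name)


def _check_classes(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    if np.isnan(values).any():
        raise ValueError("missing values are not allowed in screening")
    x1, x0 = values[labels == 1], values[labels == 0]
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both classes must be non-empty")
    return x1, x0


def screen_t(values, labels, p_threshold: float = 0.01) -> TTestResult:
    """Welch two-sample t-test; degenerate equal-constant classes give p = 1."""
    x1, x0 = _check_classes(values, labels)
    if np.std(x1) == 0 and np.std(x0) == 0:
        p = 1.0 if np.mean(x1) == np.mean(x0) else 0.0
    else:
        _, p = stats.ttest_ind(x1, x0, equal_var=False)
        p = float(p)
        if np.isnan(p):
            p = 1.0
    return TTestResult(p, bool(p < p_threshold))


def _rank_auc(x1: np.ndarray, x0: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted half."""
    n1, n0 = len(x1), len(x0)
    ranks = stats.rankdata(np.concatenate([x1, x0]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _rank_auc_rows(x1: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matrices of bootstrap resamples (B x n1, B x n0)."""
    n1 = x1.shape[1]
    n0 = x0.shape[1]
    ranks = stats.rankdata(np.concatenate([x1, x0], axis=1), axis=1)
    return (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)


def screen_auc(values, labels, config: ScreenConfig, rng: np.random.Generator | None = None) -> AucResult:
    """Rank AUC with a within-class percentile-bootstrap CI.

    Passes when the lower bound clears ``auc_lower_bound`` or, via the inverse
    branch, when the upper bound stays below ``auc_inverse_bound``.
    """
    if config.n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    x1, x0 = _check_classes(values, labels)
    if rng is None:
        rng = child_rng(config.seed, "auc")
    point = _rank_auc(x1, x0)
    B = config.n_bootstrap
    b1 = x1[rng.integers(0, len(x1), size=(B, len(x1)))]
    b0 = x0[rng.integers(0, len(x0), size=(B, len(x0)))]
    aucs = _rank_auc_rows(b1, b0)
    alpha = 1.0 - config.confidence
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    passed = bool(lo > config.auc_lower_bound or hi < config.auc_inverse_bound)
    return AucResult(point, float(lo), float(hi), passed)


def _discretize(values: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Equal-frequency binning; returns integer codes and the bin count."""
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    codes = np.searchsorted(edges, values, side="right")
    return codes, len(edges) + 1


def _histogram_mi(codes: np.ndarray, labels: np.ndarray, n_codes: int) -> float:
    """Plug-in MI (nats) of a discrete variable against binary labels."""
    n = len(codes)
    joint = np.zeros((n_codes, 2))
    np.add.at(joint, (codes, labels), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def _histogram_mi_rows(codes: np.ndarray, labels: np.ndarray, n_codes: int) -> np.ndarray:
    """Row-wise plug-in MI for a (B x n) matrix of code rows against per-row labels."""
    B, n = codes.shape
    flat = (np.arange(B)[:, None] * (n_codes * 2) + codes * 2 + labels).ravel()
    joint = np.bincount(flat, minlength=B * n_codes * 2).reshape(B, n_codes, 2) / n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return np.nansum(terms, axis=(1, 2))


def screen_mi(values, labels, config: ScreenConfig, rng: np.random.Generator | None = None) -> MiResult:
    """Permutation-normalized mutual information screen.

    The raw histogram MI is biased upward at finite n even under
    independence, so it is divided by its mean over ``n_permutation`` label
    permutations; the resulting ratio equals 1 in expectation under
    independence. A within-class bootstrap of the numerator (the null mean is
    held fixed) yields the lower confidence bound compared against
    ``mi_ratio_bound``. Constant features give ratio 0 and fail.
    """
    if config.n_permutation < 100:
        raise ValueError("n_permutation must be >= 100")
    x1, x0 = _check_classes(values, labels)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if rng is None:
        rng = child_rng(config.seed, "mi")

    codes, n_codes = _discretize(values, config.mi_bins)
    if n_codes < 2:
        return MiResult(0.0, 0.0, False)

    mi_obs = _histogram_mi(codes, labels, n_codes)

    P = config.n_permutation
    perm_labels = np.array([rng.permutation(labels) for _ in range(P)])
    null_mis = _histogram_mi_rows(np.broadcast_to(codes, (P, len(codes))), perm_labels, n_codes)
    null_mean = float(null_mis.mean())
    if null_mean <= 0:
        return MiResult(0.0, 0.0, False)

    # Bootstrap the numerator within class; the permutation-null mean is a
    # property of the sample design and is held fixed across resamples.
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    B = config.n_bootstrap
    take1 = idx1[rng.integers(0, len(idx1), size=(B, len(idx1)))]
    take0 = idx0[rng.integers(0, len(idx0), size=(B, len(idx0)))]
    boot_idx = np.concatenate([take1, take0], axis=1)
    boot_codes = codes[boot_idx]
    boot_labels = labels[boot_idx]
    boot_mis = _histogram_mi_rows(boot_codes, boot_labels, n_codes)
    # Within-class pair resampling inflates plug-in MI even under
    # independence; recentre the bootstrap distribution on the observed MI
    # (bootstrap bias correction) before taking the percentile bound.
    boot_mis = boot_mis - (boot_mis.mean() - mi_obs)
    ratios = boot_mis / null_mean
    lo = float(np.quantile(ratios, 1.0 - config.confidence))
    ratio = mi_obs / null_mean
    return MiResult(float(ratio), lo, bool(lo > config.mi_ratio_bound))


_COMBO_NAMES = {
    (True, False, False): "t_only",
    (False, True, False): "auc_only",
    (False, False, True): "mi_only",
    (True, True, False): "t+auc",
    (True, False, True): "t+mi",
    (False, True, True): "auc+mi",
    (True, True, True): "t+auc+mi",
}


def select_features(cohort: Cohort, subset: pd.Index, config: ScreenConfig) -> ScreenResult:
    """Run all three screens on every feature over the balanced subset only.

    A feature is selected if it passes at least one test. Bootstrap and
    permutation streams are seeded per feature from the config seed and the
    feature's column position, so results are independent of evaluation order.
    """
    if cohort.n_features < 1:
        raise ValueError("cohort has no features")
    if not subset.isin(cohort.features.index).all():
        raise ValueError("subset contains subjects not in the cohort")
    labels = cohort.label.loc[subset].to_numpy().astype(int)
    X = cohort.features.loc[subset]

    records = []
    for j, fid in enumerate(X.columns):
        values = X[fid].to_numpy()
        t_res = screen_t(values, labels, config.p_threshold)
        auc_res = screen_auc(values, labels, config, rng=child_rng(config.seed, "auc", j))
        mi_res = screen_mi(values, labels, config, rng=child_rng(config.seed, "mi", j))
        records.append(
            {
                "feature_id": fid,
                "t_p_value": t_res.p_value,
                "auc_point": auc_res.auc_point,
                "auc_lower_ci": auc_res.lower_ci,
                "auc_upper_ci": auc_res.upper_ci,
                "mi_ratio": mi_res.mi_ratio,
                "mi_ratio_lower_ci": mi_res.mi_ratio_lower_ci,
                "pass_t": t_res.passed,
                "pass_auc": auc_res.passed,
                "pass_mi": mi_res.passed,
            }
        )
    table = pd.DataFrame(records).set_index("feature_id")
    any_pass = table[["pass_t", "pass_auc", "pass_mi"]].any(axis=1)
    selected = list(table.index[any_pass])
    combos: dict[str, int] = {}
    for fid in selected:
        key = _COMBO_NAMES[
            (
                bool(table.at[fid, "pass_t"]),
                bool(table.at[fid, "pass_auc"]),
                bool(table.at[fid, "pass_mi"]),
            )
        ]
        combos[key] = combos.get(key, 0) + 1
    if not selected:
        import warnings

        warnings.warn("no features passed screening", stacklevel=2)
    return ScreenResult(table=table, selected=selected, combo_counts=combos, config=config, subset_index=subset)
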