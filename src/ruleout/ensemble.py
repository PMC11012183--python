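"""Out-of-fold training of a bagged elastic-net + random-forest stack.

The modelling engine treats disease prediction as regression on {0, 1}
labels. One *stacked model* is the arithmetic mean of an elastic-net linear
model (l1 + l2 penalised, features standardized on its training split) and a
random-forest regressor (squared-error splits), both fitted with per-subject
sample weights that equalize the total weighted mass of the four
sex-by-disease cells.

Repeated stratified k-fold cross-validation produces *out-of-fold* (OOF)
predictions: in each of ``n_iterations`` iterations a fresh seeded fold split
is drawn, k stacks are trained (one per training split) and every subject is
scored by the single model whose training excluded them. The per-subject OOF
score is the mean of its naive predictions across iterations. All
``k * n_iterations`` trained stacks are retained in a :class:`ModelBank`; a
new subject's score is the median (by default) of all bank members'
predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ._rng import child_int_seed
from .cohort import Cohort

__all__ = [
    "TrainConfig",
    "StackModel",
    "ModelBank",
    "OofResult",
    "compute_sample_weights",
    "stratified_folds",
    "train_stack",
    "run_oof",
    "predict_bank",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the OOF bagged-stack engine.

    ``en_penalty_strength`` of ``None`` selects the elastic-net alpha by
    internal 3-fold cross-validation on each training split (no test-fold
    leakage); a float fixes it, which is much faster for large banks.
    """

    k_folds: int = 5
    n_iterations: int = 100
    en_l1_ratio: float = 0.5
    en_penalty_strength: float | None = None
    en_cv_folds: int = 3
    rf_n_trees: int = 500
    rf_min_leaf: int = 5
    stack_rule: Literal["mean"] = "mean"
    bank_compression: Literal["median", "mean"] = "median"
    use_sample_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.en_l1_ratio <= 1.0:
            raise ValueError("en_l1_ratio must lie in [0, 1]")
        if self.en_penalty_strength is not None and self.en_penalty_strength < 0:
            raise ValueError("en_penalty_strength must be non-negative")
        if self.rf_n_trees < 1 or self.rf_min_leaf < 1:
            raise ValueError("random-forest sizes must be positive")
        if self.bank_compression not in ("median", "mean"):
            raise ValueError("bank_compression must be 'median' or 'mean'")

    @property
    def n_models(self) -> int:
        return self.k_folds * self.n_iterations


def compute_sample_weights(label, sex) -> np.ndarray:
    """Inverse-frequency weights over the four sex-by-disease cells.

    A subject in cell ``c`` receives weight ``N / (4 * n_c)``, so every cell
    carries total weighted mass ``N / 4``: the learner sees a population
    balanced in both disease and sex. Raises on an empty cell, naming it.
    """
    label = np.asarray(label).astype(int)
    sex = np.asarray(sex).astype(int)
    n = len(label)
    weights = np.empty(n, dtype=float)
    for lab, sx, name in [(0, 0, "male CAD-"), (0, 1, "female CAD-"), (1, 0, "male CAD+"), (1, 1, "female CAD+")]:
        mask = (label == lab) & (sex == sx)
        n_c = int(mask.sum())
        if n_c == 0:
            raise ValueError(f"sex-by-disease cell '{name}' is empty")
        weights[mask] = n / (4.0 * n_c)
    return weights


def stratified_folds(label, k: int, seed: int = 0) -> np.ndarray:
    """Label-stratified fold assignment (0..k-1) for every subject.

    Per-fold class counts differ from exact proportionality by at most one.
    """
    label = np.asarray(label).astype(int)
    classes, counts = np.unique(label, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small} has only {counts.min()} subjects, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    assignment = np.empty(len(label), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(label)), label)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class StackModel:
    """Mean-stack of one elastic net and one random forest.

    The elastic net carries its own feature scaler fitted on the training
    split (the penalty is scale-sensitive; the forest is not and sees raw
    features).
    """

    scaler: StandardScaler
    en: ElasticNet
    rf: RandomForestRegressor
    feature_ids: tuple[str, ...]
    iteration: int = -1
    fold: int = -1
    train_subjects: tuple[str, ...] = field(default=(), repr=False)

    def _check(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_ids if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing[:5]}")
            X = X[list(self.feature_ids)].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_ids):
            raise ValueError(f"expected {len(self.feature_ids)} features, got {X.shape[1]}")
        return X

    def predict_parts(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = self._check(X)
        return self.en.predict(self.scaler.transform(X)), self.rf.predict(X)

    def predict(self, X) -> np.ndarray:
        en_pred, rf_pred = self.predict_parts(X)
        return (en_pred + rf_pred) / 2.0


def train_stack(
    features: pd.DataFrame | np.ndarray,
    label,
    weights=None,
    config: TrainConfig = TrainConfig(),
    *,
    feature_ids: Sequence[str] | None = None,
    model_seed: int = 0,
) -> StackModel:
    """Fit one EN + RF stack on {0,1}-encoded labels with sample weights."""
    if isinstance(features, pd.DataFrame):
        feature_ids = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        feature_ids = tuple(feature_ids) if feature_ids is not None else tuple(f"x{j}" for j in range(X.shape[1]))
    y = np.asarray(label, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if weights is None:
        weights = np.ones(len(y))
    weights = np.asarray(weights, dtype=float)

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if config.en_penalty_strength is None and len(np.unique(y)) > 1:
        en = ElasticNetCV(
            l1_ratio=config.en_l1_ratio,
            alphas=np.logspace(-4, 0, 12),
            cv=config.en_cv_folds,
            random_state=model_seed % (2**31),
        )
    else:
        alpha = config.en_penalty_strength if config.en_penalty_strength is not None else 0.01
        en = ElasticNet(l1_ratio=config.en_l1_ratio, alpha=max(alpha, 1e-12))
    en.fit(Xs, y, sample_weight=weights)

    rf = RandomForestRegressor(
        n_estimators=config.rf_n_trees,
        min_samples_leaf=config.rf_min_leaf,
        max_features="sqrt",
        criterion="squared_error",
        random_state=model_seed % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y, sample_weight=weights)
    return StackModel(scaler=scaler, en=en, rf=rf, feature_ids=feature_ids)


@dataclass
class ModelBank:
    """All stacked models trained across OOF iterations, with provenance."""

    models: list[StackModel]
    feature_ids: tuple[str, ...]
    config: TrainConfig

    def __len__(self) -> int:
        return len(self.models)

    def manifest(self) -> dict:
        import dataclasses

        return {
            "n_models": len(self.models),
            "feature_ids": list(self.feature_ids),
            "config": dataclasses.asdict(self.config),
            "models": [
                {"iteration": m.iteration, "fold": m.fold, "n_train": len(m.train_subjects)}
                for m in self.models
            ],
        }

    def save(self, directory: str | Path) -> None:
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
        joblib.dump(self.models, directory / "models.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBank":
        import joblib

        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        models = joblib.load(directory / "models.joblib")
        return cls(
            models=models,
            feature_ids=tuple(manifest["feature_ids"]),
            config=TrainConfig(**manifest["config"]),
        )


@dataclass
class OofResult:
    """Naive per-subject predictions from repeated cross-validation."""

    oof_score: pd.Series
    en_oof_score: pd.Series
    rf_oof_score: pd.Series
    per_iteration: pd.DataFrame  # subjects x iterations, stacked predictions

    def to_csv(self, path) -> None:
        pd.concat(
            [
                self.oof_score.rename("oof_score"),
                self.en_oof_score.rename("en_oof_score"),
                self.rf_oof_score.rename("rf_oof_score"),
            ],
            axis=1,
        ).to_csv(path)


def run_oof(
    cohort: Cohort,
    selected_features: Sequence[str],
    config: TrainConfig = TrainConfig(),
    *,
    folds_per_iteration: Sequence[np.ndarray] | None = None,
) -> tuple[ModelBank, OofResult]:
    """Repeated stratified OOF training over the modelling-eligible subjects.

    For each iteration a fresh seeded fold split is drawn (unless
    ``folds_per_iteration`` supplies explicit assignments), k stacks are
    trained with sample weights recomputed on each training split, and every
    subject is predicted by the model whose training excluded it. Returns the
    full bank of ``k * n_iterations`` models and the averaged OOF scores.
    """
    selected_features = list(selected_features)
    if not selected_features:
        raise ValueError("selected_features must be non-empty")
    idx = cohort.modelling_eligible()
    X = cohort.features.loc[idx, selected_features]
    y = cohort.label.loc[idx].to_numpy().astype(int)
    sex = cohort.sex.loc[idx].to_numpy().astype(int)
    n = len(idx)

    stack_preds = np.empty((n, config.n_iterations))
    en_preds = np.empty((n, config.n_iterations))
    rf_preds = np.empty((n, config.n_iterations))
    models: list[StackModel] = []

    X_np = X.to_numpy(dtype=float)
    for it in range(config.n_iterations):
        if folds_per_iteration is not None:
            assignment = np.asarray(folds_per_iteration[it])
            if len(assignment) != n:
                raise ValueError("fold assignment length mismatch")
        else:
            fold_seed = child_int_seed(config.seed, "folds", it)
            assignment = stratified_folds(y, config.k_folds, seed=fold_seed)
        for fold in range(config.k_folds):
            test_mask = assignment == fold
            train_mask = ~test_mask
            w = (
                compute_sample_weights(y[train_mask], sex[train_mask])
                if config.use_sample_weights
                else None
            )
            model = train_stack(
                X_np[train_mask],
                y[train_mask],
                w,
                config,
                feature_ids=selected_features,
                model_seed=child_int_seed(config.seed, "model", it, fold),
            )
            model.iteration = it
            model.fold = fold
            model.train_subjects = tuple(idx[train_mask])
            models.append(model)
            en_p, rf_p = model.predict_parts(X_np[test_mask])
            en_preds[test_mask, it] = en_p
            rf_preds[test_mask, it] = rf_p
            stack_preds[test_mask, it] = (en_p + rf_p) / 2.0

    bank = ModelBank(models=models, feature_ids=tuple(selected_features), config=config)
    result = OofResult(
        oof_score=pd.Series(stack_preds.mean(axis=1), index=idx, name="oof_score"),
        en_oof_score=pd.Series(en_preds.mean(axis=1), index=idx, name="en_oof_score"),
        rf_oof_score=pd.Series(rf_preds.mean(axis=1), index=idx, name="rf_oof_score"),
        per_iteration=pd.DataFrame(stack_preds, index=idx, columns=[f"iter_{i:03d}" for i in range(config.n_iterations)]),
    )
    return bank, result


def predict_bank(bank: ModelBank, features: pd.DataFrame | np.ndarray, compression: str | None = None) -> np.ndarray:
    """Score new subjects through the whole bagged ensemble.

    Every stored stack predicts every subject; predictions are compressed
    across models by the bank's configured reducer (median by default).
    """
    if isinstance(features, pd.DataFrame):
        missing = [f for f in bank.feature_ids if f not in features.columns]
        extra = [f for f in features.columns if f not in bank.feature_ids]
        if missing or extra:
            raise ValueError(f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}")
        features = features[list(bank.feature_ids)]
    compression = compression or bank.config.bank_compression
    all_preds = np.stack([m.predict(features) for m in bank.models], axis=0)
    if compression == "median":
        return np.median(all_preds, axis=0)
    if compression == "mean":
        return all_preds.mean(axis=0)
    raise ValueError(f"unknown compression {compression!r}")
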