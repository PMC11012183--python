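"""End-to-end pipeline orchestration with YAML configuration.

``run_pipeline`` executes generate/load -> balanced subset -> screening ->
OOF ensemble training -> cut-point calibration -> evaluation, writing every
intermediate artifact plus a run manifest (config, seed, library versions,
stage checksums) to the output directory. Identical config + seed gives
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, FeatureCounts, cohort_summary, generate_cohort, read_cohort, write_cohort
from .ensemble import TrainConfig
from .evaluation import PerformanceReport
from .model import RuleOutModel
from .screening import ScreenConfig

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("ruleout")


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Either ``cohort_spec`` (synthetic generation) or ``cohort_dir`` (CSV
    input per the cohort interchange layout) must be provided.
    """

    cohort_spec: CohortSpec | None = None
    cohort_dir: str | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    target_sensitivity: float = 0.90
    prevalences: tuple[float, ...] = (0.038, 0.10, 0.20, 0.30)
    category_importance: bool = False
    importance_max_models: int = 50
    importance_n_perm: int = 3
    out_dir: str = "ruleout_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort_spec is None and self.cohort_dir is None:
            raise ValueError("provide either cohort_spec or cohort_dir")
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise ValueError(f"cohort_dir does not exist: {self.cohort_dir}")


def _build_nested(section: dict, cls):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file into a validated :class:`PipelineConfig`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "cohort_spec" in raw:
        section = dict(raw.pop("cohort_spec") or {})
        if "features_per_category" in section:
            section["features_per_category"] = {
                cat: FeatureCounts(**counts) for cat, counts in section["features_per_category"].items()
            }
        kwargs["cohort_spec"] = _build_nested(section, CohortSpec)
    if "screen" in raw:
        kwargs["screen"] = _build_nested(dict(raw.pop("screen") or {}), ScreenConfig)
    if "train" in raw:
        kwargs["train"] = _build_nested(dict(raw.pop("train") or {}), TrainConfig)
    if "prevalences" in raw:
        raw["prevalences"] = tuple(raw["prevalences"])
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _library_versions() -> dict[str, str]:
    import sklearn
    import scipy
    import statsmodels

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: PipelineConfig) -> PerformanceReport:
    """Execute all stages, persisting artifacts and a manifest under
    ``config.out_dir``; returns the final :class:`PerformanceReport`."""
    logging.basicConfig(level=config.log_level, stream=sys.stderr, force=False)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    manifest: dict = {"seed": config.seed, "versions": _library_versions(), "stages": {}, "checksums": {}}

    def fail(stage: str, err: Exception):
        logger.error("stage %s failed: %s", stage, err)
        manifest["stages"][stage] = f"failed: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    try:
        if config.cohort_spec is not None:
            spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
            cohort = generate_cohort(spec)
            manifest["stages"]["cohort"] = f"generated n={cohort.n_subjects}, p={cohort.n_features}"
        else:
            cohort = read_cohort(config.cohort_dir)
            manifest["stages"]["cohort"] = f"loaded from {config.cohort_dir}"
        paths = write_cohort(cohort, out / "cohort")
        cohort_summary(cohort).to_csv(out / "cohort_summary.csv")
    except Exception as err:  # noqa: BLE001
        fail("cohort", err)
    logger.info("cohort ready: %d subjects, %d features", cohort.n_subjects, cohort.n_features)

    screen_cfg = dataclasses.replace(config.screen, seed=config.seed)
    train_cfg = dataclasses.replace(config.train, seed=config.seed)
    model = RuleOutModel(
        cohort,
        screen_config=screen_cfg,
        train_config=train_cfg,
        target_sensitivity=config.target_sensitivity,
    )

    try:
        results = model.fit()
    except Exception as err:  # noqa: BLE001
        fail("fit", err)

    try:
        if results.screen_result is not None:
            results.screen_result.to_csv(out / "screen_result.csv")
            results.screen_result.to_json_sidecar(out / "screen_result.json")
            pd.Series(results.screen_result.subset_index).to_csv(out / "balanced_subset.csv", index=False)
            manifest["stages"]["screen"] = f"selected {len(results.selected_features)} features"
        results.oof.to_csv(out / "oof_scores.csv")
        results.bank.save(out / "model_bank")
        results.cut_points.to_json(out / "cut_points.json")
        manifest["stages"]["train"] = f"{len(results.bank)} models in bank"
    except Exception as err:  # noqa: BLE001
        fail("persist", err)

    try:
        report = results.performance_report(
            prevalences=config.prevalences,
            include_adjusted_or=True,
            include_category_importance=config.category_importance,
            importance_kwargs={
                "max_models": config.importance_max_models,
                "n_perm": config.importance_n_perm,
                "seed": config.seed,
            },
        )
        report.to_json(out / "performance_report.json")
        (out / "performance_report.txt").write_text(report.text_report() + "\n")
        (out / "summary.txt").write_text(results.summary() + "\n")
    except Exception as err:  # noqa: BLE001
        fail("evaluate", err)

    for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json")):
        manifest["checksums"][str(p.relative_to(out))] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.removeHandler(fh)
    fh.close()
    return report
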