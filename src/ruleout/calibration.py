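"""Per-sex cut-point selection at a target sensitivity, with score zeroing.

A rule-out test must catch nearly all diseased subjects, so the decision
threshold is chosen per sex as the largest score value (among observed
diseased scores) at which sensitivity still reaches the target — i.e. the
most specific threshold compatible with the sensitivity constraint. The
chosen cut point is then subtracted from each subject's score so that zero
delineates test-negative (below) from test-positive (at or above); a score
exactly at the cut counts as positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CutPoints", "select_cut_point", "fit_cut_points", "apply_cut_points"]


def select_cut_point(scores, label, target: float = 0.90) -> float:
    """Largest observed positive score ``t`` with ``P(score >= t | CAD+) >= target``.

    Candidates are restricted to the observed diseased scores; among all
    thresholds meeting the sensitivity constraint this is the one with
    maximal specificity.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target sensitivity must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    label = np.asarray(label).astype(int)
    pos = scores[label == 1]
    if len(pos) == 0:
        raise ValueError("no diseased subjects to calibrate on")
    pos_sorted = np.sort(pos)[::-1]
    # Smallest count of positives at/above threshold that satisfies target.
    k = int(np.ceil(target * len(pos) - 1e-12))
    k = max(k, 1)
    return float(pos_sorted[k - 1])


@dataclass
class CutPoints:
    """Sex-specific thresholds with achieved calibration metrics."""

    target_sensitivity: float
    threshold_by_sex: dict[int, float]
    achieved: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        for sx, metrics in self.achieved.items():
            if metrics["sensitivity"] < self.target_sensitivity - 1e-12:
                raise ValueError(
                    f"achieved sensitivity {metrics['sensitivity']:.4f} for sex={sx} "
                    f"below target {self.target_sensitivity}"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_sensitivity": self.target_sensitivity,
            "threshold_by_sex": {str(k): v for k, v in self.threshold_by_sex.items()},
            "achieved": {str(k): v for k, v in self.achieved.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CutPoints":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            target_sensitivity=payload["target_sensitivity"],
            threshold_by_sex={int(k): v for k, v in payload["threshold_by_sex"].items()},
            achieved={int(k): v for k, v in payload["achieved"].items()},
        )


def fit_cut_points(scores, label, sex, target: float = 0.90) -> CutPoints:
    """Select a cut point per sex on calibration scores and record the
    achieved per-sex sensitivity/specificity at that cut."""
    scores = np.asarray(scores, dtype=float)
    label = np.asarray(label).astype(int)
    sex = np.asarray(sex).astype(int)
    thresholds: dict[int, float] = {}
    achieved: dict[int, dict[str, float]] = {}
    for sx in sorted(np.unique(sex)):
        mask = sex == sx
        t = select_cut_point(scores[mask], label[mask], target)
        thresholds[int(sx)] = t
        pos = mask & (label == 1)
        neg = mask & (label == 0)
        sens = float((scores[pos] >= t).mean()) if pos.any() else float("nan")
        spec = float((scores[neg] < t).mean()) if neg.any() else float("nan")
        achieved[int(sx)] = {"sensitivity": sens, "specificity": spec}
    return CutPoints(target_sensitivity=target, threshold_by_sex=thresholds, achieved=achieved)


def apply_cut_points(scores, sex, cut_points: CutPoints) -> tuple[np.ndarray, np.ndarray]:
    """Zero the scores at each sex's cut point.

    Returns ``(zeroed_scores, test_result)`` where ``zeroed = score -
    threshold[sex]`` and ``test_result = 1`` iff the zeroed score is >= 0.
    """
    scores = np.asarray(scores, dtype=float)
    sex = np.asarray(sex).astype(int)
    unknown = set(np.unique(sex)) - set(cut_points.threshold_by_sex)
    if unknown:
        raise ValueError(f"no cut point for sex categories {sorted(unknown)}")
    offsets = np.array([cut_points.threshold_by_sex[int(s)] for s in sex])
    zeroed = scores - offsets
    return zeroed, (zeroed >= 0).astype(int)
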