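"""Plots mirroring the standard figures of rule-out test development:
per-sex ROC curves, score distributions by sex/disease cell before and after
cut-point zeroing, and category importance bars."""

from __future__ import annotations

import numpy as np

from .evaluation import roc_auc, roc_coordinates


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_roc(results, ax=None):
    ax = _get_ax(ax)
    idx = results.eval_index
    label = results.cohort.label.loc[idx].to_numpy()
    sex = results.cohort.sex.loc[idx].to_numpy()
    zeroed, _ = results.zeroed_scores()
    for name, mask, color in [
        ("both sexes", np.ones(len(idx), bool), "tab:blue"),
        ("male", sex == 0, "tab:orange"),
        ("female", sex == 1, "tab:green"),
    ]:
        coords = roc_coordinates(zeroed[mask], label[mask])
        auc = roc_auc(zeroed[mask], label[mask])
        ax.plot(coords["fpr"], coords["tpr"], color=color, label=f"{name} (AUC = {auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_score_distributions(results, ax=None, zeroed: bool = True):
    ax = _get_ax(ax)
    idx = results.eval_index
    label = results.cohort.label.loc[idx].to_numpy()
    sex = results.cohort.sex.loc[idx].to_numpy()
    scores = results.zeroed_scores()[0] if zeroed else results.oof.oof_score.to_numpy()
    cells = [
        ("female CAD+", (label == 1) & (sex == 1), "tab:red"),
        ("male CAD+", (label == 1) & (sex == 0), "tab:orange"),
        ("female CAD-", (label == 0) & (sex == 1), "tab:green"),
        ("male CAD-", (label == 0) & (sex == 0), "tab:blue"),
    ]
    for name, mask, color in cells:
        if mask.any():
            ax.hist(scores[mask], bins=30, histtype="step", density=True, label=name, color=color)
    if zeroed:
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("zeroed score" if zeroed else "raw OOF score")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_category_importance(share, ax=None):
    ax = _get_ax(ax)
    share = share.sort_values()
    ax.barh(share.index, 100 * share.to_numpy(), color="tab:blue")
    ax.set_xlabel("importance share (%)")
    return ax
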