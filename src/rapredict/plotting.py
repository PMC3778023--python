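"""Figure exports: ROC curves, ordered risk distributions, category bars,
Kaplan–Meier onset curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import km_curve

__all__ = ["roc_plot", "ordered_risk_plot", "category_bar_plot", "km_plot"]


def _roc_points(cases: np.ndarray, controls: np.ndarray):
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [(cases >= t).mean() for t in thresholds]
    fpr = [(controls >= t).mean() for t in thresholds]
    return [0.0] + fpr + [1.0], [0.0] + tpr + [1.0]


def roc_plot(score_groups: dict, path) -> None:
    """ROC curves for one or more models: {name: (case_scores, control_scores)}."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (cases, controls) in score_groups.items():
        fpr, tpr = _roc_points(np.asarray(cases, float), np.asarray(controls, float))
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ordered_risk_plot(risks: pd.DataFrame, path, by: str = "status") -> None:
    """Log OR per individual ordered by risk, one line per stratum."""
    df = risks[risks["eligible"]] if "eligible" in risks else risks
    fig, ax = plt.subplots(figsize=(6, 4))
    for stratum, sub in df.dropna(subset=["log_or"]).groupby(by):
        vals = np.sort(sub["log_or"].to_numpy())
        ax.plot(np.arange(1, vals.size + 1), vals, label=str(stratum))
    ax.set_xlabel("individuals ordered by risk")
    ax.set_ylabel("log OR")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def category_bar_plot(proportions: pd.DataFrame, path) -> None:
    """Stacked proportions of the four risk categories per stratum."""
    fig, ax = plt.subplots(figsize=(6, 4))
    proportions.plot(kind="bar", stacked=True, ax=ax, width=0.7)
    ax.set_ylabel("proportion")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def km_plot(strata: dict, path) -> None:
    """Cumulative-incidence (onset) curves per stratum: {label: onset_ages}."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, ages in strata.items():
        curve = km_curve(np.asarray(ages, float))
        x = np.repeat(curve.times, 2)
        y = np.repeat(curve.cumulative_incidence(), 2)
        ax.plot(np.concatenate([[0], x]), np.concatenate([[0, 0], y[:-1]]), label=str(label))
    ax.set_xlabel("age of onset (years)")
    ax.set_ylabel("cumulative incidence")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
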