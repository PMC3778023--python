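"""Discrimination and descriptive evaluation of prediction models.

AUC is the Mann–Whitney probability that a random case outscores a random
control (ties counted half); its variance and the paired comparison of two
correlated AUCs use DeLong's structural components.  2x2 exposure tables get
Woolf (log-normal) confidence intervals with a Haldane–Anscombe +0.5
correction when a cell is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk_model import ModelError, _z

__all__ = [
    "RocResult",
    "DeLongComparison",
    "ContingencyOR",
    "roc_auc",
    "delong_compare",
    "contingency_or",
    "category_crosstab",
    "risk_distribution_export",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    var_auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    z: float
    p_two_sided: float


@dataclass(frozen=True)
class ContingencyOR:
    """2x2 odds ratio: a/b case exposed/unexposed, c/d control exposed/unexposed."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied (some cell was zero)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties receive the average rank."""
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_components(
    cases: np.ndarray, controls: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components (per-case V10, per-control V01)."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    tz = _midrank(combined)
    tx = _midrank(cases)
    ty = _midrank(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def _var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if v.size > 1 else 0.0


def roc_auc(
    scores_cases: Sequence[float],
    scores_controls: Sequence[float],
    level: float = 0.95,
) -> RocResult:
    """AUC with a DeLong variance and Wald CI (clipped to [0, 1])."""
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ModelError("both score groups must be nonempty")
    auc, v10, v01 = _delong_components(cases, controls)
    var = _var(v10) / cases.size + _var(v01) / controls.size
    half = _z(level) * math.sqrt(var)
    return RocResult(
        auc=auc,
        var_auc=var,
        ci_low=max(auc - half, 0.0),
        ci_high=min(auc + half, 1.0),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> DeLongComparison:
    """DeLong's paired z-test for two correlated AUCs.

    ``scores_a`` and ``scores_b`` are two models' scores on the same
    individuals; ``labels`` is the case indicator.  Identical score vectors
    give z = 0, p = 1; otherwise a degenerate variance raises.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ModelError("paired scores and labels must share one length")
    if y.all() or not y.any():
        raise ModelError("labels must contain both cases and controls")
    m = int(y.sum())
    n = int((~y).sum())
    auc_a, v10_a, v01_a = _delong_components(a[y], a[~y])
    auc_b, v10_b, v01_b = _delong_components(b[y], b[~y])
    var_a = _var(v10_a) / m + _var(v01_a) / n
    var_b = _var(v10_b) / m + _var(v01_b) / n
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) / n
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-16:
        if abs(auc_a - auc_b) <= 1e-12:
            return DeLongComparison(auc_a, auc_b, 0.0, 1.0)
        raise ModelError("degenerate variance: AUC difference is not testable")
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, float(z), p)


def contingency_or(a: int, b: int, c: int, d: int, level: float = 0.95) -> ContingencyOR:
    """2x2 odds ratio with a Woolf CI.

    Cells: a = case exposed, b = case unexposed, c = control exposed,
    d = control unexposed.  If any single cell is zero the Haldane–Anscombe
    +0.5 correction is applied (flagged); two zero cells in the same margin
    leave the OR undefined.
    """
    cells = (a, b, c, d)
    for v in cells:
        if v < 0 or int(v) != v:
            raise ModelError(f"cells must be non-negative integers, got {cells}")
    margins = ((a, b), (c, d), (a, c), (b, d))
    if any(x == 0 and y == 0 for x, y in margins):
        raise ModelError(f"odds ratio undefined: empty margin in {cells}")
    corrected = any(v == 0 for v in cells)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    half = _z(level) * se
    return ContingencyOR(
        a=int(a),
        b=int(b),
        c=int(c),
        d=int(d),
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - half),
        ci_high=math.exp(log_or + half),
        corrected=corrected,
    )


def category_crosstab(risks: pd.DataFrame, by: str = "status") -> dict:
    """Per-stratum category proportions plus headline enrichment ratios.

    ``risks`` is a scored cohort (``score_cohort`` output); ineligible rows
    are dropped.  Returns the proportions table (strata x four categories),
    the case:control high-risk percentage ratio and the control:case
    reduced-risk percentage ratio (None when a denominator is zero or a
    stratum is absent).
    """
    df = risks[risks["eligible"]].copy() if "eligible" in risks else risks.copy()
    if df.empty:
        raise ModelError("no eligible individuals to tabulate")
    cats = ["reduced", "average", "elevated", "high"]
    tab = (
        df.groupby(by)["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=cats, fill_value=0.0)
    )

    def _prop(stratum: str, cat: str) -> Optional[float]:
        if "status" not in df.columns:
            return None
        sub = df[df["status"] == stratum]
        if sub.empty:
            return None
        return float((sub["category"] == cat).mean())

    def _ratio(num: Optional[float], den: Optional[float]) -> Optional[float]:
        if num is None or den is None or den == 0.0:
            return None
        return num / den

    high_ratio = _ratio(_prop("case", "high"), _prop("control", "high"))
    reduced_ratio = _ratio(_prop("control", "reduced"), _prop("case", "reduced"))
    return {
        "proportions": tab,
        "high_risk_case_control_ratio": high_ratio,
        "reduced_risk_control_case_ratio": reduced_ratio,
    }


def risk_distribution_export(risks: pd.DataFrame, by: str = "status") -> pd.DataFrame:
    """Ordered log-OR table (rank ascending within stratum, ties by id)."""
    df = risks[risks["eligible"]].copy() if "eligible" in risks else risks.copy()
    df = df.dropna(subset=["log_or"])
    df = df.sort_values([by, "log_or", "id"], kind="mergesort")
    df["rank"] = df.groupby(by).cumcount() + 1
    return df[[by, "rank", "id", "log_or"]].reset_index(drop=True)
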