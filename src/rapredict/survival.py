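"""Age-of-onset analysis: Kaplan–Meier curves and log-rank tests.

The case-only "time to RA" analysis treats every onset age as an event (no
censoring), in which case the product-limit estimator reduces to the
empirical distribution; censoring support is implemented for generality.
The median onset is the smallest age at which cumulative incidence reaches
one half.  Multivariate Cox modelling is deliberately out of scope — a tidy
(time, covariates) export for standard survival tooling is provided instead
(:func:`cox_export`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk_model import ModelError

__all__ = ["KMCurve", "km_curve", "logrank", "median_onset_delta", "cox_export"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    times: np.ndarray  # distinct event times, ascending
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    median: Optional[float]  # smallest time with cumulative incidence >= 1/2

    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_times_events(sample) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sample, tuple) and len(sample) == 2:
        t = np.asarray(sample[0], dtype=float)
        e = np.asarray(sample[1], dtype=int)
    else:
        t = np.asarray(sample, dtype=float)
        e = np.ones(t.shape, dtype=int)
    if t.size == 0:
        raise ModelError("need at least one observation")
    if np.any(t <= 0):
        raise ModelError("event times must be positive")
    return t, e


def km_curve(sample) -> KMCurve:
    """Kaplan–Meier estimate from event times (or a (times, events) pair).

    With no censoring this equals the empirical CDF exactly.  Tied event
    times are handled by the aggregate-increment convention.
    """
    t, e = _as_times_events(sample)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    n_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    surv = np.empty(event_times.size)
    s = 1.0
    for i, et in enumerate(event_times):
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / at_risk
        n_risk[i] = at_risk
        n_events[i] = d
        surv[i] = s
    median = None
    reached = np.nonzero(surv <= 0.5 + 1e-12)[0]
    if reached.size:
        median = float(event_times[reached[0]])
    return KMCurve(event_times, n_risk, n_events, surv, median)


def logrank(groups: Sequence) -> tuple[float, int, float]:
    """K-sample log-rank test: returns (chi2, df, p).

    Each group is an array of event times or a (times, events) pair.  With
    identical event experience across groups the statistic is zero.
    """
    if len(groups) < 2:
        raise ModelError("log-rank needs at least two groups")
    parsed = [_as_times_events(g) for g in groups]
    k = len(parsed)
    all_t = np.concatenate([t for t, _ in parsed])
    all_e = np.concatenate([e for _, e in parsed])
    grp = np.concatenate([np.full(t.size, i) for i, (t, _) in enumerate(parsed)])
    event_times = np.unique(all_t[all_e == 1])

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = all_t >= et
        n_t = int(at_risk.sum())
        d_t = int(((all_t == et) & (all_e == 1)).sum())
        if n_t == 0:
            continue
        n_j = np.array([int((at_risk & (grp == j)).sum()) for j in range(k)], float)
        d_j = np.array(
            [int(((all_t == et) & (all_e == 1) & (grp == j)).sum()) for j in range(k)],
            float,
        )
        observed += d_j
        expected += d_t * n_j / n_t
        if n_t > 1:
            frac = n_j / n_t
            hyper = d_t * (n_t - d_t) / (n_t - 1.0)
            cov += hyper * (np.diag(frac) - np.outer(frac, frac))
    x = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    chi2 = float(x @ np.linalg.pinv(v) @ x) if np.any(v) else 0.0
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def median_onset_delta(sample_a, sample_b) -> float:
    """Difference in Kaplan–Meier median onset ages (a minus b), in years."""
    med_a = km_curve(sample_a).median
    med_b = km_curve(sample_b).median
    if med_a is None or med_b is None:
        raise ModelError("median onset undefined (never reaches 1/2)")
    return med_a - med_b


def cox_export(risks: pd.DataFrame) -> pd.DataFrame:
    """Tidy (time, covariates) table for external Cox proportional-hazards
    tooling: onset age, HLA-model summary OR score, sex, ever-smoking and
    their interaction, for cases with a known onset age."""
    df = risks.copy()
    if "eligible" in df:
        df = df[df["eligible"]]
    df = df[(df["status"] == "case") & df["onset_age"].notna()]
    out = pd.DataFrame(
        {
            "id": df["id"],
            "onset_age": df["onset_age"].astype(float),
            "event": 1,
            "or_score": df["or_point"].astype(float),
            "male": (df["sex"] == "male").astype(int),
            "ever_smoker": df["ever_smoker"],
        }
    )
    out["male_x_smoker"] = out["male"] * out["ever_smoker"].fillna(0).astype(int)
    return out.reset_index(drop=True)
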