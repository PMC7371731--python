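"""Survival curves and group-comparison statistics.

Kaplan–Meier product-limit estimation and the (asymptotic) log-rank test
are implemented directly from their defining formulas; the log-rank
statistic uses the hypergeometric-variance form with the full covariance
matrix for more than two groups, df = groups - 1. Kruskal–Wallis uses the
tie-corrected H statistic with a chi-square reference, and the 2x2
contingency test is Fisher's exact (hypergeometric) two-sided test.
Reported p-values are floored at the smallest positive double rather than
printed as exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "km_curve",
    "logrank_test",
    "kruskal_wallis",
    "contingency_test",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


def _clean_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events differ in length")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (observed)")
    return t, e.astype(int)


def km_curve(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate S(t) over distinct event times.

    Returns a frame with columns time, n_at_risk, n_events, survival;
    with no observed events the curve is the constant 1 (empty frame of
    event times).
    """
    t, e = _clean_surv(times, events)
    event_times = np.unique(t[e == 1])
    rows = []
    surv = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        surv *= 1.0 - d / at_risk
        rows.append({"time": et, "n_at_risk": at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> TestResult:
    """k-sample log-rank test (observed-minus-expected chi-square).

    At each distinct event time the expected events per group follow the
    hypergeometric model; the statistic is U' V^- U over the first k-1
    groups with the hypergeometric covariance V, df = k - 1.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    cleaned = [_clean_surv(t, e) for t, e in groups]
    k = len(cleaned)
    all_t = np.concatenate([t for t, _ in cleaned])
    all_e = np.concatenate([e for _, e in cleaned])
    gidx = np.concatenate([np.full(t.size, i) for i, (t, _) in enumerate(cleaned)])
    if all_e.sum() == 0:
        raise ValueError("log-rank needs at least one observed event")
    event_times = np.unique(all_t[all_e == 1])
    U = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = all_t >= et
        n = int(at_risk.sum())
        d = int(np.sum((all_t == et) & (all_e == 1)))
        n_g = np.array([int(np.sum(at_risk & (gidx == g))) for g in range(k)])
        d_g = np.array(
            [int(np.sum((all_t == et) & (all_e == 1) & (gidx == g))) for g in range(k)]
        )
        U += d_g - n_g * d / n
        if n > 1:
            frac = n_g / n
            scale = d * (n - d) / (n - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    Ur, Vr = U[:-1], V[:-1, :-1]
    stat = float(Ur @ np.linalg.pinv(Vr) @ Ur)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k - 1))
    return TestResult(statistic=stat, df=k - 1, p_value=max(p, _P_FLOOR))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank-sum H with tie correction, chi-square reference."""
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise ValueError("all values identical; ranks are degenerate")
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += a.size * (r.mean() - (n + 1) / 2) ** 2
        start += a.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    h /= tie_corr
    df = len(arrays) - 1
    p = float(stats.chi2.sf(h, df))
    return TestResult(statistic=float(h), df=df, p_value=max(p, _P_FLOOR))


def contingency_test(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact two-sided test on a 2x2 count table.

    The reported statistic is the sample odds ratio; df is 1 by
    convention for the 2x2 layout.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("contingency test expects a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be non-negative integers")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=float(odds), df=1, p_value=max(float(p), _P_FLOOR))
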