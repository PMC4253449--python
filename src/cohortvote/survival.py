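"""Survival and ordinal-trend validation of a candidate marker gene.

Implements the product-limit (Kaplan–Meier) estimator, the two-group
log-rank test, and the Jonckheere–Terpstra ordered-alternative trend test
from first principles.  The marker is dichotomized at the median (ties to
"low") unless an explicit cutoff is given; the log-rank test is two-sided
(1-df chi-square), the trend test one-sided for an increasing trend, matching
the directional claim that marker expression rises with clinical grade.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dichotomize",
    "km_estimate",
    "SurvivalResult",
    "logrank_test",
    "ordinal_trend_test",
]


def dichotomize(
    expression: np.ndarray | pd.Series, cutoff: str | float = "median"
) -> np.ndarray:
    """Split samples into 'high'/'low' expression groups.

    ``cutoff="median"`` performs a median split with ties assigned to "low"
    (i.e. low = value <= median); a numeric cutoff assigns low = value <=
    cutoff.  A split that leaves either group empty (e.g. constant
    expression) is an error.
    """
    values = np.asarray(expression, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    threshold = float(np.median(values)) if cutoff == "median" else float(cutoff)
    low = values <= threshold
    if low.all() or not low.any():
        raise ValueError(
            "degenerate grouping: all samples fall on one side of the cutoff"
        )
    return np.where(low, "low", "high")


def _check_times(times: np.ndarray, events: np.ndarray) -> None:
    if times.size == 0:
        raise ValueError("need at least one observation")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i), with
    d_i events and n_i at risk just before t_i.  Returns one row per distinct
    event time: ``time, n_risk, n_events, survival``.  Censored-only input
    yields an empty table (S identically 1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _check_times(times, events)
    event_times = np.unique(times[events == 1])
    rows = []
    surv = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / n_risk
        rows.append({"time": t, "n_risk": n_risk, "n_events": d,
                     "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events",
                                       "survival"])


@dataclass
class SurvivalResult:
    """Two-group survival comparison: per-group curves plus log-rank test."""

    statistic: float
    p_value: float
    observed_minus_expected: float
    variance: float
    group_sizes: dict[str, int]
    curves: dict[str, pd.DataFrame]


def logrank_test(group_a, group_b) -> SurvivalResult:
    """Two-group log-rank test.

    At each distinct pooled event time, the observed events in group A are
    compared with the expectation under a common hazard, with hypergeometric
    variance; statistic = (sum(O-E))^2 / sum(V), p from chi-square with 1 df
    (two-sided).  Zero total events is an error (test undefined).
    """
    t_a, e_a = (np.asarray(x) for x in group_a)
    t_b, e_b = (np.asarray(x) for x in group_b)
    t_a, e_a = t_a.astype(float), e_a.astype(int)
    t_b, e_b = t_b.astype(float), e_b.astype(int)
    _check_times(t_a, e_a)
    _check_times(t_b, e_b)
    if e_a.sum() + e_b.sum() == 0:
        raise ValueError("log-rank test undefined with zero total events")

    pooled_times = np.concatenate([t_a, t_b])
    pooled_events = np.concatenate([e_a, e_b])
    event_times = np.unique(pooled_times[pooled_events == 1])

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t_a >= t).sum())
        n2 = int((t_b >= t).sum())
        n = n1 + n2
        d1 = int(((t_a == t) & (e_a == 1)).sum())
        d2 = int(((t_b == t) & (e_b == 1)).sum())
        d = d1 + d2
        if n < 2 or n1 == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = o_minus_e**2 / var
        p = float(stats.chi2.sf(statistic, df=1))
    return SurvivalResult(
        statistic=float(statistic),
        p_value=p,
        observed_minus_expected=float(o_minus_e),
        variance=float(var),
        group_sizes={"A": len(t_a), "B": len(t_b)},
        curves={
            "A": km_estimate(t_a, e_a),
            "B": km_estimate(t_b, e_b),
        },
    )


def _jt_statistic(level_slices: list[np.ndarray]) -> float:
    """Jonckheere–Terpstra J: sum of pairwise Mann–Whitney counts over
    ordered level pairs, ties mid-counted (0.5 per tied pair)."""
    j = 0.0
    for a, b in itertools.combinations(level_slices, 2):
        # a has the lower level; count concordant (a < b) pairs
        diff = b[None, :] - a[:, None]
        j += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(j)


def _jt_null_moments(
    group_sizes: np.ndarray, tie_sizes: np.ndarray
) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the JT statistic."""
    n = int(group_sizes.sum())
    mean = (n * n - (group_sizes**2).sum()) / 4.0
    gi = group_sizes.astype(float)
    tj = tie_sizes.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(gi * (gi - 1) * (2 * gi + 5))
        - np.sum(tj * (tj - 1) * (2 * tj + 5))
    ) / 72.0
    term2 = (
        np.sum(gi * (gi - 1) * (gi - 2)) * np.sum(tj * (tj - 1) * (tj - 2))
    ) / (36.0 * n * (n - 1) * (n - 2)) if n > 2 else 0.0
    term3 = (
        np.sum(gi * (gi - 1)) * np.sum(tj * (tj - 1))
    ) / (8.0 * n * (n - 1))
    return mean, term1 + term2 + term3


def ordinal_trend_test(
    expression, level, method: str = "auto"
) -> tuple[float, float]:
    """Jonckheere–Terpstra test for an increasing trend across ordered levels.

    ``level`` gives each sample's ordinal category; the one-sided alternative
    is that expression increases with level.  ``method`` is ``"normal"``
    (tie-corrected normal approximation), ``"exact"`` (full enumeration of
    level assignments, feasible for n <= 12), or ``"auto"`` (exact when
    n <= 12).  Returns ``(statistic, p_value)``.
    """
    values = np.asarray(expression, dtype=float)
    levels = np.asarray(level)
    if values.shape != levels.shape:
        raise ValueError("expression and level must be aligned")
    unique_levels = np.unique(levels)
    if unique_levels.size < 2:
        raise ValueError("need at least 2 ordered levels")
    slices = [values[levels == lv] for lv in unique_levels]
    j_obs = _jt_statistic(slices)
    n = values.size

    if method not in ("auto", "normal", "exact"):
        raise ValueError("method must be auto, normal or exact")
    use_exact = method == "exact" or (method == "auto" and n <= 12)
    if use_exact and n > 12:
        raise ValueError("exact enumeration supported only for n <= 12")

    if use_exact:
        group_sizes = [len(s) for s in slices]
        count_ge = 0
        total = 0
        for perm in _multiset_assignments(n, group_sizes):
            perm_slices = [values[list(idx)] for idx in perm]
            if _jt_statistic(perm_slices) >= j_obs - 1e-12:
                count_ge += 1
            total += 1
        return j_obs, count_ge / total

    group_sizes = np.array([len(s) for s in slices])
    _, tie_counts = np.unique(values, return_counts=True)
    mean, var = _jt_null_moments(group_sizes, tie_counts)
    if var <= 0:
        return j_obs, 1.0 if j_obs <= mean else 0.0
    z = (j_obs - mean) / math.sqrt(var)
    return j_obs, float(stats.norm.sf(z))


def _multiset_assignments(n: int, group_sizes: list[int]):
    """Yield all partitions of indices 0..n-1 into ordered groups of the
    given sizes (the exact permutation null of the level labels)."""

    def rec(remaining: frozenset, sizes: list[int]):
        if not sizes:
            yield ()
            return
        k = sizes[0]
        for combo in itertools.combinations(sorted(remaining), k):
            rest = remaining - set(combo)
            for tail in rec(rest, sizes[1:]):
                yield (combo,) + tail

    yield from rec(frozenset(range(n)), group_sizes)
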