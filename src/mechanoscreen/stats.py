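"""Shared statistical primitives for the screen analysis.

Group comparisons (Welch's unequal-variance t-test and the Brown–Forsythe
variance test) are the two tests reported for every AFM and trajectory
figure; Benjamini–Hochberg adjustment and the Gini index support the
enrichment and sequencing-QC stages; Kaplan–Meier estimation and the
two-group log-rank test support survival-based hit prioritization.

Degenerate inputs (zero-variance groups, event-free survival data) return
flagged results rather than raising, so batch pipelines keep running.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupComparison",
    "SurvivalComparison",
    "KMEstimate",
    "welch_t_test",
    "brown_forsythe",
    "bh_adjust",
    "gini_index",
    "km_estimate",
    "logrank_test",
    "compare_groups",
]


@dataclass(frozen=True)
class TestResult:
    """Statistic / degrees-of-freedom / p triple with optional QC flag."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    flag: str | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Welch + Brown–Forsythe comparison of two samples.

    ``welch_p`` tests a difference in means allowing unequal variances;
    ``bf_p`` tests a difference in spread (ANOVA on absolute deviations
    from the group medians).
    """

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    welch_t: float
    welch_df: float
    welch_p: float
    bf_stat: float
    bf_df1: int
    bf_df2: int
    bf_p: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve on the observed event grid."""

    times: np.ndarray            # distinct times, ascending
    survival: np.ndarray         # S(t) just after each time
    median: float                # earliest t with S(t) <= 0.5; nan if never

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class SurvivalComparison:
    """Bottom- vs top-tercile survival contrast for one endpoint."""

    endpoint: str
    median_low: float
    median_high: float
    median_difference: float     # median(low-expression) - median(high)
    logrank_chi2: float
    logrank_p: float
    n_low: int
    n_high: int
    flags: tuple[str, ...] = ()


def _as_sample(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch unequal-variance t-test.

    Returns t, Welch–Satterthwaite degrees of freedom and the two-sided
    p-value. Zero-variance degeneracies are flagged: equal constant samples
    give (t=0, p=1); distinct constants give p=0.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, "zero-variance")
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TestResult(sign * np.inf, float(a.size + b.size - 2), 0.0, "zero-variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def brown_forsythe(*groups: Sequence[float]) -> TestResult:
    """Brown–Forsythe test for equality of group variances.

    One-way ANOVA F statistic on z_ij = |x_ij - median(group j)|, referred
    to F(k-1, N-k). All-identical deviations are flagged with W=0, p=1.
    """
    if len(groups) < 2:
        raise ValueError("brown_forsythe needs at least two groups")
    gs = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(gs)
    n_total = sum(g.size for g in gs)
    z = [np.abs(g - np.median(g)) for g in gs]
    if all(np.ptp(zi) == 0 for zi in z) and np.ptp(np.concatenate(z)) == 0:
        return TestResult(0.0, (k - 1, n_total - k), 1.0, "degenerate")
    stat, p = sps.levene(*gs, center="median")
    return TestResult(float(stat), (k - 1, n_total - k), float(p))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    padj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def gini_index(counts: Sequence[float]) -> float:
    """Population Gini index of a non-negative count vector.

    Uses the sorted form G = sum_i (2i - n - 1) x_(i) / (n^2 * mean),
    which equals the pairwise mean-absolute-difference definition.
    0 for perfectly even counts; approaches 1 as a few items dominate.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("empty count vector")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector: Gini undefined")
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan–Meier product-limit estimate with first-crossing median.

    ``events`` is 1 for an observed event, 0 for right-censoring. The
    median is the earliest time at which S(t) <= 0.5 and is nan when the
    curve never reaches 0.5 (e.g. everything censored).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events must align")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # drop the t=0 anchor row if present and keep event/censor times only
    below = surv <= 0.5
    median = float(grid[below][0]) if below.any() else float("nan")
    return KMEstimate(times=grid, survival=surv, median=median)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> TestResult:
    """Two-group log-rank test (1 df chi-square, hypergeometric variance)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return TestResult(0.0, 1.0, 1.0, "no-events")
    from lifelines.statistics import logrank_test as _lr

    res = _lr(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(float(res.test_statistic), 1.0, float(res.p_value))


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Welch + Brown–Forsythe summary of two samples, as reported per figure."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    w = welch_t_test(a, b)
    bf = brown_forsythe(a, b)
    flags = tuple(f for f in (w.flag, bf.flag) if f)
    df1, df2 = bf.df  # type: ignore[misc]
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        welch_t=w.statistic,
        welch_df=float(w.df),  # type: ignore[arg-type]
        welch_p=w.p,
        bf_stat=bf.statistic,
        bf_df1=int(df1),
        bf_df2=int(df2),
        bf_p=bf.p,
        flags=flags,
    )
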