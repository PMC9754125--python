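"""Cohort statistics for embryo counting and per-embryo measures.

The experimental readouts come in two flavours: categorical per-embryo calls
(gastrulating / non-gastrulating), compared between conditions with Fisher's
exact test on the 2x2 count table, and quantitative per-embryo measures
(d/D, intensity ratios, ...), compared with the Mann-Whitney U test.  A
special subsampling rule handles the case where one condition shows a clearly
bimodal distribution: the top five values of the upper mode are compared with
the five values most representative of the lower-mode mean.

``fisher_exact`` is written with exact integer arithmetic so that its p-value
carries no floating-point enumeration error for tables with total count up to
~10^4.  ``mann_whitney`` is exact (full rank-sum distribution) for small
tie-free samples and falls back to the tie-corrected normal approximation
with continuity correction otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, erf, sqrt
from typing import Sequence

import numpy as np

__all__ = [
    "CohortCounts",
    "TestResult",
    "fisher_exact",
    "mann_whitney",
    "bimodal_subsample_test",
    "responder_pool_fraction",
]


@dataclass(frozen=True)
class CohortCounts:
    """2x2 table of positive/negative embryo counts for two conditions."""

    a_pos: int
    a_neg: int
    b_pos: int
    b_neg: int

    def __post_init__(self) -> None:
        for name in ("a_pos", "a_neg", "b_pos", "b_neg"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("all-zero table: the test is undefined")

    @property
    def total(self) -> int:
        return self.a_pos + self.a_neg + self.b_pos + self.b_neg

    def as_array(self) -> np.ndarray:
        return np.array([[self.a_pos, self.a_neg], [self.b_pos, self.b_neg]])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def fisher_exact(counts: CohortCounts, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table of positive/negative counts.

    The two-sided p-value follows the probability-ordering convention: it sums
    the hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed that of the observed table.  All
    comparisons are made on exact integer numerators (the common denominator
    ``C(n, c1)`` cancels), so no floating-point tolerance enters the ordering.
    """
    if isinstance(counts, (tuple, list, np.ndarray)):
        arr = np.asarray(counts, dtype=int).reshape(2, 2)
        counts = CohortCounts(*arr.ravel().tolist())
    r1 = counts.a_pos + counts.a_neg
    r2 = counts.b_pos + counts.b_neg
    c1 = counts.a_pos + counts.b_pos
    n = counts.total

    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    # integer numerators of the hypergeometric pmf, common denominator C(n, c1)
    num = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    denom = comb(n, c1)
    obs = counts.a_pos
    num_obs = num[obs]

    if alternative == "two-sided":
        p_num = sum(v for v in num.values() if v <= num_obs)
    elif alternative == "less":
        p_num = sum(v for k, v in num.items() if k <= obs)
    elif alternative == "greater":
        p_num = sum(v for k, v in num.items() if k >= obs)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")

    p = float(min(1.0, p_num / denom))
    # odds ratio (conditional sample estimate) as the reported statistic
    if counts.a_neg * counts.b_pos > 0:
        stat = (counts.a_pos * counts.b_neg) / (counts.a_neg * counts.b_pos)
    else:
        stat = float("inf") if counts.a_pos * counts.b_neg > 0 else float("nan")
    return TestResult(
        statistic=stat,
        p_value=p,
        method=f"fisher-exact-{alternative}",
        n_per_group=(r1, r2),
    )


def _rank(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_u_counts(n1: int, n2: int) -> list[int]:
    """Number of label assignments yielding each U value, U = 0..n1*n2.

    Classical recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1),
    where m/n are the sizes of the two samples.
    """
    max_u = n1 * n2
    # a[m][u] for the current n; start at n = 0 where U is always 0
    a = [[1] + [0] * max_u for _ in range(n1 + 1)]
    for n in range(1, n2 + 1):
        new = [row[:] for row in a]
        for m in range(1, n1 + 1):
            row = new[m]
            prev_row = new[m - 1]
            old_row = a[m]
            for u in range(max_u + 1):
                row[u] = old_row[u] + (prev_row[u - n] if u >= n else 0)
        a = new
    return a[n1]


def mann_whitney(
    sample1: Sequence[float],
    sample2: Sequence[float],
    exact_max_n: int = 8,
) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact p by full enumeration of all label assignments when both samples
    have at most ``exact_max_n`` observations (ties handled exactly through
    the midranks); otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rank(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    if n1 <= exact_max_n and n2 <= exact_max_n:
        # exact permutation distribution over all C(n1+n2, n1) label
        # assignments of the midranks; valid with and without ties
        mu = n1 * n2 / 2.0
        dev = abs(u1 - mu)
        total = hits = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        p = min(1.0, hits / total)
        method = "mann-whitney-exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / sqrt(sigma2)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0))))
            p = max(p, np.nextafter(0.0, 1.0))
        method = "mann-whitney-normal"
    return TestResult(statistic=float(u1), p_value=float(p), method=method, n_per_group=(n1, n2))


def bimodal_subsample_test(
    sample1: Sequence[float],
    sample2: Sequence[float],
    k: int = 5,
    seed: int | None = 0,
) -> TestResult:
    """Compare the top-k of a bimodal sample's upper mode with the k values of
    its lower mode closest to the lower-mode mean.

    ``sample1`` is the condition flagged bimodal by the caller (the flagging is
    deliberately manual); its upper/lower modes are split at the midpoint
    between the two extreme values.  ``sample2`` is kept whole if it is the
    reference condition of the same size rule; here both selections are drawn
    from ``sample1`` against ``sample2`` reduced to k representative values of
    its mean.  Ties among equally close values are resolved reproducibly with
    the given seed.
    """
    import warnings

    x = np.sort(np.asarray(sample1, dtype=float))[::-1]
    y = np.asarray(sample2, dtype=float)
    rng = np.random.default_rng(seed)

    if x.size < k or y.size < k:
        warnings.warn(
            f"fewer than k={k} elements in a mode; using all available"
        )
    upper = x[: min(k, x.size)]
    # k values of sample2 closest to its mean ("representative of the mean")
    dist = np.abs(y - y.mean())
    # random, seeded tie-break among equal distances
    jitter = rng.random(y.size) * 1e-12 * (1.0 + dist.max())
    idx = np.argsort(dist + jitter, kind="mergesort")[: min(k, y.size)]
    lower = y[idx]

    res = mann_whitney(upper, lower)
    return TestResult(
        statistic=res.statistic,
        p_value=res.p_value,
        method="bimodal-subsample",
        n_per_group=(upper.size, lower.size),
        extra={"base_method": res.method},
    )


def responder_pool_fraction(p_stim: float, p_ctrl: float) -> float:
    """Fraction of the statically negative pool that responds under stimulation.

    With a stimulated positive rate ``p_stim`` and a control rate ``p_ctrl``,
    the stimulation converted ``(p_stim - p_ctrl) / (1 - p_ctrl)`` of the pool
    that would have stayed negative in static conditions (clipped below at 0).
    """
    if not (0.0 <= p_ctrl < 1.0):
        raise ValueError("p_ctrl must lie in [0, 1); the pool is undefined at 1")
    if not (0.0 <= p_stim <= 1.0):
        raise ValueError("p_stim must lie in [0, 1]")
    return max(0.0, (p_stim - p_ctrl) / (1.0 - p_ctrl))
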