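"""Rank-based tests, multiple-testing correction and the normality gate.

Small-sample p-values are exact: the Mann-Whitney and Wilcoxon null
distributions are computed by dynamic programming over the (tie-aware)
midrank lattice, which reproduces full permutation / sign-flip enumeration
without enumerating it.  Larger samples fall back to the usual normal
approximation with tie and continuity corrections.  Two-sided p-values use
the doubling rule min(1, 2 * smaller tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestReport",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "bh_adjust",
    "normality_gate",
]

#: exactness thresholds: exact Mann-Whitney when n*m <= this
MW_EXACT_MAX_NM = 400
#: exact Wilcoxon signed-rank when n (nonzero pairs) <= this
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    n: tuple
    tie_corrected: bool
    exact: bool

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _two_sided_from_tails(lower: float, upper: float) -> float:
    return float(min(1.0, 2.0 * min(lower, upper)))


def _rank_sum_distribution(weights: np.ndarray, n: int) -> np.ndarray:
    """Count subsets of size ``n`` of ``weights`` (non-negative ints) by sum.

    Returns an array ``c`` with ``c[s]`` = number of size-n subsets summing
    to ``s``.  This is the exact permutation distribution of the rank sum.
    """
    total = int(weights.sum())
    # dp[k, s] = number of k-subsets with weight-sum s
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for w in weights:
        w = int(w)
        # iterate k downwards so each item is used at most once
        for k in range(min(n, 1_000_000), 0, -1):
            if dp[k - 1].any():
                dp[k, w:] += dp[k - 1, : total + 1 - w]
    return dp[n]


def mann_whitney_u(x, y, two_sided: bool = True) -> TestReport:
    """Mann-Whitney U test with midrank ties.

    Exact permutation p-value (tie-aware DP) when ``len(x)*len(y) <= 400``,
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n].sum()  # rank sum of x
    u_obs = w_obs - n * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n * m <= MW_EXACT_MAX_NM:
        # midranks are multiples of 1/2: doubling makes them integers
        weights = np.round(2 * ranks).astype(np.int64)
        dist = _rank_sum_distribution(weights, n)
        total = dist.sum()
        w2 = int(round(2 * w_obs))
        lower = dist[: w2 + 1].sum() / total
        upper = dist[w2:].sum() / total
        p = _two_sided_from_tails(lower, upper) if two_sided else float(
            min(lower, upper)
        )
        return TestReport("mann-whitney", float(u_obs), p, (n, m), has_ties, True)

    N = n + m
    mu = n * m / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    sigma = np.sqrt(sigma2)
    # continuity correction toward the mean
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / sigma if u_obs != mu else 0.0
    p = 2 * sps.norm.sf(abs(z)) if two_sided else sps.norm.sf(abs(z))
    return TestReport(
        "mann-whitney", float(u_obs), float(min(1.0, max(p, np.nextafter(0, 1)))),
        (n, m), has_ties, False,
    )


def wilcoxon_signed_rank(x_paired, y_paired, two_sided: bool = True) -> TestReport:
    """Wilcoxon matched-pairs signed-rank test (zero differences dropped)."""
    x = np.asarray(x_paired, dtype=float)
    y = np.asarray(y_paired, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n <= WILCOXON_EXACT_MAX_N:
        # sign-flip distribution: every subset of ranks is equally likely
        weights = np.round(2 * ranks).astype(np.int64)
        total_w = int(weights.sum())
        dist = np.zeros(total_w + 1)
        dist[0] = 1.0
        for w in weights:
            w = int(w)
            shifted = np.zeros_like(dist)
            shifted[w:] = dist[: total_w + 1 - w]
            dist = dist + shifted
        total = dist.sum()  # 2**n
        w2 = int(round(2 * w_plus))
        lower = dist[: w2 + 1].sum() / total
        upper = dist[w2:].sum() / total
        p = _two_sided_from_tails(lower, upper) if two_sided else float(
            min(lower, upper)
        )
        return TestReport("wilcoxon-signed-rank", float(w_plus), p, (n,), has_ties, True)

    mu = n * (n + 1) / 4.0
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma if w_plus != mu else 0.0
    p = 2 * sps.norm.sf(abs(z)) if two_sided else sps.norm.sf(abs(z))
    return TestReport(
        "wilcoxon-signed-rank", float(w_plus),
        float(min(1.0, max(p, np.nextafter(0, 1)))), (n,), has_ties, False,
    )


def spearman_rho(x, y) -> tuple[float, TestReport]:
    """Spearman rank correlation (midranks) with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = np.nextafter(0, 1)
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2 * sps.t.sf(abs(t), df=n - 2)
    report = TestReport(
        "spearman", rho, float(min(1.0, max(p, np.nextafter(0, 1)))),
        (n,), True, n >= 10,
    )
    return rho, report


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(ranked, 1.0)
    return q


def normality_gate(groups, alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: 'parametric' unless any group rejects normality."""
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            raise ValueError("Shapiro-Wilk requires n >= 3 per group")
        if np.ptp(g) == 0:
            return "nonparametric"
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"
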