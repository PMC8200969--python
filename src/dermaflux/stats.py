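"""Statistical kernels for the paired and unpaired comparisons.

These are authored implementations (exact signed-rank null for small n,
normal approximation with continuity and tie corrections above; Welch's t
with Satterthwaite degrees of freedom; Holm step-down adjustment). The test
suite cross-checks every p-value against an independent reference
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "InsufficientDataError",
    "wilcoxon_signed_rank",
    "welch_t",
    "holm_adjust",
]

#: Largest n for which the exact signed-rank null is enumerated.
EXACT_N_MAX = 25

ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str


def _exact_signed_rank_counts(n: int) -> np.ndarray:
    """Number of rank subsets of {1..n} summing to each value 0..n(n+1)/2."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on ``x`` (or paired ``x - y``).

    Zero differences are discarded. With no ties and n <= 25 the exact
    null distribution of the positive-rank sum is enumerated; otherwise a
    normal approximation with tie correction and continuity correction is
    used. The reported statistic is ``min(W+, W-)``.
    """
    d = np.asarray(x, dtype=np.float64)
    if y is not None:
        d = d - np.asarray(y, dtype=np.float64)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        # every pair tied: no evidence against the null
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="wilcoxon_degenerate")
    ranks = rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    statistic = min(r_plus, r_minus)
    has_ties = np.unique(np.abs(d)).size != n

    if n <= EXACT_N_MAX and not has_ties:
        counts = _exact_signed_rank_counts(n)
        total = counts.sum()
        w = int(round(r_plus))
        p_le = counts[: w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "wilcoxon_exact"
    else:
        mn = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, rep_counts = np.unique(ranks, return_counts=True)
        var -= (rep_counts**3 - rep_counts).sum() / 48.0
        se = np.sqrt(var)
        correction = 0.5 * np.sign(r_plus - mn)
        z = (r_plus - mn - correction) / se
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "wilcoxon_normal"
    return TestResult(statistic=statistic, p_value=float(p), n=n, method=method)


def welch_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, unpaired)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError("Welch's t requires at least 2 values per group")
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        t_stat = 0.0
        p = 1.0
        df = na + nb - 2.0
    else:
        t_stat = float((a.mean() - b.mean()) / denom)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return TestResult(statistic=t_stat, p_value=p, n=na + nb, method="welch_t")


def holm_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (controls FWER, assumption-free)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for i, idx in enumerate(order):
        running_max = max(running_max, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted
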