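"""Nonparametric test battery: Friedman, Wilcoxon signed-rank,
Mann-Whitney U, Bonferroni correction.

Ties are handled with mid-ranks throughout.  Small samples use exact null
distributions (a generating-function convolution for the signed-rank sum,
enumeration of group labelings for U, enumeration of within-row orderings
for Friedman); larger samples use the tie-corrected normal or chi-square
approximations.  Zero differences are dropped in the signed-rank test
(Wilcoxon's original treatment).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

#: switchover sample sizes between exact and approximate p-values
WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 20        # n + m
FRIEDMAN_EXACT_MAX = 500_000        # (k!)^n enumeration budget


@dataclass(frozen=True)
class TestResult:
    name: str                       # "Friedman Q" | "Wilcoxon W" | "Mann-Whitney U"
    value: float
    p: float
    df: Optional[int] = None
    n: Optional[int] = None
    p_adjusted: Optional[float] = None
    method: str = "exact"           # "exact" | "normal" | "chi2"
    screening_flag: Optional[str] = None

    def adjusted(self, m: int) -> "TestResult":
        from dataclasses import replace
        return replace(self, p_adjusted=min(1.0, m * self.p))


# -- Friedman ----------------------------------------------------------------


def _friedman_q(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman statistic for an n x k (subjects x conditions)
    matrix, mid-ranks within rows."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: inflate Q by the mean within-row tie factor
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    c = 1.0 - tie_term / (n * k * (k ** 2 - 1))
    return q / c if c > 0 else 0.0


def friedman_test(matrix, exact: bool = False) -> TestResult:
    """Friedman test for repeated measures on an n x k matrix.

    Chi-square p with df = k - 1 by default; ``exact=True`` computes the
    permutation p over all (k!)^n within-subject orderings (small matrices
    only).  Rank-based, so invariant under any monotone transform of the
    data.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    n, k = matrix.shape
    q_obs = _friedman_q(matrix)
    if exact:
        if math.factorial(k) ** n > FRIEDMAN_EXACT_MAX:
            raise ValueError("matrix too large for exact enumeration")
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        for assignment in itertools.product(perms, repeat=n):
            permuted = np.array([matrix[i, list(p)]
                                 for i, p in enumerate(assignment)])
            total += 1
            if _friedman_q(permuted) >= q_obs - 1e-12:
                count += 1
        return TestResult(name="Friedman Q", value=q_obs, p=count / total,
                          df=k - 1, n=n, method="exact")
    p = float(chi2.sf(q_obs, k - 1))
    return TestResult(name="Friedman Q", value=q_obs, p=p, df=k - 1, n=n,
                      method="chi2")


# -- Wilcoxon signed-rank ----------------------------------------------------


def _signed_rank_null(weights: Sequence[int]) -> np.ndarray:
    """Exact null distribution of the positive-rank sum over all 2^n sign
    assignments, by generating-function convolution.  ``weights`` are the
    (doubled, integer) mid-ranks."""
    total = sum(weights)
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for w in weights:
        shifted = np.zeros_like(dist)
        shifted[w:] = dist[:len(dist) - w]
        dist = dist + shifted
    return dist / dist.sum()


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided",
                         method: str = "auto") -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or differences).

    W is the smaller of the positive and negative rank sums; zero
    differences are dropped and ties get mid-ranks.  Exact p for
    n <= 25 (or ``method='exact'``), tie-corrected normal approximation
    with continuity correction above.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    use_exact = method == "exact" or (method == "auto"
                                      and n <= WILCOXON_EXACT_MAX_N)
    if use_exact:
        weights = [int(round(2 * r)) for r in ranks]
        dist = _signed_rank_null(weights)
        wp2 = int(round(2 * w_plus))
        cdf_le = float(dist[:wp2 + 1].sum())
        cdf_ge = float(dist[wp2:].sum())
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
        elif alternative == "less":       # W+ small: differences negative
            p = cdf_le
        elif alternative == "greater":
            p = cdf_ge
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return TestResult(name="Wilcoxon W", value=w, p=p, n=n,
                          method="exact")

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = float(np.sum(counts ** 3 - counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    z = (w_plus - mean)
    cc = 0.5 * np.sign(z) if z != 0 else 0.0
    z = (w_plus - mean - cc) / math.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * float(norm.sf(abs(z)))
    elif alternative == "less":
        p = float(norm.cdf(z))
    elif alternative == "greater":
        p = float(norm.sf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(name="Wilcoxon W", value=w, p=min(1.0, p), n=n,
                      method="normal")


def signed_rank_critical_check(n: int, w: float) -> dict:
    """Exact tail probabilities around an observed W for distinct ranks --
    the published critical-value convention rejects when W falls strictly
    below the tabulated value."""
    weights = [2 * r for r in range(1, n + 1)]
    dist = _signed_rank_null(weights)
    w2 = int(round(2 * w))
    return {
        "p_le_w": float(dist[:w2 + 1].sum()),
        "p_lt_w": float(dist[:w2].sum()) if w2 >= 1 else 0.0,
    }


# -- Mann-Whitney U ----------------------------------------------------------


def mann_whitney_u(a, b, alternative: str = "two-sided",
                   method: str = "auto") -> TestResult:
    """Mann-Whitney U test for two independent samples, mid-ranks for ties.

    U is the smaller of U1 and U2.  Exact p by enumeration of all
    C(n+m, n) group labelings of the pooled mid-ranks for n + m <= 20 (or
    ``method='exact'``); tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n].sum())
    u1 = n * m + n * (n + 1) / 2.0 - r1
    u2 = n * m - u1
    u = min(u1, u2)

    use_exact = method == "exact" or (method == "auto"
                                      and n + m <= MANNWHITNEY_EXACT_MAX_N)
    if use_exact:
        idx = range(n + m)
        u1_vals = []
        for comb in itertools.combinations(idx, n):
            r = float(ranks[list(comb)].sum())
            u1_vals.append(n * m + n * (n + 1) / 2.0 - r)
        u1_vals = np.array(u1_vals)
        total = len(u1_vals)
        eps = 1e-9
        le = float(np.sum(u1_vals <= u1 + eps)) / total
        ge = float(np.sum(u1_vals >= u1 - eps)) / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(le, ge))
        elif alternative == "less":
            p = le
        elif alternative == "greater":
            p = ge
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return TestResult(name="Mann-Whitney U", value=u, p=p, n=n + m,
                          method="exact")

    mean = n * m / 2.0
    nm = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts))
    var = n * m / 12.0 * ((nm + 1) - tie / (nm * (nm - 1)))
    z = u1 - mean
    cc = 0.5 * np.sign(z) if z != 0 else 0.0
    z = (u1 - mean - cc) / math.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * float(norm.sf(abs(z)))
    elif alternative == "less":
        p = float(norm.cdf(z))
    elif alternative == "greater":
        p = float(norm.sf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(name="Mann-Whitney U", value=u, p=min(1.0, p), n=n + m,
                      method="normal")


# -- multiple testing --------------------------------------------------------


def bonferroni(p_values, m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, m p).  ``m`` defaults to the
    number of p-values but can be set to the full comparison count of a
    battery (e.g., 45 parameters compared across two groups)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mm = len(p) if m is None else int(m)
    if mm < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, mm * p)


def quartile_overlap(a, b) -> bool:
    """Screening rule used before pairwise testing: True when the boxplot
    positions (median and quartiles) of the two samples overlap, i.e. each
    sample's median lies inside the other's interquartile range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return bool(qb[0] <= qa[1] <= qb[2] and qa[0] <= qb[1] <= qa[2])
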