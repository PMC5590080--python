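"""Nonparametric tests used by the DMR caller.

Two tests are computed per candidate region:

* a two-sided Mann-Whitney U test comparing the per-position group-mean
  vectors.  For combined n <= ``EXACT_MAX_N`` the exact permutation
  distribution of the rank sum is computed (a shift-algorithm dynamic
  program over doubled midranks, so ties are handled exactly); larger
  instances use the normal approximation with tie correction and
  continuity correction.
* a two-sample two-dimensional Kolmogorov-Smirnov test on the point sets
  {(position rank, group mean rate)}, with the classical asymptotic
  significance approximation (quadrant statistic averaged over both
  samples' points as origins, correlation-corrected effective N).

Both p-values are clamped into (0, 1].
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import comb
from scipy.stats import kstwobign, norm, rankdata

EXACT_MAX_N = 20


def _rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Number of n1-subsets of the pooled ranks attaining each doubled
    rank sum; index t = number of subsets with sum(2*rank) == t."""
    total = int(doubled_ranks.sum())
    # dp[k][t] = number of k-subsets with doubled-rank sum t
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in doubled_ranks.astype(int):
        upper = min(n1, len(doubled_ranks))
        for k in range(upper, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n1]


def mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p: fraction of the C(n1+n2, n1)
    group-label assignments whose U is at least as far from its null
    mean as the observed U.  Handles ties via midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks; doubled midranks are integers
    doubled = np.rint(2 * ranks).astype(int)
    t_obs = int(doubled[:n1].sum())
    mu = n1 * (n1 + n2 + 1)  # E[2 * R1]
    dist = _rank_sum_distribution(doubled, n1)
    dev = np.abs(np.arange(len(dist)) - mu)
    count = dist[dev >= abs(t_obs - mu)].sum()
    p = count / comb(n1 + n2, n1, exact=True)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def mann_whitney_asymptotic(x: np.ndarray, y: np.ndarray) -> float:
    """Normal-approximation two-sided Mann-Whitney p with tie correction.

    No continuity correction: in the regime this branch serves
    (both samples > 10 observations) the uncorrected statistic tracks
    the exact permutation p more closely across the whole p range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = abs(u - mu) / math.sqrt(var)
    p = 2 * norm.sf(max(z, 0.0))
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value; exact for combined n <= 20."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if len(x) + len(y) <= EXACT_MAX_N:
        return mann_whitney_exact(x, y)
    return mann_whitney_asymptotic(x, y)


# ---------------------------------------------------------------------------
# two-dimensional two-sample KS


def _max_quadrant_diff(origins: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Max over origins and quadrants of |fraction(a) - fraction(b)|.

    Quadrant membership uses strict > / <= splits so every point falls
    in exactly one quadrant per origin.
    """
    # vectorized over origins: quadrant fractions for both samples at once
    d = 0.0
    ax_gt = a[None, :, 0] > origins[:, None, 0]  # origins x points
    ay_gt = a[None, :, 1] > origins[:, None, 1]
    bx_gt = b[None, :, 0] > origins[:, None, 0]
    by_gt = b[None, :, 1] > origins[:, None, 1]
    for qa, qb in (
        (ax_gt & ay_gt, bx_gt & by_gt),
        (~ax_gt & ay_gt, ~bx_gt & by_gt),
        (~ax_gt & ~ay_gt, ~bx_gt & ~by_gt),
        (ax_gt & ~ay_gt, bx_gt & ~by_gt),
    ):
        fa = qa.sum(axis=1) / len(a)
        fb = qb.sum(axis=1) / len(b)
        d = max(d, float(np.abs(fa - fb).max()))
    return d


def _safe_corr(points: np.ndarray) -> float:
    sx = points[:, 0].std()
    sy = points[:, 1].std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(points[:, 0], points[:, 1])[0, 1])
    return 0.0 if not np.isfinite(r) else r


def ks2d_statistic(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d1 = _max_quadrant_diff(a, a, b)
    d2 = _max_quadrant_diff(b, a, b)
    return (d1 + d2) / 2


def ks2d_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample 2-D KS statistic and asymptotic p for point sets
    ``a`` (n1 x 2) and ``b`` (n2 x 2)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 points per sample")
    d = ks2d_statistic(a, b)
    sqen = math.sqrt(n1 * n2 / (n1 + n2))
    r1, r2 = _safe_corr(a), _safe_corr(b)
    rr = math.sqrt(max(1.0 - 0.5 * (r1 * r1 + r2 * r2), 0.0))
    denom = 1.0 + rr * (0.25 - 0.75 / sqen)
    lam = d * sqen / denom if denom > 0 else d * sqen
    p = float(kstwobign.sf(lam))
    return d, float(min(max(p, np.nextafter(0, 1)), 1.0))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH q-values: q_(i) = min_{j >= i} (m * p_(j) / j), clipped to 1."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
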