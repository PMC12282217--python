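"""Shared statistical machinery: vectorised OLS t-tests, rank-sum tests
with exact small-sample enumeration, 2x2 exact tests, and FDR adjustment.

These primitives back several differential-abundance engines, so they are
written to operate on a response *matrix* (samples x features) at once.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ols_fit_matrix",
    "ranksum_matrix",
    "ranksum_exact",
    "exact_test_2x2",
    "fdr_adjust",
]

_ZERO_VAR = 1e-28


def ols_fit_matrix(X: np.ndarray, Y: np.ndarray):
    """Fit ``Y[:, f] ~ X`` for every column f by ordinary least squares.

    Parameters
    ----------
    X : (n, p) design matrix, full column rank.
    Y : (n, m) response matrix.

    Returns
    -------
    dict with ``beta`` (p, m), ``se`` (p, m), ``t`` (p, m), ``p`` (p, m),
    ``resid`` (n, m), ``df`` (scalar residual degrees of freedom).

    Features with (numerically) zero residual variance get t = 0, p = 1
    when the coefficient is also zero, else p = 0; this is the
    "zero-variance" policy used by the linear engines.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(_collinear_message(X))
    df = n - p
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T                      # (p, n)
    beta = hat @ Y                           # (p, m)
    resid = Y - X @ beta
    sigma2 = np.einsum("nm,nm->m", resid, resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = sigma2 < _ZERO_VAR
    if degenerate.any():
        coef_zero = np.abs(beta) < 1e-12
        pval[:, degenerate] = np.where(coef_zero[:, degenerate], 1.0, 0.0)
        t[:, degenerate] = np.where(coef_zero[:, degenerate], 0.0, np.inf)
    return {"beta": beta, "se": se, "t": t, "p": pval, "resid": resid, "df": df}


def _collinear_message(X: np.ndarray) -> str:
    """Name the columns involved in a rank deficiency (best effort)."""
    bad = []
    base_rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == base_rank:
            bad.append(j)
    return f"design matrix is rank-deficient; collinear column indices: {bad}"


def ranksum_matrix(Y: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values for every column of Y.

    Mid-ranks with the normal approximation and tie correction for n > 8;
    exact enumeration of all group assignments otherwise. ``mask_a``
    selects group A; the rest of the rows form group B. Columns where
    every value is identical get p = 1.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    n1 = int(mask_a.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n <= 8:
        idx_a = np.flatnonzero(mask_a)
        return np.array([ranksum_exact(Y[idx_a, j], Y[~mask_a, j])
                         for j in range(m)])
    ranks = stats.rankdata(Y, axis=0)
    r1 = ranks[mask_a].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum over tie groups of (t^3 - t)
    tie_term = np.zeros(m)
    for j in range(m):
        _, counts = np.unique(Y[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var <= 0, 1.0, np.minimum(p, 1.0))
    return p


def ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Enumerates every C(n1+n2, n1) split of the pooled values, computing the
    rank-sum of group one under mid-ranks, and counts splits whose statistic
    is at least as far from its mean as the observed one. Intended for
    n1 + n2 <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12:
            count += 1
    return count / total


def exact_test_2x2(table) -> tuple[float, float]:
    """Two-sided exact hypergeometric test on a 2x2 table.

    Returns (odds_ratio, p). p sums hypergeometric point probabilities not
    exceeding that of the observed table (the standard two-sided rule).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    if a * d == 0 and b * c == 0:
        odds = math.nan
    return odds, min(p, 1.0)


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Adjust p-values for multiplicity.

    method 'bh' is Benjamini-Hochberg step-up; 'holm' is the Holm-Bonferroni
    step-down family-wise correction (used here in the same q < alpha role).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm"}[method]
    return multipletests(p, method=key)[1]
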