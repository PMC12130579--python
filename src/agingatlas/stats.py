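"""Rank-correlation and multiple-testing primitives shared across stages.

Spearman's rho is Pearson on mid-ranks.  The two-sided p-value uses the exact
permutation null (all n! orderings, cached per rank multiset) for n <= 9 and
the usual t approximation, t = rho*sqrt((n-2)/(1-rho^2)) with n-2 df, above
that.  |rho| = 1 always falls back to the exact tail 2/n!.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_N_MAX = 9


@lru_cache(maxsize=64)
def _perm_rho_null(rx: tuple, ry: tuple) -> np.ndarray:
    """All-permutation null distribution of rho for the given rank multisets."""
    rx_arr = np.asarray(rx, dtype=float)
    n = rx_arr.size
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    rxc = rx_arr - rx_arr.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum()) * np.sqrt((pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (pc @ rxc) / denom
    return rho


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p for two equal-length vectors (ties allowed).

    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        null = _perm_rho_null(tuple(np.sort(rx)), tuple(np.sort(ry)))
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0 - 1e-12:
        p = 2.0 / math.factorial(n)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho/p between rows of ``a`` and rows of ``b``.

    Vectorised rho (rank then Pearson); p-values delegate to :func:`spearman`
    per pair so the exact small-n rule is honoured.
    """
    ra = np.apply_along_axis(sps.rankdata, 1, a)
    rb = np.apply_along_axis(sps.rankdata, 1, b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra ** 2).sum(axis=1))
    nb = np.sqrt((rb ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra @ rb.T) / np.outer(na, nb)
    n = a.shape[1]
    pvals = np.empty_like(rho)
    for i in range(rho.shape[0]):
        for j in range(rho.shape[1]):
            r = rho[i, j]
            if not np.isfinite(r):
                pvals[i, j] = np.nan
            elif n <= EXACT_N_MAX:
                null = _perm_rho_null(tuple(np.sort(sps.rankdata(a[i]))),
                                      tuple(np.sort(sps.rankdata(b[j]))))
                pvals[i, j] = np.mean(np.abs(null) >= abs(r) - 1e-12)
            elif abs(r) >= 1.0 - 1e-12:
                pvals[i, j] = 2.0 / math.factorial(n)
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r ** 2))
                pvals[i, j] = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, np.minimum(pvals, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaNs propagate)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def correlation_t_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a correlation via the t transform with n-2 df."""
    if abs(rho) >= 1.0 - 1e-12:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def fisher_z_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a correlation via the Fisher z transform."""
    if abs(rho) >= 1.0 - 1e-12:
        return 0.0
    z = 0.5 * math.log((1 + rho) / (1 - rho)) * math.sqrt(n - 3)
    return float(2.0 * sps.norm.sf(abs(z)))
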