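"""Shared statistical machinery: rank-sum tests, p→Z mapping, BH adjustment.

Every two-group comparison in the pipeline funnels through
:func:`rank_sum_test` so the exact/approximate policy is applied uniformly.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "z_from_p", "bh_adjust"]

# Largest |Z| representable without the normal quantile overflowing.
_Z_CAP = 37.0

# Exact enumeration with ties is O(C(n, n1)); cap keeps it trivial.
_ENUM_MAX_N = 14
_EXACT_MAX_N = 20


def _enumerate_p(pooled: np.ndarray, n1: int) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group-1 index sets.

    Valid with ties (works on average ranks). Two-sided p is the probability
    of a rank sum at least as far from its mean as the observed one.
    """
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-12:
            hits += 1
    u_obs = w_obs - n1 * (n1 + 1) / 2.0
    return u_obs, hits / total


def rank_sum_test(x, y, method: str = "auto") -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Policy (``method="auto"``):

    * all pooled values identical → degenerate, p = 1;
    * no ties and total n ≤ 20 → exact null distribution;
    * ties and total n ≤ 14 → exact enumeration over label assignments;
    * otherwise → normal approximation with tie and continuity correction.

    Returns ``(U, p, policy)`` where ``U`` is the Mann-Whitney statistic of
    the first group and ``policy`` names the branch taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n = pooled.size
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0, "degenerate"
    has_ties = np.unique(pooled).size < n

    if method == "exact" or (method == "auto" and not has_ties and n <= _EXACT_MAX_N):
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(min(res.pvalue, 1.0)), "exact"
    if method == "auto" and has_ties and n <= _ENUM_MAX_N:
        u, p = _enumerate_p(pooled, x.size)
        return float(u), float(p), "enumeration"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance after tie correction
        p = 1.0
    return float(res.statistic), min(p, 1.0), "asymptotic"


def z_from_p(p, sign=1.0):
    """Signed Z score equivalent of a two-sided p-value.

    ``|Z|`` is the standard-normal quantile of ``p / 2``; the sign carries
    the direction of the effect.
    """
    p = np.asarray(p, dtype=float)
    z = stats.norm.isf(np.clip(p, 0.0, 1.0) / 2.0)
    z = np.clip(z, 0.0, _Z_CAP)
    return z * np.sign(sign) if np.ndim(p) else float(z * np.sign(sign))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe, NaN stays NaN)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
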