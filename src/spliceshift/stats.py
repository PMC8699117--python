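"""Shared statistics helpers.

Benjamini-Hochberg adjustment, Spearman rank correlation with an exact
small-sample permutation p-value, and the Wilcoxon rank-sum test with an
exact small-sample null.  These are the primitives every analysis family
(isoform tests, ASE tests, cohort comparisons) builds on; multiple-testing
correction is BH only, applied within each family separately.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["benjamini_hochberg", "spearman_rho", "wilcoxon_ranksum"]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment.

    NaN entries are excluded from the ranking and propagated unchanged.
    Output is elementwise >= input, capped at 1, and monotone along the
    sorted-p order.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def spearman_rho(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with midrank tie handling.

    The p-value is the exact two-sided permutation probability when
    n <= ``exact_max_n`` (all n! relabelings of one margin), otherwise the
    t-approximation.  Requires >= 4 complete pairs after pairwise removal
    of missing values.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"spearman_rho needs >= 4 complete pairs, got {n}")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("spearman_rho undefined: a margin is constant")
    rho = float(xc @ yc) / denom

    if n <= exact_max_n:
        # Exact null: rho recomputed under every permutation of the y ranks.
        obs = abs(rho) - 1e-12
        count = 0
        total = 0
        chunk: list[tuple[int, ...]] = []
        yc_arr = yc

        def flush(chunk):
            nonlocal count, total
            idx = np.array(chunk, dtype=np.intp)
            s = yc_arr[idx] @ xc
            count += int(np.sum(np.abs(s) / denom >= obs))
            total += idx.shape[0]

        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            if len(chunk) >= 200_000:
                flush(chunk)
                chunk = []
        if chunk:
            flush(chunk)
        return rho, count / total

    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, min(1.0, p)


def wilcoxon_ranksum(a, b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled size is at most
    ``exact_max_n`` and there are no ties, a normal approximation with tie
    correction otherwise.  Returns the Mann-Whitney U of the first group.
    When every value in both groups is identical the test is vacuous and
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("wilcoxon_ranksum: all values identical; p = 1 by convention")
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
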