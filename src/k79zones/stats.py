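"""Rank tests and FDR control shared across the analysis stages.

The zone-level significance statements all use the two-sided Wilcoxon
rank-sum test; per-gene contrast evidence uses a paired signed-rank test on
window-level log2 differences.  Multiple testing is Benjamini-Hochberg.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the combined sample is small
    (n <= 20 without ties; n <= 14 with ties, via midrank enumeration), and
    the normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum requires two non-empty samples")
    n = a.size + b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < n
    if n <= 20 and not has_ties:
        return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    if n <= 14:
        return _exact_midrank_p(a, b)
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True).pvalue
    )


def _exact_midrank_p(a, b) -> float:
    """Exact two-sided p by enumerating all label assignments (midranks for ties).

    The rank-sum null distribution is symmetric about its mean (complementing
    a subset mirrors its rank sum), so |T - mu| >= |T_obs - mu| is the
    two-sided rejection region.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = a.size
    n = pooled.size
    mu = na * (n + 1) / 2.0
    t_obs = float(ranks[:na].sum())
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n), na):
        t = float(ranks[list(idx)].sum())
        total += 1
        if abs(t - mu) >= abs(t_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def paired_evidence_p(diffs, min_obs: int = 4) -> tuple[float, bool]:
    """Two-sided paired test on per-observation log2 differences.

    Returns ``(p, low_evidence)``.  The primary test is the Wilcoxon
    signed-rank; when ties or all-zero differences make it degenerate the
    fallback is a paired t-test with the variance floored at 1e-8 (log2
    scale), so exactly-replicated synthetic observations still yield a
    defined p.  Fewer than ``min_obs`` finite observations gives p = 1 and a
    low-evidence flag.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < min_obs:
        return 1.0, True
    if np.all(np.abs(d) < 1e-12):
        return 1.0, False
    nz = d[d != 0]
    tied = nz.size < d.size or np.unique(np.abs(nz)).size < nz.size
    # exact signed-rank distribution when tie-free and small; normal
    # approximation with continuity correction otherwise (scipy's automatic
    # tie fallback is an exhaustive permutation enumeration, far too slow here)
    method = "exact" if (not tied and nz.size <= 25) else "approx"
    try:
        p = float(sps.wilcoxon(nz, alternative="two-sided", method=method, correction=True).pvalue)
        if math.isfinite(p):
            return min(p, 1.0), False
    except ValueError:
        pass
    var = max(float(d.var(ddof=1)), 1e-8)
    t = float(d.mean()) / math.sqrt(var / d.size)
    return float(2.0 * sps.t.sf(abs(t), d.size - 1)), False


def welch_t_p(x, y, var_floor: float = 1e-8) -> float:
    """Two-sided Welch t-test p-value with a variance floor.

    The floor (on the log2 scale) keeps zero-variance groups — exact ties are
    common in synthetic fixtures — from producing undefined statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("welch_t_p requires >= 2 observations per group")
    vx = max(float(x.var(ddof=1)), var_floor)
    vy = max(float(y.var(ddof=1)), var_floor)
    se2 = vx / nx + vy / ny
    t = (float(x.mean()) - float(y.mean())) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2.0 * sps.t.sf(abs(t), df))
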