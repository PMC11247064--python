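"""Restenosis outcome metrics and the rank-sum comparison.

All percentages follow the clinical reporting conventions: lumen-area
increase and restenosis as integers, residual stenosis with one decimal.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = ["median_iqr", "lumen_increase_pct", "restenosis_pct",
           "residual_stenosis_pct", "mann_whitney_u"]


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def lumen_increase_pct(a_pre: float, a_post: float,
                       decimals: int | None = 0) -> float:
    """Acute gain of the intervention: 100 (a_post - a_pre) / a_pre."""
    if a_pre <= 0:
        raise ValueError("pre-intervention area must be positive")
    out = 100.0 * (a_post - a_pre) / a_pre
    return round(out, decimals) if decimals is not None else out


def restenosis_pct(a_post: float, a_t: float,
                   decimals: int | None = 0) -> float:
    """Lumen-area loss at follow-up relative to the post-intervention state:
    100 (1 - a_t / a_post)."""
    if a_post <= 0:
        raise ValueError("post-intervention area must be positive")
    out = 100.0 * (1.0 - a_t / a_post)
    return round(out, decimals) if decimals is not None else out


def residual_stenosis_pct(a_min: float, a_target: float,
                          decimals: int | None = 1) -> float:
    """Fraction of the target lumen area still obstructed right after the
    procedure: 100 (1 - a_min / a_target)."""
    if a_target <= 0:
        raise ValueError("target area must be positive")
    out = 100.0 * (1.0 - a_min / a_target)
    return round(out, decimals) if decimals is not None else out


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n+m, n) group assignments of
    the pooled sample (tie-safe).  Two-sided via min(U, U') tail doubling
    capped at 1, consistent with the distribution's symmetry."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    total = comb(n + m, n)
    u_min_obs = min(u_obs, n * m - u_obs)
    count = 0
    for idx in combinations(range(n + m), n):
        rx = ranks[list(idx)].sum()
        u = rx - n * (n + 1) / 2.0
        if min(u, n * m - u) <= u_min_obs + 1e-9:
            count += 1
    return min(1.0, count / total)


def mann_whitney_u(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all group assignments when n_x + n_y does not
    exceed ``exact_max_n`` (covers the 11-plane comparisons); tie-corrected
    normal approximation with continuity correction otherwise.  Returns
    (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n + m <= exact_max_n:
        return u_x, _exact_two_sided_p(x, y, u_x)
    # tie-corrected normal approximation
    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    nm = n + m
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term / (nm * (nm - 1)))
    if sigma2 <= 0:
        return u_x, 1.0
    z = (abs(u_x - mu) - 0.5) / np.sqrt(sigma2)
    return u_x, float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
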