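"""Hartigan's dip test of unimodality for cross-cell methylation levels.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance from F_n to the class of unimodal distribution functions (convex up
to some mode, concave after).  It is computed here by scanning the mode
position over gaps between order statistics: for each split, the minimal
distance achievable by a convex fit to the left part within the two-sided
step bands is half the maximal gap between the upper step values and the
greatest convex minorant of the lower step values (symmetrically, the least
concave majorant on the right), and the dip is the minimax over splits.

P-values come from Monte-Carlo calibration against the uniform distribution,
the least-favourable unimodal null; null tables are cached per sample size.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np

from ._jit import njit

__all__ = ["dip_statistic", "dip_test", "null_dip_table", "bimodality_scan"]


@njit(cache=False)
def _convex_fit_dist(xs, lo, hi, start, stop):
    """Max gap hi_i - gcm(lo)_i over indices [start, stop) of the greatest
    convex minorant of points (xs, lo); half of it is the minimal sup-norm
    distance of a convex nondecreasing fit within the step bands."""
    m = stop - start
    hull = np.empty(m, dtype=np.int64)
    hull[0] = start
    h_len = 1
    for i in range(start + 1, stop):
        while h_len >= 2:
            i1 = hull[h_len - 2]
            i2 = hull[h_len - 1]
            if (lo[i2] - lo[i1]) * (xs[i] - xs[i2]) <= (lo[i] - lo[i2]) * (xs[i2] - xs[i1]):
                break
            h_len -= 1
        hull[h_len] = i
        h_len += 1
    best = 0.0
    h = 0
    for i in range(start, stop):
        while h + 1 < h_len and xs[hull[h + 1]] <= xs[i]:
            h += 1
        if h + 1 < h_len:
            i1 = hull[h]
            i2 = hull[h + 1]
            t = (xs[i] - xs[i1]) / (xs[i2] - xs[i1])
            g = lo[i1] * (1 - t) + lo[i2] * t
        else:
            g = lo[hull[h]]
        gap = hi[i] - g
        if gap > best:
            best = gap
    return best


@njit(cache=False)
def _gcm_clears(xs, top, lo, m, t):
    """True if gcm of min(top_i, t) stays >= lo_i everywhere (indices 0..m-1)."""
    hull_x = np.empty(m)
    hull_y = np.empty(m)
    h_len = 0
    for i in range(m):
        y = top[i] if top[i] < t else t
        while h_len >= 2:
            if (hull_y[h_len - 1] - hull_y[h_len - 2]) * (xs[i] - hull_x[h_len - 1]) <= \
               (y - hull_y[h_len - 1]) * (hull_x[h_len - 1] - hull_x[h_len - 2]):
                break
            h_len -= 1
        hull_x[h_len] = xs[i]
        hull_y[h_len] = y
        h_len += 1
    h = 0
    for i in range(m):
        while h + 1 < h_len and hull_x[h + 1] <= xs[i]:
            h += 1
        if h + 1 < h_len:
            tt = (xs[i] - hull_x[h]) / (hull_x[h + 1] - hull_x[h])
            g = hull_y[h] * (1 - tt) + hull_y[h + 1] * tt
        else:
            g = hull_y[h]
        if g < lo[i] - 1e-12:
            return False
    return True


@njit(cache=False)
def _min_feasible_end(xs, top, lo, m):
    """Smallest end value t of a convex nondecreasing function within the
    bands lo_i <= g_i <= top_i on points 0..m-1 (g realized as the gcm of the
    clipped tops); +inf if the bands are infeasible altogether."""
    t_hi = top[m - 1]
    if not _gcm_clears(xs, top, lo, m, t_hi):
        return np.inf
    t_lo = lo[m - 1]
    if _gcm_clears(xs, top, lo, m, t_lo):
        return t_lo
    for _ in range(50):
        t_mid = 0.5 * (t_lo + t_hi)
        if _gcm_clears(xs, top, lo, m, t_mid):
            t_hi = t_mid
        else:
            t_lo = t_mid
    return t_hi


@njit(cache=False)
def _split_feasible(ux, f_lo, f_hi, rx, rlo, rhi, m, k, d):
    """Feasibility of a unimodal fit at sup-distance d with the mode between
    points k and k+1: both side bands feasible and the joint monotone
    (left end value <= right start value)."""
    kl = k + 1
    top = np.empty(kl)
    lo = np.empty(kl)
    for i in range(kl):
        top[i] = f_lo[i] + d
        lo[i] = f_hi[i] - d
    a_min = _min_feasible_end(ux, top, lo, kl)
    if a_min == np.inf:
        return False
    kr = m - k - 1
    if kr == 0:
        return True
    top2 = np.empty(kr)
    lo2 = np.empty(kr)
    for i in range(kr):
        top2[i] = rlo[i] + d
        lo2[i] = rhi[i] - d
    b_neg = _min_feasible_end(rx, top2, lo2, kr)
    if b_neg == np.inf:
        return False
    b_max = -b_neg
    return a_min <= b_max + 1e-12


@njit(cache=False)
def _dip_core(ux, f_lo, f_hi, n):
    m = ux.size
    # mirrored arrays for the concave (right) side
    rx = np.empty(m)
    rlo = np.empty(m)
    rhi = np.empty(m)
    for i in range(m):
        rx[i] = -ux[m - 1 - i]
        rlo[i] = -f_hi[m - 1 - i]
        rhi[i] = -f_lo[m - 1 - i]
    best = 1.0
    for k in range(m):
        d_left = 0.5 * _convex_fit_dist(ux, f_lo, f_hi, 0, k + 1)
        if k + 1 < m:
            # right part k+1..m-1 maps to mirrored prefix 0..m-k-2
            d_right = 0.5 * _convex_fit_dist(rx, rlo, rhi, 0, m - k - 1)
        else:
            d_right = 0.0
        cand = max(max(d_left, d_right), 0.5 / n)
        if cand >= best:
            continue
        # band distances ignore the junction between the two sides; lift d
        # until a monotone joint fit exists (binding only for well-separated
        # clusters)
        rxs = rx[: m - k - 1] if k + 1 < m else rx[:1]
        if not _split_feasible(ux, f_lo, f_hi, rxs, rlo, rhi, m, k, cand + 1e-12):
            d_hi = best
            if not _split_feasible(ux, f_lo, f_hi, rxs, rlo, rhi, m, k, d_hi):
                continue  # this split cannot beat the current best
            d_lo = cand
            for _ in range(50):
                d_mid = 0.5 * (d_lo + d_hi)
                if _split_feasible(ux, f_lo, f_hi, rxs, rlo, rhi, m, k, d_mid):
                    d_hi = d_mid
                else:
                    d_lo = d_mid
            cand = d_hi
        if cand < best:
            best = cand
    return best


def dip_statistic(values: np.ndarray) -> float:
    """Dip statistic of a one-dimensional sample.

    Ties are collapsed into weighted jumps of the empirical cdf.  A sample
    with fewer than two distinct values has the minimal dip 1/(2n)
    (degenerate; perfectly unimodal).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    ux, counts = np.unique(x, return_counts=True)
    if ux.size == 1:
        return 0.5 / n
    cum = np.cumsum(counts)
    f_hi = cum / n                       # F at the point (after the jump)
    f_lo = (cum - counts) / n            # F just left of the point
    return float(_dip_core(ux, f_lo, f_hi, n))


@lru_cache(maxsize=64)
def _cached_null_table(n: int, n_mc: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.sort([dip_statistic(rng.uniform(size=n)) for _ in range(n_mc)])


def null_dip_table(n: int, n_mc: int = 2000, seed: int = 987) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the dip for uniform samples
    of size n (cached per (n, n_mc, seed))."""
    return _cached_null_table(int(n), int(n_mc), int(seed))


def dip_test(values: np.ndarray, n_mc: int = 2000, seed: int = 987) -> tuple[float, float]:
    """(dip, p-value) against the uniform (least-favourable unimodal) null.

    The p-value is the Monte-Carlo tail fraction with the add-one correction
    (p >= 1/(n_mc + 1)); requires at least 10 observations.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("dip test requires n >= 10 observations")
    d = dip_statistic(x)
    table = null_dip_table(x.size, n_mc=n_mc, seed=seed)
    n_ge = table.size - np.searchsorted(table, d, side="left")
    p = (n_ge + 1) / (table.size + 1)
    return d, float(min(p, 1.0))


def bimodality_scan(
    tiles,
    group_by: str = "cpg_density",
    bin_edges: Optional[np.ndarray] = None,
    min_cells: int = 10,
    alpha: float = 0.05,
    n_mc: int = 2000,
    n_boot: int = 1000,
    dither: bool = True,
    seed: int = 987,
):
    """Fraction of tiles with significantly bimodal cross-cell methylation.

    For each tile with at least ``min_cells`` covered cells, the dip test is
    applied to the per-cell rates; tiles are then binned by CpG density or by
    across-cell mean methylation, and the per-bin fraction of significant
    tiles (p < alpha) is reported with bootstrap 95% CIs over tiles.

    Rates are discrete fractions k/c; at low coverage the resulting lattice
    alone registers as multimodality against the continuous null.  With
    ``dither`` (default) each rate is smeared uniformly over its own
    discretization cell (+- 1/(2c)), a standard continuization that leaves
    genuinely bimodal signals intact.

    Returns ``(per_tile, per_bin)`` DataFrames.
    """
    import pandas as pd

    from .variance import binned_profile

    if group_by not in ("cpg_density", "mean_methylation"):
        raise ValueError("group_by must be 'cpg_density' or 'mean_methylation'")
    rates = tiles.rates()
    total = tiles.total
    n_tiles = tiles.n_tiles
    dens = tiles.table["cpg_density"].to_numpy()
    dips = np.full(n_tiles, np.nan)
    pvals = np.full(n_tiles, np.nan)
    mean_m = np.full(n_tiles, np.nan)
    rng = np.random.default_rng(seed)
    for i in range(n_tiles):
        cov = total[i] > 0
        if cov.sum() < min_cells:
            continue
        c = total[i, cov]
        m = rates[i, cov]
        mean_m[i] = float(np.sum(c * m) / c.sum())
        if dither:
            m = np.clip(m + rng.uniform(-0.5, 0.5, size=m.size) / c, 0.0, 1.0)
        dips[i], pvals[i] = dip_test(m, n_mc=n_mc, seed=seed)
    per_tile = pd.DataFrame({
        "chrom": tiles.table["chrom"],
        "start": tiles.table["start"],
        "end": tiles.table["end"],
        "cpg_density": dens,
        "mean_methylation": mean_m,
        "dip": dips,
        "p_value": pvals,
    })
    group = dens if group_by == "cpg_density" else mean_m
    if bin_edges is None:
        bin_edges = (np.array([0.0, 0.01, 0.02, 0.03, 0.05, 0.10, 0.20, 1.0])
                     if group_by == "cpg_density"
                     else np.linspace(0.0, 1.0, 6))
    tested = np.isfinite(pvals)
    per_bin = binned_profile(group[tested], (pvals[tested] < alpha).astype(float),
                             np.asarray(bin_edges), n_boot=n_boot, seed=seed)
    per_bin = per_bin.rename(columns={"value": "fraction_significant"})
    return per_tile, per_bin
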