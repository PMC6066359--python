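"""Excess-variance statistics: biological variability over technical noise.

A tile observed at mean methylation mbar with mean coverage cbar has
binomial (technical) variance mbar*(1-mbar)/cbar across samples even without
any biological signal.  The excess-variance statistic divides the
coverage-weighted variance of per-sample rates by this quantity: ~1 for
technical noise only, >1 in the presence of biological variability, and it
serves as the amplitude proxy for methylation oscillations.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tiling import Tiles

__all__ = [
    "excess_variance",
    "technical_null_bounds",
    "binned_profile",
    "feature_correlation",
]


def excess_variance(tiles: Tiles, min_samples: int = 3) -> np.ndarray:
    """Per-tile ratio of weighted rate variance to binomial expectation.

    Weights are per-sample tile coverages normalized to sum 1 (frequency
    weights); cbar is the mean coverage over covered samples.  Tiles with
    fewer than ``min_samples`` covered samples, or with weighted mean of
    exactly 0 or 1 (no binomial variance), yield NaN.
    """
    meth, total = tiles.meth, tiles.total
    out = np.full(tiles.n_tiles, np.nan)
    for i in range(tiles.n_tiles):
        cov = total[i] > 0
        if cov.sum() < min_samples:
            continue
        c = total[i, cov]
        m = meth[i, cov] / c
        w = c / c.sum()
        mbar = float(np.sum(w * m))
        if mbar <= 0.0 or mbar >= 1.0:
            continue
        wvar = float(np.sum(w * (m - mbar) ** 2))
        cbar = float(np.mean(c))
        out[i] = wvar / (mbar * (1.0 - mbar) / cbar)
    return out


def technical_null_bounds(
    coverages: Sequence[float],
    m_bar: float,
    n_rep: int = 1000,
    seed: int = 0,
    q: Tuple[float, float] = (2.5, 97.5),
) -> Tuple[float, float]:
    """Null band of the coverage-weighted mean rate under pure binomial
    sampling at (m_bar, per-sample coverages): percentiles of ``n_rep``
    resampled weighted means."""
    c = np.asarray(coverages, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("no coverage")
    if not 0 <= m_bar <= 1:
        raise ValueError("m_bar must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = rng.binomial(c.astype(int)[None, :].repeat(n_rep, 0), m_bar)
    means = k.sum(axis=1) / c.sum()
    lo, hi = np.percentile(means, q)
    return float(lo), float(hi)


def binned_profile(
    x: np.ndarray,
    y: np.ndarray,
    bin_edges: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Binned summary of y versus x with bootstrap 95% CIs (resampling
    entries within each bin).  NaNs in y are dropped."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    rng = np.random.default_rng(seed)
    stat = np.nanmean if statistic == "mean" else np.nanmedian
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (x >= lo) & (x < hi)
        yy = y[sel]
        if yy.size == 0:
            rows.append({"bin_lo": lo, "bin_hi": hi, "n": 0, "value": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        boots = stat(rng.choice(yy, size=(n_boot, yy.size), replace=True), axis=1)
        rows.append({
            "bin_lo": lo, "bin_hi": hi, "n": int(yy.size),
            "value": float(stat(yy)),
            "ci_lo": float(np.percentile(boots, 2.5)),
            "ci_hi": float(np.percentile(boots, 97.5)),
        })
    return pd.DataFrame(rows)


def feature_correlation(
    values: pd.DataFrame, weights: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Coverage-weighted Pearson correlation between per-cell feature means.

    ``values`` is cells x features; ``weights`` (same shape) holds coverage
    depths.  Pairwise weights are the geometric mean of the two features'
    coverages; cells lacking either feature are dropped per pair.  Constant
    features give NaN off-diagonals; the diagonal is exactly 1 where defined.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 cells")
    feats = list(values.columns)
    v = values.to_numpy(dtype=float)
    if weights is None:
        w_all = np.ones_like(v)
    else:
        if list(weights.columns) != feats or len(weights) != len(values):
            raise ValueError("weights must align with values")
        w_all = weights.to_numpy(dtype=float)
    n = len(feats)
    out = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a, n):
            ok = np.isfinite(v[:, a]) & np.isfinite(v[:, b]) \
                & (w_all[:, a] > 0) & (w_all[:, b] > 0)
            if ok.sum() < 3:
                continue
            w = np.sqrt(w_all[ok, a] * w_all[ok, b])
            w = w / w.sum()
            xa, xb = v[ok, a], v[ok, b]
            ma, mb = np.sum(w * xa), np.sum(w * xb)
            va = np.sum(w * (xa - ma) ** 2)
            vb = np.sum(w * (xb - mb) ** 2)
            eps = 1e-24 * max(1.0, ma * ma) * max(1.0, mb * mb)
            if va <= eps or vb <= eps:
                continue
            cov = np.sum(w * (xa - ma) * (xb - mb))
            out[a, b] = out[b, a] = cov / np.sqrt(va * vb)
    return pd.DataFrame(out, index=feats, columns=feats)
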