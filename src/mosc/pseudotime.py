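"""Methylation pseudo-time: ordering cells by CpG-dense-region methylation.

CpG-rich regions (10-15% density) gain methylation monotonically during the
exit from pluripotency and show no appreciable oscillation, so their average
methylation level serves as a per-cell developmental clock.  Charting the
methylation of oscillation-prone CpG-poor regions (2-3% density) against
this pseudo-time turns a static single-cell snapshot into a time series.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .tiling import MethCallTable, Tiles, tile_by_informative_cpgs

logger = logging.getLogger(__name__)

__all__ = ["pseudo_time", "pseudotime_series"]


def pseudo_time(
    calls: MethCallTable,
    density_range: Tuple[float, float] = (0.10, 0.15),
    window: int = 100,
    min_tiles: int = 5,
    tiles: Optional[Tiles] = None,
) -> pd.Series:
    """Per-cell pseudo-time: mean methylated-read fraction over CpG-dense tiles.

    Tiles (``window`` informative CpGs) with CpG density inside
    ``density_range`` qualify; each cell's pseudo-time is the unweighted mean
    of its per-tile methylation fractions there.  Cells with fewer than
    ``min_tiles`` covered qualifying tiles are excluded (NaN, logged).
    """
    if tiles is None:
        tiles = tile_by_informative_cpgs(calls, window=window)
    dens = tiles.table["cpg_density"].to_numpy()
    qual = (dens >= density_range[0]) & (dens <= density_range[1])
    if not np.any(qual):
        raise ValueError("no tiles inside the qualifying density range")
    rates = tiles.rates()[qual]
    covered = np.isfinite(rates)
    out = pd.Series(np.nan, index=tiles.sample_ids, name="pseudo_time")
    for j, s in enumerate(tiles.sample_ids):
        n_cov = int(covered[:, j].sum())
        if n_cov < min_tiles:
            logger.info("pseudo_time: cell %s excluded (%d qualifying tiles)", s, n_cov)
            continue
        out[s] = float(np.nanmean(rates[:, j]))
    return out


def pseudotime_series(
    tiles: Tiles,
    pt: pd.Series,
    density_range: Tuple[float, float] = (0.02, 0.03),
) -> pd.DataFrame:
    """Detrended, noise-rescaled methylation series along pseudo-time.

    For each cell: the coverage-weighted mean methylation over tiles in
    ``density_range``, ordered by pseudo-time, linearly detrended, and
    divided by the expected technical standard deviation
    sqrt(mbar(1-mbar)/cbar) of that cell's aggregate.
    """
    dens = tiles.table["cpg_density"].to_numpy()
    sel = (dens >= density_range[0]) & (dens <= density_range[1])
    if not np.any(sel):
        raise ValueError("no tiles inside the requested density range")
    meth = tiles.meth[sel]
    total = tiles.total[sel]
    rows = []
    for j, s in enumerate(tiles.sample_ids):
        if s not in pt.index or not np.isfinite(pt[s]):
            continue
        tot = total[:, j].sum()
        if tot <= 0:
            continue
        mbar = meth[:, j].sum() / tot
        cbar = total[:, j][total[:, j] > 0].mean()
        rows.append({"sample": s, "pt": float(pt[s]), "mean_meth": float(mbar),
                     "cbar": float(cbar)})
    df = pd.DataFrame(rows).sort_values("pt").reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("fewer than 4 cells with pseudo-time and coverage")
    slope, icept = np.polyfit(df["pt"], df["mean_meth"], 1)
    resid = df["mean_meth"] - (icept + slope * df["pt"])
    mb = df["mean_meth"].clip(1e-6, 1 - 1e-6)
    tech_sd = np.sqrt(mb * (1 - mb) / df["cbar"])
    df["detrended"] = resid
    df["rescaled"] = resid / tech_sd
    return df
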