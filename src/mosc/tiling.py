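"""Coverage-based genome tiling into windows of fixed informative-CpG count.

Sequencing coverage varies strongly along the genome, so fixed-length tiles
confound CpG density with coverage.  Tiles of a constant number of
*informative* CpGs (>= 1 read pooled across samples) are unbiased probes:
every tile carries the same amount of evidence, while its genomic span, and
hence its CpG density, varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["MethCallTable", "Tiles", "tile_by_informative_cpgs", "filter_tiles"]


@dataclass
class MethCallTable:
    """Per-sample CpG methylation calls plus sample metadata.

    ``calls`` has columns (sample, chrom, pos, meth, unmeth) with 1-based CpG
    coordinates, strictly increasing within each (sample, chrom).
    ``cpg_positions`` optionally lists all CpG coordinates per chromosome
    (the genome registry used for density); otherwise the union of observed
    positions stands in for it.
    """

    calls: pd.DataFrame
    samples: pd.DataFrame
    cpg_positions: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "pos", "meth", "unmeth"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"calls missing columns: {sorted(missing)}")
        if (self.calls[["meth", "unmeth"]] < 0).any().any():
            raise ValueError("negative read counts")
        for (sample, chrom), grp in self.calls.groupby(["sample", "chrom"], sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if np.any(d <= 0):
                raise ValueError(
                    f"positions not strictly increasing for sample={sample} chrom={chrom}"
                )
        unknown = set(self.calls["sample"]) - set(self.samples["sample"])
        if unknown:
            raise ValueError(f"calls reference unknown samples: {sorted(unknown)}")

    @classmethod
    def from_files(cls, cov_paths: Dict[str, Union[str, "os.PathLike"]],
                   sample_sheet: pd.DataFrame,
                   cpg_positions: Optional[Dict[str, np.ndarray]] = None) -> "MethCallTable":
        from .io import read_bismark_cov

        frames = []
        for sample, path in cov_paths.items():
            df = read_bismark_cov(path)
            df.insert(0, "sample", sample)
            frames.append(df)
        return cls(pd.concat(frames, ignore_index=True), sample_sheet, cpg_positions)

    @property
    def sample_ids(self) -> list:
        return list(self.samples["sample"])

    def registry(self, chrom: str) -> np.ndarray:
        """All CpG coordinates for a chromosome (genome registry or the
        union of observed positions)."""
        if self.cpg_positions is not None and chrom in self.cpg_positions:
            return np.asarray(self.cpg_positions[chrom])
        pos = self.calls.loc[self.calls["chrom"] == chrom, "pos"].unique()
        return np.sort(pos)


@dataclass
class Tiles:
    """Tiling result: per-tile metadata plus per-sample count matrices."""

    table: pd.DataFrame            # chrom, start, end, n_informative, n_cpgs, cpg_density
    meth: np.ndarray               # (n_tiles, n_samples)
    total: np.ndarray
    sample_ids: list

    @property
    def n_tiles(self) -> int:
        return len(self.table)

    def rates(self) -> np.ndarray:
        """Per-tile per-sample methylation rates (NaN where no coverage)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tile metadata joined with per-sample rate columns."""
        rates = self.rates()
        df = self.table.copy()
        for j, s in enumerate(self.sample_ids):
            df[f"rate_{s}"] = rates[:, j]
        return df


def tile_by_informative_cpgs(calls: MethCallTable, window: int = 50) -> Tiles:
    """Segment each chromosome into consecutive blocks of exactly ``window``
    informative CpGs (pooled across samples); the trailing partial block is
    dropped.  CpG density is the number of registry CpGs in the spanned
    interval divided by the span length in base pairs.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    samples = calls.sample_ids
    s_index = {s: j for j, s in enumerate(samples)}

    records = []
    meth_rows = []
    total_rows = []
    for chrom, grp in calls.calls.groupby("chrom", sort=True):
        pooled = grp.groupby("pos")[["meth", "unmeth"]].sum()
        pooled_total = (pooled["meth"] + pooled["unmeth"]).to_numpy()
        inf_pos = pooled.index.to_numpy()[pooled_total >= 1]
        n_tiles = inf_pos.size // window
        if n_tiles == 0:
            continue
        registry = calls.registry(chrom)
        # per-sample counts at informative positions
        pivot_m = grp.pivot_table(index="pos", columns="sample", values="meth",
                                  aggfunc="sum", fill_value=0)
        pivot_u = grp.pivot_table(index="pos", columns="sample", values="unmeth",
                                  aggfunc="sum", fill_value=0)
        pivot_m = pivot_m.reindex(inf_pos, fill_value=0)
        pivot_t = (pivot_m + pivot_u.reindex(inf_pos, fill_value=0))
        m_arr = np.zeros((inf_pos.size, len(samples)))
        t_arr = np.zeros((inf_pos.size, len(samples)))
        for s in pivot_m.columns:
            m_arr[:, s_index[s]] = pivot_m[s].to_numpy()
            t_arr[:, s_index[s]] = pivot_t[s].to_numpy()
        for k in range(n_tiles):
            sel = slice(k * window, (k + 1) * window)
            start = int(inf_pos[sel][0])
            end = int(inf_pos[sel][-1])
            span = end - start + 1
            n_cpgs = int(np.searchsorted(registry, end, side="right")
                         - np.searchsorted(registry, start, side="left"))
            records.append({
                "chrom": chrom, "start": start, "end": end,
                "n_informative": window, "n_cpgs": n_cpgs,
                "cpg_density": n_cpgs / span,
            })
            meth_rows.append(m_arr[sel].sum(axis=0))
            total_rows.append(t_arr[sel].sum(axis=0))

    table = pd.DataFrame(records, columns=["chrom", "start", "end",
                                           "n_informative", "n_cpgs", "cpg_density"])
    meth = np.asarray(meth_rows) if meth_rows else np.zeros((0, len(samples)))
    total = np.asarray(total_rows) if total_rows else np.zeros((0, len(samples)))
    return Tiles(table=table, meth=meth, total=total, sample_ids=samples)


def filter_tiles(tiles: Tiles, preset: str) -> Tiles:
    """Context-specific tile filters mirroring common feature analyses.

    ``enhancer``: keep the half of tiles with the highest total coverage
    depth.  ``exon_promoter``: regions of very mixed density; keep tiles
    below the 1st quartile of CpG density AND above the 95th percentile of
    total coverage.
    """
    total_cov = tiles.total.sum(axis=1)
    dens = tiles.table["cpg_density"].to_numpy()
    if preset == "enhancer":
        keep = total_cov > np.median(total_cov)
    elif preset == "exon_promoter":
        keep = (dens < np.quantile(dens, 0.25)) & (total_cov > np.quantile(total_cov, 0.95))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    idx = np.flatnonzero(keep)
    return Tiles(
        table=tiles.table.iloc[idx].reset_index(drop=True),
        meth=tiles.meth[idx],
        total=tiles.total[idx],
        sample_ids=tiles.sample_ids,
    )
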