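"""Readers and writers for methylation call tables and sample sheets.

The on-disk dialect is the Bismark coverage format: tab-separated
``chrom, start, end, percent_methylation, count_methylated, count_unmethylated``
with 1-based inclusive coordinates (start == end for a CpG call).  Sample
sheets are TSV with at least a ``sample`` column plus metadata such as
``time_point`` (minutes), ``cell_id`` or ``condition``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "read_bismark_cov",
    "write_bismark_cov",
    "read_sample_sheet",
    "write_sample_sheet",
]

_COV_COLUMNS = ["chrom", "start", "end", "pct_meth", "meth", "unmeth"]


def read_bismark_cov(path: Union[str, Path]) -> pd.DataFrame:
    """Read one Bismark coverage file into (chrom, pos, meth, unmeth).

    ``pos`` is the 1-based CpG coordinate; the percent column is dropped
    (recomputable) after a consistency check.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS,
                     dtype={"chrom": str})
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    if not (df["start"] == df["end"]).all():
        raise ValueError(f"{path}: expected single-CpG records (start == end)")
    out = df[["chrom", "start", "meth", "unmeth"]].rename(columns={"start": "pos"})
    return out


def write_bismark_cov(calls: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write (chrom, pos, meth, unmeth) records as a Bismark coverage file."""
    total = calls["meth"] + calls["unmeth"]
    pct = (100.0 * calls["meth"] / total.where(total > 0)).fillna(0.0)
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["pos"],
        "end": calls["pos"],
        "pct_meth": pct,
        "meth": calls["meth"].astype(int),
        "unmeth": calls["unmeth"].astype(int),
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet must have a 'sample' column")
    if sheet["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: Union[str, Path]) -> None:
    sheet.to_csv(path, sep="\t", index=False)
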