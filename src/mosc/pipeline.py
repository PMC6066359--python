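"""End-to-end orchestration: simulate, analyze, report.

A run config (YAML) names the stages to execute and a mandatory seed; each
stage writes its outputs under ``out_dir/<stage>`` together with a manifest
keyed by a hash of the stage configuration, so reruns with an unchanged
config reuse cached outputs.  The final summary is machine-readable JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

logger = logging.getLogger("mosc.pipeline")

STAGES = ("single_cell", "bulk", "amplicon", "expression", "dde")

REQUIRED_FIELDS = ("seed", "out_dir")


class ConfigError(ValueError):
    pass


def load_config(path_or_dict: Union[str, Path, dict]) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    for fieldname in REQUIRED_FIELDS:
        if fieldname not in cfg:
            raise ConfigError(f"run config missing required field: {fieldname!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("fast", True)
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    return cfg


def _stage_hash(cfg: dict, stage: str) -> str:
    payload = {"stage": stage, "seed": cfg["seed"], "fast": cfg["fast"],
               "options": cfg.get(stage, {})}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _cached(stage_dir: Path, digest: str) -> bool:
    mark = stage_dir / "stage_hash.txt"
    return mark.exists() and mark.read_text().strip() == digest


def _mark(stage_dir: Path, digest: str) -> None:
    (stage_dir / "stage_hash.txt").write_text(digest + "\n")


def run_pipeline(config: Union[str, Path, dict], force: bool = False) -> dict:
    """Execute the configured stages in dependency order; returns (and
    writes) the JSON summary of all computed statistics."""
    from scipy import stats as _sstats

    from .dip import bimodality_scan
    from .pseudotime import pseudo_time
    from .spectral import amplicon_scan, detrend_poly2, spectral_enrichment
    from .synth import (generate_amplicon_timecourse, generate_bulk_timecourse,
                        generate_expression_matrix, generate_single_cell_dataset,
                        make_genome)
    from .tiling import tile_by_informative_cpgs
    from .variance import binned_profile, excess_variance

    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    fast = bool(cfg["fast"])
    summary: dict = {"seed": seed, "fast": fast, "stages": {}}
    n_cells = 40 if fast else 80
    n_null = 5000 if fast else 50000

    genome = make_genome(seed=seed)
    density_bins = np.array([0.0, 0.01, 0.02, 0.03, 0.05, 0.10, 0.30])

    for stage in cfg["stages"]:
        stage_dir = out_dir / stage
        digest = _stage_hash(cfg, stage)
        result_file = stage_dir / "result.json"
        if not force and _cached(stage_dir, digest) and result_file.exists():
            logger.info("[%s] cache hit (%s)", stage, digest)
            summary["stages"][stage] = json.loads(result_file.read_text())
            continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        logger.info("[%s] running", stage)

        if stage == "single_cell":
            ds = generate_single_cell_dataset(genome, n_cells=n_cells, seed=seed)
            ds.write(stage_dir / "data")
            tiles = tile_by_informative_cpgs(ds.calls, window=50)
            ev = excess_variance(tiles)
            prof = binned_profile(tiles.table["cpg_density"].to_numpy(), ev,
                                  density_bins, seed=seed)
            peak = prof.loc[prof["value"].idxmax()]
            res = {
                "n_tiles": int(tiles.n_tiles),
                "excess_variance_profile": prof.to_dict(orient="records"),
                "peak_density_bin": [float(peak["bin_lo"]), float(peak["bin_hi"])],
            }
        elif stage == "bulk":
            bd = generate_bulk_timecourse(genome, seed=seed + 1)
            bd.write(stage_dir / "data")
            tiles = tile_by_informative_cpgs(bd.calls, window=50)
            meta = bd.calls.samples.set_index("sample")
            times = np.sort(meta["time_point"].unique())
            rates = tiles.rates()
            cols = {
                t: [j for j, s in enumerate(tiles.sample_ids)
                    if float(meta.loc[s, "time_point"]) == t]
                for t in times
            }
            series = np.stack([np.nanmean(rates[:, cols[t]], axis=1) for t in times], 1)
            dens = tiles.table["cpg_density"].to_numpy()
            sel = (dens >= 0.01) & (dens <= 0.05)
            detr = np.vstack([detrend_poly2(times, s) for s in series[sel]])
            periods = np.arange(100.0, 1201.0, 25.0)
            spec = spectral_enrichment(times, detr, periods, n_null=n_null, seed=seed)
            res = {
                "n_elements": int(spec.n_elements),
                "significant_periods_min": [float(x) for x in spec.significant_periods],
                "best_period_min": float(periods[int(np.argmax(spec.observed_mean - spec.null_mean))]),
            }
        elif stage == "amplicon":
            am = generate_amplicon_timecourse(seed=seed + 2)
            am.to_frame().to_csv(stage_dir / "amplicon.tsv", sep="\t", index=False)
            scan = amplicon_scan(am.times_min, am.meth, am.total, groups=am.groups,
                                 seed=seed)
            trt = am.groups == "treatment"
            res = {
                "n_loci": int(trt.sum()),
                "significant_treatment": int(scan.significant[trt].sum()),
                "significant_control": int(scan.significant[~trt].sum()),
                "recovered_truth": int(np.sum(scan.significant & am.truth_oscillating)),
                "fisher_p": scan.fisher_p,
            }
        elif stage == "expression":
            ex = generate_expression_matrix(n_cells=200, seed=seed + 3)
            ex.counts.to_csv(stage_dir / "counts.tsv", sep="\t")
            from .expression import normalize_expression

            norm = normalize_expression(ex.counts, ex.lifetimes)
            meth = norm.loc[["Dnmt3a", "Dnmt3b", "Dnmt3l", "Dnmt1"]].sum()
            dem = norm.loc[["Tet1", "Tet2", "Tet3", "Tdg"]].sum()
            r2 = float(_sstats.pearsonr(meth - dem, ex.truth["global_meth"])[0] ** 2)
            res = {"dnmt_tet_r2": r2,
                   "lifetime_median_h": float(ex.lifetimes.median())}
        elif stage == "dde":
            from .dde import DelayModelParams, hopf_threshold_scan

            grid = np.arange(0.0, 10.01, 0.5 if fast else 0.25)
            scan = hopf_threshold_scan(
                DelayModelParams(delta_tau=0.0, u0=1.6, v0=0.4,
                                 t_max=400 if fast else 1000),
                grid,
            )
            res = {"hopf_threshold": scan["threshold"],
                   "grid_step": float(grid[1] - grid[0])}
        else:  # pragma: no cover
            raise ConfigError(f"unhandled stage {stage}")

        result_file.write_text(json.dumps(res, indent=2))
        _mark(stage_dir, digest)
        summary["stages"][stage] = res

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
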