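"""Synthetic methylome datasets with known ground truth.

Emulates the study designs around genome-scale methylation oscillations:

- single-cell methylomes: each cell carries one oscillator phase shared
  coherently across the genome; the oscillation amplitude depends on the
  local CpG density, peaking near 2.5% and vanishing in CpG-rich regions;
  reads follow the truncated-exponential coverage / binomial call model.
- a release time course: bulk samples on a 31-point non-uniform grid over
  56 h 30 min (triplicates), rising logistic trend plus a 150-min
  oscillation.
- amplicon panels: 14 deeply sequenced loci at 47 x 20-min spacing, a
  fraction oscillating, with a matched flat control panel.
- an expression matrix whose Dnmt/Tet summary is nearly uncorrelated with
  the cells' global methylation (target R^2 ~ 0.06) and transcript
  lifetimes with ~7 h median.

Genome coordinates are base pairs, times are minutes, and every generator is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .tiling import MethCallTable
from .turnover import ReadNoiseModel

__all__ = [
    "GenomeSpec",
    "make_genome",
    "amplitude_profile",
    "bulk_time_grid",
    "SingleCellDataset",
    "generate_single_cell_dataset",
    "BulkDataset",
    "generate_bulk_timecourse",
    "AmpliconDataset",
    "generate_amplicon_timecourse",
    "ExpressionDataset",
    "generate_expression_matrix",
]

DEFAULT_DENSITIES = (0.005, 0.01, 0.015, 0.022, 0.028, 0.04, 0.06, 0.125, 0.20)


def amplitude_profile(density: np.ndarray, a0: float = 0.30, d_star: float = 0.025,
                      log_width: float = 0.5, suppress_above: float = 0.10) -> np.ndarray:
    """Oscillation amplitude as a function of CpG density: log-Gaussian bump
    peaking at ``d_star`` with hard suppression in CpG-rich regions."""
    d = np.asarray(density, dtype=float)
    a = a0 * np.exp(-((np.log(d) - np.log(d_star)) ** 2) / (2 * log_width**2))
    return np.where(d >= suppress_above, 0.0, a)


@dataclass
class GenomeSpec:
    """Synthetic genome: CpG positions arranged in constant-density blocks."""

    blocks: pd.DataFrame          # chrom, block, start, end, density_target,
                                  # density_realized, n_cpgs, affinity
    cpg_positions: Dict[str, np.ndarray]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_cpgs(self, row) -> np.ndarray:
        pos = self.cpg_positions[row["chrom"]]
        return pos[(pos >= row["start"]) & (pos <= row["end"])]


def make_genome(
    densities: Sequence[float] = DEFAULT_DENSITIES,
    blocks_per_density: int = 8,
    cpgs_per_block: int = 100,
    dense_cpgs_per_block: int = 200,
    seed: int = 0,
    chrom: str = "chrS",
) -> GenomeSpec:
    """Build a single-chromosome genome of density blocks (0.5%-20%).

    Within a block, CpG spacing is regular at 1/density with +-20% jitter,
    keeping the realized density within 10% of target; dense blocks
    (>= 10%) get more CpGs so that 100-CpG windows fit inside one block.
    Block sizes are exact multiples of the standard 50- and 100-CpG tiling
    windows, so fully covered data tile without blocks straddling tiles.
    The per-block DNMT3-affinity proxy follows the amplitude profile.
    """
    rng = np.random.default_rng(seed)
    positions = []
    records = []
    cursor = 1000
    block_id = 0
    for d in densities:
        n_cpg = dense_cpgs_per_block if d >= 0.10 else cpgs_per_block
        spacing = 1.0 / d
        for _ in range(blocks_per_density):
            jitter = rng.uniform(0.8, 1.2, size=n_cpg - 1)
            gaps = np.maximum(2, np.round(spacing * jitter).astype(int))
            pos = cursor + np.concatenate([[0], np.cumsum(gaps)])
            span = pos[-1] - pos[0] + 1
            realized = n_cpg / span
            records.append({
                "chrom": chrom, "block": block_id,
                "start": int(pos[0]), "end": int(pos[-1]),
                "density_target": d, "density_realized": realized,
                "n_cpgs": n_cpg,
                "affinity": float(amplitude_profile(np.array([d]))[0]),
            })
            positions.append(pos)
            cursor = int(pos[-1]) + int(10 * spacing) + 500
            block_id += 1
    blocks = pd.DataFrame(records)
    return GenomeSpec(blocks=blocks, cpg_positions={chrom: np.concatenate(positions)})


@dataclass
class TruthTables:
    cells: Optional[pd.DataFrame] = None
    blocks: Optional[pd.DataFrame] = None
    extra: dict = field(default_factory=dict)


def _write_dataset(out_dir, calls: MethCallTable, truth: TruthTables,
                   manifest: dict) -> None:
    from .io import write_bismark_cov, write_sample_sheet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, grp in calls.calls.groupby("sample"):
        write_bismark_cov(grp, out / f"{sample}.cov")
    write_sample_sheet(calls.samples, out / "samples.tsv")
    if truth.cells is not None:
        truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    if truth.blocks is not None:
        truth.blocks.to_csv(out / "truth_blocks.tsv", sep="\t", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


@dataclass
class SingleCellDataset:
    calls: MethCallTable
    truth: TruthTables
    genome: GenomeSpec
    params: dict

    def write(self, out_dir) -> None:
        _write_dataset(out_dir, self.calls, self.truth, self.params)


def generate_single_cell_dataset(
    genome: GenomeSpec,
    n_cells: int = 80,
    noise: Optional[ReadNoiseModel] = None,
    coherence: float = 0.9,
    amplitude_scale: float = 1.0,
    midpoint: float = 0.5,
    age_span: float = 0.2,
    phase_from_age: bool = False,
    pt_cycles: float = 3.0,
    scenario: str = "steady",
    waveform: str = "relaxation",
    seed: int = 0,
) -> SingleCellDataset:
    """Single-cell methylomes with coherent per-cell oscillator phase.

    Block true rate: ``midpoint + amplitude(density) * w(phase)`` for
    CpG-poor blocks, where the waveform w is either a pure sinusoid
    (``waveform='sin'``) or, by default, a sharpened sinusoid
    sgn(sin)|sin|^(1/3) emulating the anharmonic limit cycle of the
    turnover model, which dwells near the oscillation extremes; CpG-dense blocks (>= 10%) instead rise monotonically
    with the cell's developmental age, spread over ``age_span`` of the full
    developmental range (small in steady-state culture, 1.0 for an in
    vivo-like progression), and do not oscillate.  The per-block phase mixes the cell's global phase with an
    incoherent jitter weighted by ``1 - coherence``.  With
    ``phase_from_age`` the cell phase follows its age through ``pt_cycles``
    oscillation cycles (for pseudo-time recovery); otherwise phases are
    uniform (steady-state snapshot).  Each cell observes each block at
    ``s ~ noise`` informative CpGs with one binomial read per CpG.

    ``scenario='invivo'`` instead models a snapshot of asynchronous global
    de novo methylation: CpG-poor blocks cycle through stage offsets (not
    yet methylated / transitioning / saturated), the per-cell stage follows
    its developmental age through a steep sigmoid, and the oscillation is
    superimposed.  Transitioning blocks are smeared across cells by onset
    variability (unimodal); blocks at the extremes expose the oscillation
    (bimodal) — the in vivo bimodality signature.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if not 0 <= coherence <= 1:
        raise ValueError("coherence must lie in [0, 1]")
    if scenario not in ("steady", "invivo"):
        raise ValueError("scenario must be 'steady' or 'invivo'")
    if waveform not in ("sin", "relaxation"):
        raise ValueError("waveform must be 'sin' or 'relaxation'")
    noise = noise or ReadNoiseModel()
    rng = np.random.default_rng(seed)
    ages = rng.uniform(0, 1, size=n_cells)
    if phase_from_age:
        phases = 2 * np.pi * pt_cycles * ages
    else:
        phases = rng.uniform(0, 2 * np.pi, size=n_cells)

    amp = amplitude_scale * amplitude_profile(
        genome.blocks["density_target"].to_numpy())
    dense = genome.blocks["density_target"].to_numpy() >= 0.10
    stage_offsets = np.tile([-0.5, 0.5, 1.5], genome.n_blocks // 3 + 1)[: genome.n_blocks]

    cell_ids = [f"cell{c:03d}" for c in range(n_cells)]
    rows = []
    for c, cell in enumerate(cell_ids):
        jitter = rng.uniform(-np.pi, np.pi, size=genome.n_blocks)
        block_phase = phases[c] + (1 - coherence) * jitter
        s_ph = np.sin(block_phase)
        wave = s_ph if waveform == "sin" else np.sign(s_ph) * np.abs(s_ph) ** (1 / 3)
        age_eff = 0.5 + age_span * (ages[c] - 0.5)
        if scenario == "invivo":
            stage = 0.1 + 0.8 / (1 + np.exp(-4.0 * (ages[c] - stage_offsets)))
            poor_rate = stage + amp * wave
            dense_rate = 0.15 + 0.7 * ages[c]
        else:
            poor_rate = midpoint + amp * wave
            dense_rate = 0.15 + 0.7 * age_eff
        rate = np.where(dense, dense_rate, poor_rate)
        rate = np.clip(rate, 0.01, 0.99)
        s = noise.sample_coverage(rng, size=genome.n_blocks)
        for b, (_, blk) in enumerate(genome.blocks.iterrows()):
            cpgs = genome.block_cpgs(blk)
            k = min(int(s[b]), cpgs.size)
            chosen = np.sort(rng.choice(cpgs, size=k, replace=False))
            meth = rng.random(k) < rate[b]
            rows.append(pd.DataFrame({
                "sample": cell, "chrom": blk["chrom"], "pos": chosen,
                "meth": meth.astype(int), "unmeth": (~meth).astype(int),
            }))
    calls_df = pd.concat(rows, ignore_index=True)
    samples = pd.DataFrame({"sample": cell_ids, "cell_id": cell_ids,
                            "condition": "primed"})
    calls = MethCallTable(calls_df, samples, cpg_positions=genome.cpg_positions)
    truth = TruthTables(
        cells=pd.DataFrame({"sample": cell_ids, "phase": phases, "age": ages,
                            "amplitude_scale": amplitude_scale}),
        blocks=genome.blocks.assign(amplitude=amp, midpoint=midpoint),
    )
    params = {"kind": "single_cell", "n_cells": n_cells, "coherence": coherence,
              "amplitude_scale": amplitude_scale, "seed": seed, "age_span": age_span,
              "coverage_mean": noise.coverage_mean, "min_coverage": noise.min_coverage,
              "phase_from_age": phase_from_age, "pt_cycles": pt_cycles,
              "scenario": scenario, "waveform": waveform}
    return SingleCellDataset(calls=calls, truth=truth, genome=genome, params=params)


def bulk_time_grid(n_points: int = 31, cycle=(75.0, 105.0, 159.0)) -> np.ndarray:
    """Non-uniform release time grid in minutes: repeating spacing cycle
    (mean 113 min), 31 points spanning 0 to 56 h 30 min."""
    gaps = np.tile(np.asarray(cycle, dtype=float), int(np.ceil((n_points - 1) / len(cycle))))
    return np.concatenate([[0.0], np.cumsum(gaps[: n_points - 1])])


@dataclass
class BulkDataset:
    calls: MethCallTable
    truth: TruthTables
    genome: GenomeSpec
    times_min: np.ndarray
    params: dict

    def write(self, out_dir) -> None:
        _write_dataset(out_dir, self.calls, self.truth, self.params)


def generate_bulk_timecourse(
    genome: GenomeSpec,
    period_min: float = 150.0,
    amplitude_scale: float = 0.12,
    replicates: int = 3,
    coverage: int = 200,
    trend: tuple[float, float] = (0.2, 0.7),
    replicate_sd: float = 0.01,
    n_points: int = 31,
    seed: int = 0,
) -> BulkDataset:
    """Bulk release time course: triplicates at 31 non-uniform time points.

    Block true rate = logistic trend (rising from ``trend[0]`` to
    ``trend[1]`` over the course) + ``amplitude_scale * amplitude(density)``
    times a common-phase 150-min sinusoid, plus replicate jitter; binomial
    reads at ``coverage`` per CpG.  ``amplitude_scale`` rescales the
    single-cell amplitude profile down to the population-average residual
    oscillation seen in bulk.
    """
    rng = np.random.default_rng(seed)
    times = bulk_time_grid(n_points)
    span = times[-1]
    amp = amplitude_scale * amplitude_profile(genome.blocks["density_target"].to_numpy())
    dense = genome.blocks["density_target"].to_numpy() >= 0.10

    sample_rows = []
    call_frames = []
    for ti, t in enumerate(times):
        trend_val = trend[0] + (trend[1] - trend[0]) / (1 + np.exp(-(t - span / 2) / (span / 8)))
        osc = np.sin(2 * np.pi * t / period_min)
        for r in range(replicates):
            sample = f"t{ti:02d}r{r}"
            rate = np.where(dense, trend_val + 0.15, trend_val + amp * osc)
            rate = np.clip(rate + rng.normal(0, replicate_sd, size=genome.n_blocks),
                           0.01, 0.99)
            frames = []
            for b, (_, blk) in enumerate(genome.blocks.iterrows()):
                cpgs = genome.block_cpgs(blk)
                meth = rng.binomial(coverage, rate[b], size=cpgs.size)
                frames.append(pd.DataFrame({
                    "sample": sample, "chrom": blk["chrom"], "pos": cpgs,
                    "meth": meth, "unmeth": coverage - meth,
                }))
            call_frames.append(pd.concat(frames, ignore_index=True))
            sample_rows.append({"sample": sample, "time_point": float(t),
                                "replicate": r, "condition": "release"})
    calls = MethCallTable(
        pd.concat(call_frames, ignore_index=True),
        pd.DataFrame(sample_rows),
        cpg_positions=genome.cpg_positions,
    )
    truth = TruthTables(
        blocks=genome.blocks.assign(amplitude=amp, period_min=period_min),
        extra={"times_min": times.tolist(), "period_min": period_min},
    )
    params = {"kind": "bulk", "period_min": period_min, "seed": seed,
              "amplitude_scale": amplitude_scale, "coverage": coverage,
              "replicates": replicates}
    return BulkDataset(calls=calls, truth=truth, genome=genome,
                       times_min=times, params=params)


@dataclass
class AmpliconDataset:
    times_min: np.ndarray
    meth: np.ndarray              # (n_loci_total, n_times) methylated reads
    total: np.ndarray
    groups: np.ndarray            # 'treatment' / 'control'
    truth_oscillating: np.ndarray
    params: dict

    def to_frame(self) -> pd.DataFrame:
        n_loci, n_t = self.meth.shape
        return pd.DataFrame({
            "locus": np.repeat(np.arange(n_loci), n_t),
            "group": np.repeat(self.groups, n_t),
            "time_min": np.tile(self.times_min, n_loci),
            "meth": self.meth.ravel(),
            "total": self.total.ravel(),
        })


def generate_amplicon_timecourse(
    n_loci: int = 14,
    oscillating_fraction: float = 4 / 14,
    period_min: float = 150.0,
    n_points: int = 47,
    spacing_min: float = 20.0,
    reads_per_point: int = 300,
    snr: float = 1.0,
    include_control: bool = True,
    seed: int = 0,
) -> AmpliconDataset:
    """Deep amplicon panels: oscillating loci at 150 min plus flat controls.

    The oscillation amplitude is set from ``snr`` as amplitude =
    snr * sqrt(0.25 / reads_per_point) (per-point binomial noise at rate
    0.5).  The control panel mirrors the treatment panel without any
    oscillation.
    """
    if not 0 <= oscillating_fraction <= 1:
        raise ValueError("oscillating_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    times = np.arange(n_points) * spacing_min
    n_osc = int(round(oscillating_fraction * n_loci))
    amplitude = snr * np.sqrt(0.25 / reads_per_point)

    panels = [("treatment", n_osc)] + ([("control", 0)] if include_control else [])
    meth_rows, tot_rows, groups, osc_flags = [], [], [], []
    for group, n_osc_g in panels:
        for i in range(n_loci):
            base = rng.uniform(0.35, 0.65)
            osc = i < n_osc_g
            phase = rng.uniform(0, 2 * np.pi)
            rate = base + (amplitude * np.sin(2 * np.pi * times / period_min + phase)
                           if osc else 0.0)
            rate = np.clip(rate, 0.01, 0.99)
            total = rng.poisson(reads_per_point, size=n_points)
            meth = rng.binomial(total, rate)
            meth_rows.append(meth)
            tot_rows.append(total)
            groups.append(group)
            osc_flags.append(osc)
    params = {"kind": "amplicon", "n_loci": n_loci, "period_min": period_min,
              "snr": snr, "reads_per_point": reads_per_point, "seed": seed,
              "oscillating_fraction": oscillating_fraction}
    return AmpliconDataset(
        times_min=times, meth=np.asarray(meth_rows), total=np.asarray(tot_rows),
        groups=np.asarray(groups), truth_oscillating=np.asarray(osc_flags),
        params=params,
    )


@dataclass
class ExpressionDataset:
    counts: pd.DataFrame          # genes x cells
    lifetimes: pd.Series          # hours
    truth: pd.DataFrame           # per-cell global methylation + ratio signal
    params: dict


METH_GENES = ["Dnmt3a", "Dnmt3b", "Dnmt3l", "Dnmt1"]
DEMETH_GENES = ["Tet1", "Tet2", "Tet3", "Tdg"]


def generate_expression_matrix(
    n_cells: int = 200,
    n_genes: int = 120,
    target_r2: float = 0.06,
    global_meth: Optional[np.ndarray] = None,
    mean_counts: float = 200.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Expression counts whose Dnmt/Tet log-ratio summary has squared
    correlation ~ ``target_r2`` with the cells' global methylation.

    Gene panel includes the methylation writers (Dnmt3a/b/l, Dnmt1) and
    erasers (Tet1/2/3, Tdg) plus unrelated genes; transcript lifetimes are
    lognormal with median ~= 7 h.
    """
    if not 0 <= target_r2 <= 0.5:
        raise ValueError("target_r2 must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if global_meth is None:
        global_meth = rng.uniform(0.15, 0.85, size=n_cells)
    z = (global_meth - global_meth.mean()) / max(global_meth.std(), 1e-12)
    ratio_signal = np.sqrt(target_r2) * z + np.sqrt(1 - target_r2) * rng.standard_normal(n_cells)

    other = [f"gene{i:03d}" for i in range(n_genes - len(METH_GENES) - len(DEMETH_GENES))]
    genes = METH_GENES + DEMETH_GENES + other
    log_mu = np.log(mean_counts)
    counts = np.empty((len(genes), n_cells), dtype=np.int64)
    for gi, g in enumerate(genes):
        if g in METH_GENES:
            lam = np.exp(log_mu + 0.25 * ratio_signal / len(METH_GENES) * 4)
        elif g in DEMETH_GENES:
            lam = np.exp(log_mu - 0.25 * ratio_signal / len(DEMETH_GENES) * 4)
        else:
            lam = np.exp(log_mu + 0.3 * rng.standard_normal(n_cells))
        counts[gi] = rng.poisson(lam)
    cells = [f"cell{c:03d}" for c in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=genes, columns=cells)
    lifetimes = pd.Series(
        np.exp(np.log(7.0) + 0.6 * rng.standard_normal(len(genes))), index=genes,
        name="lifetime_h",
    )
    truth = pd.DataFrame({"sample": cells, "global_meth": global_meth,
                          "ratio_signal": ratio_signal})
    params = {"kind": "expression", "n_cells": n_cells, "target_r2": target_r2,
              "seed": seed}
    return ExpressionDataset(counts=counts_df, lifetimes=lifetimes, truth=truth,
                             params=params)
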