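"""Synthetic-data generators: determinism, round trips, truth invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosc.expression import normalize_expression
from mosc.synth import (METH_GENES, DEMETH_GENES, amplitude_profile,
                        bulk_time_grid, generate_amplicon_timecourse,
                        generate_bulk_timecourse, generate_expression_matrix,
                        generate_single_cell_dataset, make_genome)
from mosc.tiling import MethCallTable, tile_by_informative_cpgs
from mosc.variance import excess_variance, feature_correlation


def test_genome_block_densities_within_ten_percent(genome):
    rel = np.abs(genome.blocks["density_realized"] / genome.blocks["density_target"] - 1)
    assert rel.max() < 0.10
    for chrom, pos in genome.cpg_positions.items():
        assert np.all(np.diff(pos) > 0)


def test_amplitude_profile_peaks_near_enhancer_density():
    d = np.array([0.005, 0.01, 0.022, 0.025, 0.028, 0.06, 0.10, 0.20])
    a = amplitude_profile(d)
    assert d[np.argmax(a)] == pytest.approx(0.025)
    assert np.all(a[d >= 0.10] == 0.0)


def test_truth_table_amplitude_invariants(sc_dataset):
    blocks = sc_dataset.truth.blocks
    in_peak = blocks[(blocks["density_target"] >= 0.02) & (blocks["density_target"] <= 0.03)]
    assert in_peak["amplitude"].max() == blocks["amplitude"].max()
    assert np.all(blocks.loc[blocks["density_target"] >= 0.10, "amplitude"] == 0.0)


def test_seeded_determinism(small_genome):
    a = generate_single_cell_dataset(small_genome, n_cells=12, seed=5)
    b = generate_single_cell_dataset(small_genome, n_cells=12, seed=5)
    c = generate_single_cell_dataset(small_genome, n_cells=12, seed=6)
    pd.testing.assert_frame_equal(a.calls.calls, b.calls.calls)
    assert not a.calls.calls.equals(c.calls.calls)


def test_write_read_round_trip(tmp_path, small_genome):
    ds = generate_single_cell_dataset(small_genome, n_cells=12, seed=5)
    out = tmp_path / "ds"
    ds.write(out)
    from mosc.io import read_sample_sheet

    sheet = read_sample_sheet(out / "samples.tsv")
    paths = {s: out / f"{s}.cov" for s in sheet["sample"]}
    back = MethCallTable.from_files(paths, sheet)
    merged = back.calls.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)
    orig = ds.calls.calls.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(
        merged[["sample", "pos", "meth", "unmeth"]].astype({"pos": "int64"}),
        orig[["sample", "pos", "meth", "unmeth"]].astype({"pos": "int64"}),
    )
    # rewriting parsed data reproduces the files byte for byte
    from mosc.io import write_bismark_cov
    s0 = sheet["sample"][0]
    p2 = tmp_path / "rewrite.cov"
    write_bismark_cov(back.calls[back.calls["sample"] == s0], p2)
    assert p2.read_bytes() == (out / f"{s0}.cov").read_bytes()


def test_bulk_time_grid_matches_design():
    t = bulk_time_grid()
    assert t.size == 31
    assert t[0] == 0.0
    assert t[-1] == pytest.approx(56 * 60 + 30)  # 56 h 30 min
    assert np.all(np.diff(t) > 0)
    assert len(np.unique(np.diff(t))) > 1  # non-uniform spacing


def test_amplitude_zero_data_has_unit_excess_variance(small_genome):
    ds = generate_single_cell_dataset(small_genome, n_cells=40,
                                      amplitude_scale=0.0, age_span=0.0, seed=7)
    tiles = tile_by_informative_cpgs(ds.calls, window=50)
    ev = excess_variance(tiles)
    assert np.nanmean(ev) == pytest.approx(1.0, abs=0.1)


def test_full_coherence_correlates_density_blocks(small_genome):
    """With coherence 1, per-cell means of the oscillation-prone density
    levels (1.5-5%, where the amplitude profile is large) rise and fall
    together across cells."""
    ds = generate_single_cell_dataset(small_genome, n_cells=40, coherence=1.0,
                                      seed=8)
    tiles = tile_by_informative_cpgs(ds.calls, window=50)
    dens = tiles.table["cpg_density"].to_numpy()
    rates = tiles.rates()
    feats = {}
    for lo, hi in [(0.015, 0.025), (0.025, 0.03), (0.03, 0.05)]:
        sel = (dens >= lo) & (dens < hi)
        feats[f"d{lo}"] = np.nanmean(rates[sel], axis=0)
    corr = feature_correlation(pd.DataFrame(feats)).to_numpy()
    off = corr[~np.eye(len(feats), dtype=bool)]
    assert np.all(off > 0.6)


def test_enhancer_vs_dense_spread_contrast(sc_dataset, sc_tiles):
    """Cross-cell spread of CpG-poor (2-3%) means far exceeds the spread of
    CpG-dense (>= 10%) means."""
    dens = sc_tiles.table["cpg_density"].to_numpy()
    rates = sc_tiles.rates()
    poor = np.nanmean(rates[(dens >= 0.02) & (dens <= 0.03)], axis=0)
    rich = np.nanmean(rates[dens >= 0.10], axis=0)
    assert np.nanstd(poor) > 3 * np.nanstd(rich)


def test_amplicon_generator_contract():
    am = generate_amplicon_timecourse(oscillating_fraction=0.0, seed=4)
    assert not am.truth_oscillating.any()
    am2 = generate_amplicon_timecourse(seed=4)
    assert am2.truth_oscillating.sum() == 4
    assert am2.times_min.size == 47
    assert np.allclose(np.diff(am2.times_min), 20.0)
    assert am2.meth.shape == (28, 47)
    assert np.all(am2.meth <= am2.total)
    df = am2.to_frame()
    assert set(df.columns) == {"locus", "group", "time_min", "meth", "total"}


def test_expression_matrix_r2_targets():
    ex0 = generate_expression_matrix(target_r2=0.0, seed=3)
    norm = normalize_expression(ex0.counts, ex0.lifetimes)
    ratio = norm.loc[METH_GENES].sum() - norm.loc[DEMETH_GENES].sum()
    r2 = stats.pearsonr(ratio, ex0.truth["global_meth"])[0] ** 2
    assert r2 < 0.05

    ex = generate_expression_matrix(target_r2=0.06, seed=3)
    norm = normalize_expression(ex.counts, ex.lifetimes)
    ratio = norm.loc[METH_GENES].sum() - norm.loc[DEMETH_GENES].sum()
    r2 = stats.pearsonr(ratio, ex.truth["global_meth"])[0] ** 2
    assert 0.01 <= r2 <= 0.15


def test_lifetime_median_near_seven_hours():
    ex = generate_expression_matrix(seed=5)
    assert float(ex.lifetimes.median()) == pytest.approx(7.0, rel=0.10)


def test_bulk_generator_writes_parseable_dataset(tmp_path, small_genome):
    bd = generate_bulk_timecourse(small_genome, replicates=1, n_points=5, seed=6)
    assert len(bd.calls.samples) == 5
    out = tmp_path / "bulk"
    bd.write(out)
    assert (out / "manifest.yaml").exists()
    assert (out / "samples.tsv").exists()
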