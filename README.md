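# mosc — genome-scale DNA methylation oscillations

During the exit from naïve pluripotency, embryonic stem cells co-express the
de novo methyltransferases (DNMT3A/B) and the demethylating TET enzymes, so
5mC marks are continuously written and erased.  `mosc` implements the
biophysical models and single-cell statistics needed to show that this
turnover produces coherent, genome-scale **oscillations** in DNA methylation,
and to detect their fingerprints in bisulfite-sequencing data.  It is aimed
at computational epigenomics researchers who want to simulate, calibrate, or
re-analyse methylome time courses and single-cell methylomes.

## The models

**Delayed turnover (continuum).**  With u and v the dimensionless
concentrations of unmodified and methylated cytosines, autocatalytic
methylation and a delay Δτ between 5mC removal and the reappearance of C give

    u'(τ) = v(τ − Δτ) − u(τ) v(τ)
    v'(τ) = u(τ) v(τ) − v(τ)

The balanced stationary branch is u = 1; increasing Δτ destabilizes it
through a Hopf bifurcation and sustained limit cycles appear at Δτ* ≈ 5
(`mosc.dde`).  Structural variants (non-autocatalytic de novo term ε,
Hill-type nonlinearity, time-dependent rates) are included.

**Delayed stochastic turnover.**  The same chemistry as a delayed Gillespie
process on molecule counts (C, M, in-transit repair intermediates), pushed
through the scBS-seq noise model: region coverage s ~ truncated exponential
(mean 14.3, s ≥ 5), positive calls k ~ Binomial(s, M/(C+M)) (`mosc.turnover`).

**Synchronization.**  Single CpGs are stochastic phase oscillators coupled
locally (cooperative DNMT3 action) and globally (enzyme-pool feedback).
Strong-disorder coarse-graining maps the lattice onto a heterogeneous
mean-field (Kuramoto) ensemble, Θ̇ᵢ = ω̃ᵢ + κ̃ᵢ r sin(Ψ − Θᵢ), with critical
coupling κ̃c = 2/[π a g(ω̃₀)] and near-critical growth r ∝ √μ (`mosc.sync`).

**Statistics.**  Coverage-based tiling into windows of 50/100 informative
CpGs, the excess-variance statistic Var(m)/[m̄(1−m̄)/c̄], Lomb–Scargle
spectral enrichment against Monte-Carlo nulls on the same (uneven) time
grid, amplicon period scans with Fisher enrichment, Hartigan's dip test for
cross-cell bimodality, methylation pseudo-time from CpG-dense regions, and
long-lived-transcript expression normalization (`mosc.tiling`,
`mosc.variance`, `mosc.spectral`, `mosc.dip`, `mosc.pseudotime`,
`mosc.expression`).  The `mosc.synth` generators produce single-cell, bulk
time-course, amplicon and expression datasets with known ground truth, and
`mosc.modality` implements the theory that makes cross-cell **bimodality at
low and high mean methylation** a static fingerprint of oscillations.

## Worked example

```python
import numpy as np
from mosc.dde import DelayModelParams, hopf_threshold_scan
from mosc.synth import make_genome, generate_single_cell_dataset
from mosc.tiling import tile_by_informative_cpgs
from mosc.variance import excess_variance, binned_profile

scan = hopf_threshold_scan(
    DelayModelParams(delta_tau=0.0, u0=1.6, v0=0.4, t_max=1000.0),
    np.arange(0.0, 10.01, 0.25))
print("oscillation onset at delay", scan["threshold"])

genome = make_genome(seed=1)
cells = generate_single_cell_dataset(genome, n_cells=80, seed=2)
tiles = tile_by_informative_cpgs(cells.calls, window=50)
prof = binned_profile(tiles.table["cpg_density"].to_numpy(),
                      excess_variance(tiles),
                      np.array([0, 0.01, 0.02, 0.03, 0.05, 0.10, 0.30]))
print(prof[["bin_lo", "bin_hi", "value"]].round(2))
```

prints

```
oscillation onset at delay 5.0
   bin_lo  bin_hi  value
0    0.00    0.01   1.03
1    0.01    0.02   1.38
2    0.02    0.03   2.94
3    0.03    0.05   1.77
4    0.05    0.10   1.05
5    0.10    0.30   1.02
```

The onset of sustained oscillations sits at dimensionless delay 5.0, and the
excess-variance profile of the simulated single-cell methylomes peaks in the
2–3% CpG-density bin — the density at which oscillation amplitude is
maximal — while CpG-rich regions stay at the technical-noise level of 1.

A thin CLI mirrors the library (`mosc dde|turnover|sync|modality|tile|
varprofile|spectra|amplicon|bimodality|pseudotime|run`); `mosc run --config
run.yaml` executes a seeded simulate→analyze→report pipeline with cached
stages and a JSON summary.

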