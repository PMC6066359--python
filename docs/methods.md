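# Methods

This note records the modelling assumptions, parameter choices, numerical
decisions and known limitations behind `mosc`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Delayed turnover model (`mosc.dde`)

The dimensionless system u' = v(τ−Δτ) − uv, v' = uv − v compresses the
multi-step demethylation pathway (oxidation, excision, repair) into a single
fixed delay between 5mC removal and cytosine reappearance, and the
cooperative action of the de novo methyltransferases into the bilinear uv
term.  Histories are constant, (u0, v0) on [−Δτ, 0]; an optional
`history_v` sets the pre-history of v alone, with `history_v = 0` describing
a system that starts with an empty repair queue (no intermediates in
transit).  The quantity u + v + ∫_{τ−Δτ}^{τ} v ds is conserved exactly by
the baseline dynamics and is the integrator's accuracy monitor.

Integration is method-of-steps with classical fixed-step RK4; the delayed
value at half-steps is linearly interpolated from the stored grid, and the
step is adjusted so the delay is an exact multiple of dt (default
dt = min(Δτ/200, 0.005)).  Oscillation summaries follow roots of dv/dτ:
period = mean spacing of next-nearest roots, amplitude = mean |Δv| at
consecutive extrema, averaged over the last 10 cycles of a 1000-unit run;
"sustained" requires amplitude > 1e-3 and < 5% drift between consecutive
10-cycle windows.  The linearization about (u=1, v̄) has characteristic
equation λ² + v̄λ + v̄(1 − e^{−λΔτ}) = 0, whose Hopf crossing is available
in closed form (ω = √(v̄(2−v̄)), Δτ* = atan2(−ω, v̄−1)/ω mod 2π); λ = 0 is
always a root (the conserved direction) and is excluded from stability
classification.  Because the conserved total ties the asymptotic level v̄ to
Δτ for a fixed history, the oracle comparison in the tests solves the
self-consistent crossing.

The `time_dependent_rates` variant multiplies the methylation and
demethylation terms by user-supplied schedules (default: a logistic ramp on
the methylation term, emulating DNMT3 upregulation after release).

## Delayed Gillespie simulator (`mosc.turnover`)

The master equation's demethylation term is implemented as "initiate at rate
β·M(t), complete at t + Δt": one M is removed immediately and one C is
scheduled for reappearance, with queued intermediates inert.  Because the
delay is fixed the completion queue is FIFO and the simulation is exact in
distribution.  C + M + in-transit is an exact integer invariant.  Defaults
are α = 0.001, β = 1, Δt = 6 with C0 = 3400, M0 = 400: the dimensionless
image (u0, v0) = (3.4, 0.4) with an empty initial queue relaxes onto the
balanced branch at v̄ = 0.4, which is supercritical at Δτ = 6, so observed
rates sweep between low- and high-methylation modes.  (Initial counts of a
few tens of molecules at α = 0.001 would instead give immediate extinction
of M — the methylation propensity must be commensurate with β, i.e.
C0 ~ β/α.)

Sequencing noise: a region is observed through s informative CpGs with
s = ceil(Exp(14.3)) rejected below 5 — the conditional mean is then
(min−1) + 1/(1 − e^{−1/14.3}) ≈ 18.8 — and k ~ Binomial(s, M/(C+M)).

The mean-field equivalence check runs in a smooth damped regime
(α = 2e−4, β = 1, Δt = 3, C0 = 6000, M0 = 4000; u0 = 1.2, v0 = 0.8,
sub-threshold) where per-site propensities are O(1): there the ensemble mean
over 500 paths at N = 10⁴ sites tracks the delay equation within 3 standard
errors at 10 checkpoints.  In spiking regimes the ensemble SE at fixed times
is orders of magnitude below the O(1/N) mean-field bias, so a z-score band
is not the right instrument; those regimes are checked qualitatively
through the rate-distribution sweep.

## Synchronization (`mosc.sync`)

Sites carry discrete phases (n_states ≥ 3, default tests use 12–60) and
step forward at rate n·ω/(2π) (an uncoupled site's step count is Poisson).
Couplings split each partner's weight into forward/backward parts
(1 ± ε·sin(Δθ))/2 — a 2π-periodic agreement bias with sharpness ε ≤ 1
(default 0.5) that keeps rates non-negative; the global term is normalized
per partner (mean-field convention).  The local kernel is exponential,
l(d) = e^{−d/ξ}, truncated at 8ξ.

Coarse-graining merges the adjacent block pair with the strongest kernel
coupling (ties to the lowest index): frequencies are weight-averaged
(Σ nᵢωᵢ conserved exactly), block response κ̃ = mean site κ / n, block
contribution σ̃ = n · mean site σ, and the local strength renormalizes as
λ → λ/(nᵢ+nⱼ) per merge, so it becomes irrelevant after O(log) merges; the
procedure stops when λ falls below the mean |ω̃| and mean κ̃.

The mean-field ensemble integrates Θ̇ᵢ = ω̃ᵢ + κ̃ᵢ r sin(Ψ − Θᵢ) (Heun
scheme) with the **contribution-weighted, normalized** order parameter
r e^{iΨ} = Σσ̃ⱼe^{iΘⱼ} / Σσ̃ⱼ, so r ∈ [0,1] always and the homogeneous
ensemble is the classic Kuramoto model with K = κ̃0 (the unnormalized
convention is recovered by rescaling κ̃).  The critical coupling is
κ̃c = 2/[π a g(ω̃₀)] with σ̃ = aκ̃; heterogeneous couplings synchronize when
a⟨κ̃²⟩ ≥ 2/[π g(ω̃₀)] — variance helps.  Threshold and scaling checks use
quantile-sampled frequency ensembles (equispaced quantiles of the normal or
of the 1–99% trimmed Lorentzian), which removes sampling noise; the √μ law
is fitted on μ ∈ [0.02, 0.1], close enough to onset that the leading-order
exponent dominates (the exact self-consistent solution has log-log slope
0.45 on this window, within the 0.5 ± 0.1 band, versus ~0.39 on
μ ∈ [0.05, 0.25]).

## Methylome statistics

- **Tiling** pools reads across samples; a CpG is informative with ≥ 1
  pooled read, windows hold exactly 50 (bulk/variance) or 100
  (bimodality/pseudo-time) informative CpGs, trailing partials are dropped,
  and CpG density = registry CpGs in the spanned interval / span length.
  Coordinates are 1-based inclusive (Bismark coverage dialect).
- **Excess variance** = coverage-weighted variance of per-sample rates over
  m̄(1−m̄)/c̄ (weights normalized to 1; c̄ = mean coverage of covered
  samples); undefined at m̄ ∈ {0,1} or < 3 covered samples.  On pure
  binomial data its mean is 1 up to an O(1/n_samples) estimation bias.
- **Spectral enrichment** uses the classic variance-normalized Lomb–Scargle
  estimator (vectorized over series and periods; numerically identical to
  `scipy.signal.lombscargle`).  The null is Gaussian white noise simulated
  on the identical time grid (default 10⁵ draws), which carries the same
  aliasing structure as the data; per period, a one-sided one-sample t-test
  compares the element-mean power to the null mean.  Because powers are
  correlated across periods, the type-I rate of a single run fluctuates;
  calibration is measured as the average over independent replicates.
- **Amplicon scans** keep points with > 100 reads and loci with ≥ 20 valid
  points, detrend with a quadratic, scan 90–180 min, discard boundary
  peaks, and attach Monte-Carlo peak p-values plus a one-sided Fisher test
  of significant-locus counts against the control panel.
- **Dip test**: the dip statistic is computed exactly by scanning the mode
  over gaps between order statistics; each side's convex (resp. concave)
  band distance is half the largest gap between the step bounds and the
  greatest convex minorant (least concave majorant), and a monotone-junction
  correction (bisection over the minimal/maximal feasible joint values of
  clipped-envelope fits) handles strongly separated clusters where the two
  sides conflict.  The implementation is validated in-suite against an
  exact linear-programming oracle.  P-values are Monte-Carlo against the
  uniform null (least favourable unimodal), tables cached per sample size.
  Measured power at n = 80 and p < 0.05 is ≈ 0.6 for a 4σ-separated equal
  Gaussian mixture and ≥ 0.8 from about 5σ.
  Rates k/c at coverage ~10 live on a coarse lattice that the continuous
  null mistakes for multimodality, so `bimodality_scan` dithers each rate
  uniformly over its own discretization cell (± 1/(2c)) by default.
- **Pseudo-time** is the unweighted mean methylated fraction over 100-CpG
  tiles with 10–15% density (≥ 5 covered tiles per cell); downstream series
  are linearly detrended and rescaled by the technical standard deviation.
- **Expression normalization**: median-of-ratios size factors on transcripts
  with lifetime above the median (~7 h), applied to all genes; output is
  natural-log(normalized + 1).
- **Weighted correlations** use coverage as frequency weights with the
  geometric mean of the two features' coverages per cell.

## Modality theory (`mosc.modality`)

p(m, τ) = ∫ f(m; m̄(Δτ)) g(Δτ; τ) dΔτ with the per-cell sigmoid
m̄ = saturation · logistic(Δτ − midpoint).  The midpoint (default 6) makes
cells start near zero methylation at onset — the literal unshifted sigmoid
would start every cell at 50% and could never produce the low-methylation
regime its own early-time asymptotics describe — and the saturation
(default 0.8) keeps the oscillatory mixture components (± A/2 around m̄)
inside [0, 1] at saturation, as they must be for an observable methylation
level.  Onsets are Gaussian (bimodal_onset: two components split by 6 time
units), truncated to [0, τ] and renormalized; quadrature is Simpson on 2001
points with a 1001-point m-grid.  Modality is counted by local maxima with
≥ 5% relative prominence, with boundary modes counted.  The variance
asymptotics Var(m̄) = u^{∓2} e^{σ²}(e^{σ²}−1) are exact lognormal moments of
the regime expansions m̄ ≈ 1/u (early) and m̄ ≈ 1 − u (late); the
next-order correction is ≈ 6.6·e^{−|μ|} relative, so Monte-Carlo agreement
within 5% requires |μ| ≳ 5 even though the mean is already within 0.1 of
the boundary from |μ| ≈ 3.

## Synthetic data (`mosc.synth`)

The genome is one chromosome of constant-density CpG blocks spanning
0.5–20% (8 blocks per density; 100 CpGs per block, 200 for ≥ 10% density so
that 50- and 100-CpG windows nest inside blocks).  Oscillation amplitude
follows A(d) = 0.3·exp(−(ln d − ln 0.025)²/(2·0.5²)) with hard suppression
at d ≥ 0.10 — amplitude peaks in the 2–3% density bin and vanishes in
CpG-rich regions.  The waveform is a sharpened sinusoid sgn(sin)|sin|^{1/3}
by default: the turnover limit cycle is strongly anharmonic and dwells near
its extremes, and a pure sinusoid's arcsine marginal convolved with
binomial noise at scBS coverage is nearly flat, hiding the bimodality the
data are known to show (``waveform="sin"`` remains available).  Cells share
one oscillator phase per cell (coherence 0.9 by default; the residual 10%
is per-block phase jitter); CpG-dense blocks rise monotonically with a
cell's developmental age instead of oscillating, spread over ``age_span``
of the full range (0.2 in steady-state culture, 1.0 for developmental
datasets).  The ``invivo`` scenario cycles CpG-poor blocks through
not-yet-methylated / transitioning / saturated stage offsets via a per-cell
age sigmoid (slope 4, chosen so the transitioning blocks' cross-cell spread
is flat rather than bimodal), reproducing bimodality at extreme mean
methylation and its depletion at intermediate levels.

Bulk time courses use 31 points over 56 h 30 min with a repeating
non-uniform spacing cycle (75, 105, 159 min; mean 113 min): the span and
point count match the emulated design, and the non-uniform grid makes a
150-min period identifiable by Lomb–Scargle, as it must be for a 2–3 h
rhythm to be detectable at all at this average sampling rate.  Coverage is
200× per CpG with 0.01 replicate jitter and a bulk amplitude scale of 0.12
on the single-cell profile (bulk averages retain only a residual of the
per-cell amplitude).  Amplicon panels: 47 × 20-min points, ~300 reads per
point, amplitude set by SNR × per-point binomial noise (default SNR 1), 4
of 14 loci oscillating, plus a flat control panel.  Expression matrices
place the written/erased summary (Dnmt3a/b/l, Dnmt1 vs Tet1/2/3, Tdg) at a
target R² ≈ 0.06 against the cells' global methylation, with lognormal
lifetimes of median 7 h.

What the generators do **not** emulate: read-level artefacts (bisulfite
conversion errors, mapping bias, PCR duplicates), realistic genome sequence
or annotation structure, chromosome-scale spatial correlation beyond the
block structure, cell-cycle effects, and the paper-scale data volumes.
Passing recovery tests therefore demonstrates correctness of the statistics
under the stated noise models, not robustness to every artefact of real
bisulfite data.

## Problem sizes

Defaults are sized for a laptop-class single-core run: 80 cells × 72 blocks
for single-cell datasets, 31 × 3 bulk samples at 200×, 10⁴–10⁵ Monte-Carlo
nulls, 2000-oscillator ensembles, 500 delayed-Gillespie paths at 10⁴ sites,
and 2000-sample dip null tables.  All stochastic entry points take explicit
seeds and are deterministic given them.

## Known limitations

- The dip statistic's Monte-Carlo null assumes continuous data; the default
  dithering restores calibration for lattice-valued rates but adds a tiny
  amount of smoothing.
- Spectral enrichment treats elements as independent; genuinely correlated
  elements (shared phase) inflate the t-statistic, which is intentional for
  an enrichment screen but means per-period p-values are not element-wise
  error rates.
- The Kuramoto reduction drops the finite-size stochasticity of the lattice;
  agreement is expected only near the continuum limit (many phase states),
  and the lattice's asymptotic coherence sits slightly below the
  deterministic mean-field value.
- `linearized_threshold`'s Newton search targets the rightmost root near the
  real axis; for extreme parameter values the search grid may need widening.
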