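"""Delayed Gillespie simulator and the scBS-seq read-noise model."""

import numpy as np
import pytest
from scipy import stats

from mosc.turnover import (ReadNoiseModel, TurnoverParams, ensemble_rates,
                           rate_distribution, sample_reads,
                           simulate_delayed_turnover, truncated_coverage_mean)


def test_zero_rates_give_constant_path():
    p = TurnoverParams(alpha=0.0, beta=0.0, delta_t=2.0, C0=30, M0=20, t_end=50, seed=1)
    path = simulate_delayed_turnover(p)
    assert np.all(path.C == 30) and np.all(path.M == 20)


def test_no_demethylation_absorbs_fully_methylated():
    p = TurnoverParams(alpha=0.05, beta=0.0, delta_t=2.0, C0=30, M0=5, t_end=500, seed=2)
    path = simulate_delayed_turnover(p)
    assert path.C[-1] == 0 and path.M[-1] == 35
    assert path.rate()[-1] == 1.0


def test_conservation_exact_on_every_event():
    p = TurnoverParams(alpha=0.02, beta=1.0, delta_t=3.0, C0=40, M0=10, t_end=40, seed=3)
    path = simulate_delayed_turnover(p)
    assert path.times.size > 50  # events actually happened
    assert np.all(path.C + path.M + path.in_transit == 50)
    assert np.all(path.C >= 0) and np.all(path.M >= 0) and np.all(path.in_transit >= 0)


def _direct_gillespie_m(alpha, beta, C0, M0, t_end, rng):
    """Independent two-reaction direct-method oracle (no delay): returns M(t_end)."""
    C, M = C0, M0
    t = 0.0
    while True:
        a1 = alpha * C * M
        a2 = beta * M
        a0 = a1 + a2
        if a0 <= 0:
            return M
        t += rng.exponential(1 / a0)
        if t > t_end:
            return M
        if rng.random() * a0 < a1:
            C, M = C - 1, M + 1
        else:
            M -= 1  # product C reappears immediately when delay is zero
            C += 1


def test_zero_delay_matches_standard_gillespie():
    """With delta_t = 0 the delayed simulator is distributionally identical
    to an independently coded two-reaction direct-method simulation
    (two-sample KS on M(t_end), p > 0.01)."""
    alpha, beta, C0, M0, t_end = 0.02, 0.5, 40, 10, 8.0
    n = 400
    p = TurnoverParams(alpha=alpha, beta=beta, delta_t=0.0, C0=C0, M0=M0,
                       t_end=t_end + 0.5, seed=11)
    rates = ensemble_rates(p, [t_end], n)
    m_delayed = rates[:, 0] * (C0 + M0)
    rng = np.random.default_rng(99)
    m_direct = np.array([_direct_gillespie_m(alpha, beta, C0, M0, t_end, rng)
                         for _ in range(n)])
    ks = stats.ks_2samp(m_delayed, m_direct)
    assert ks.pvalue > 0.01


def test_sample_reads_zero_rate_and_forced_coverage(rng):
    out = sample_reads(0.0, ReadNoiseModel(seed=5))
    assert out["k"] == 0
    # forced coverage 10 at rate 0.5: binomial mean/variance
    draws = rng.binomial(10, 0.5, size=20000) / 10
    assert np.mean(draws) == pytest.approx(0.5, abs=0.01)
    assert np.var(draws) == pytest.approx(0.025, rel=0.05)
    with pytest.raises(ValueError):
        sample_reads(1.5, ReadNoiseModel())


def test_coverage_mean_matches_truncated_exponential():
    noise = ReadNoiseModel(coverage_mean=14.3, min_coverage=5, seed=7)
    rng = np.random.default_rng(7)
    s = noise.sample_coverage(rng, size=100_000)
    expected = truncated_coverage_mean(noise)
    assert expected > 14.3  # truncation raises the mean
    assert s.min() >= 5
    assert np.mean(s) == pytest.approx(expected, rel=0.01)


def test_rate_distribution_reproducible_and_seed_stable():
    p = TurnoverParams(alpha=0.004, beta=1.0, delta_t=6.0, C0=850, M0=100,
                       t_end=18.0, seed=1)
    noise = ReadNoiseModel(seed=1)
    tps = [6.0, 12.0, 18.0]
    h1 = rate_distribution(p, noise, 4800, tps, seed=21)
    h2 = rate_distribution(p, noise, 4800, tps, seed=22)
    h1b = rate_distribution(p, noise, 4800, tps, seed=21)
    assert np.array_equal(h1["hist"], h1b["hist"])  # determinism
    tv = 0.5 * np.abs(h1["hist"] - h2["hist"]).sum(axis=1)
    assert np.all(tv < 0.05)  # sampling-error bound between seeds


def test_rate_distribution_sweeps_between_modes():
    """Fig 2D regime: the observed-rate distribution moves between low- and
    high-methylation modes across timepoints."""
    p = TurnoverParams(alpha=0.004, beta=1.0, delta_t=6.0, C0=850, M0=100,
                       t_end=30.0, seed=1)
    res = rate_distribution(p, ReadNoiseModel(seed=1), 2000,
                            np.linspace(3, 30, 10), seed=5)
    means = np.nansum(res["hist"] * (res["bin_edges"][:-1] + 0.025), axis=1)
    assert means.max() - means.min() > 0.3  # large sweeps of the mean rate
    with np.errstate(invalid="ignore"):
        p_low = res["hist"][:, :6].sum(axis=1)
        p_high = res["hist"][:, -6:].sum(axis=1)
    assert p_low.max() > 0.5 and p_high.max() > 0.5  # both modes visited


def test_timepoint_validation():
    p = TurnoverParams(t_end=10.0)
    with pytest.raises(ValueError):
        ensemble_rates(p, [20.0], 10)
    with pytest.raises(ValueError):
        TurnoverParams(alpha=-1.0)


def test_observed_variance_at_least_binomial():
    """Across-simulation variance of observed rates k/s is at least the
    technical binomial variance at every timepoint."""
    p = TurnoverParams(alpha=0.004, beta=1.0, delta_t=6.0, C0=850, M0=100,
                       t_end=20.0, seed=9)
    noise = ReadNoiseModel(seed=9)
    res = rate_distribution(p, noise, 2000, [5.0, 10.0, 15.0, 20.0], seed=9)
    obs = res["observed"]
    rates = ensemble_rates(p, [5.0, 10.0, 15.0, 20.0], 2000, seed=9)
    cbar = truncated_coverage_mean(noise)
    for j in range(4):
        m = np.nanmean(rates[:, j])
        tech = m * (1 - m) / cbar
        assert np.nanvar(obs[:, j]) >= 0.8 * tech  # never collapses below binomial
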