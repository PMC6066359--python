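"""Coupled CpG-site oscillators: lattice, coarse-graining, Kuramoto theory."""

import numpy as np
import pytest
from scipy import stats

from mosc.sync import (LatticeModel, OscillatorEnsemble, coarse_grain,
                       critical_scaling, gaussian_ensemble, lorentzian_ensemble,
                       simulate_kuramoto, simulate_lattice,
                       synchronization_threshold)


def test_single_site_phase_increments_are_poisson():
    """An uncoupled site advances its phase as a Poisson process with mean
    and variance omega * t * n / (2 pi)."""
    omega, t_end, n_states = 2.0, 50.0, 12
    m = LatticeModel(positions=[0.0], n_states=n_states, omega=omega, lam=0.0,
                     xi=1.0, kappa=0.0, sigma=1.0)
    counts = np.array([
        simulate_lattice(m, t_end, record_every=t_end,
                         rng=np.random.default_rng(s))["steps"][-1][0]
        for s in range(300)
    ])
    expect = omega * t_end * n_states / (2 * np.pi)
    se = np.sqrt(expect / 300)
    assert abs(counts.mean() - expect) < 4 * se
    # index of dispersion ~ 1 for Poisson
    assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.25)


def test_uncoupled_sites_stay_incoherent():
    n = 200
    m = LatticeModel(positions=np.arange(n) * 10.0, n_states=20, omega=1.0,
                     lam=0.0, xi=5.0, kappa=0.0, sigma=1.0, seed=3)
    res = simulate_lattice(m, t_end=30, record_every=1.0)
    # r stays at the finite-size noise floor ~ n^{-1/2}, no growth
    assert res["summary"].r_asymptotic < 4 / np.sqrt(n)
    assert np.all(res["summary"].r <= 1.0) and np.all(res["summary"].r >= 0.0)


def test_strong_global_coupling_synchronizes_lattice():
    n = 200
    m = LatticeModel(positions=np.arange(n) * 10.0, n_states=40, omega=1.0,
                     lam=0.0, xi=5.0, kappa=20.0, sigma=1.0, seed=2)
    res = simulate_lattice(m, t_end=25, record_every=1.0)
    assert res["summary"].r_asymptotic > 0.8


def test_coarse_grain_bookkeeping():
    """Merging identical unit blocks keeps omega; kappa*n and sigma/n are
    invariant; the weighted frequency sum is conserved exactly."""
    n = 24
    rng = np.random.default_rng(5)
    m = LatticeModel(positions=np.cumsum(rng.integers(3, 30, n)).astype(float),
                     n_states=12, omega=rng.normal(1.0, 0.2, n), lam=100.0,
                     xi=20.0, kappa=rng.uniform(0.5, 2.0, n),
                     sigma=rng.uniform(0.5, 2.0, n))
    total_omega = float(np.sum(m.omega))
    site_kappa_mean = None
    ens = coarse_grain(m)
    assert ens.omega.size < n  # merges actually happened
    assert np.sum(ens.weights) == pytest.approx(n)
    assert np.sum(ens.weights * ens.omega) == pytest.approx(total_omega, rel=1e-12)
    # kappa_block * n_block recovers the mean site response of the block;
    # sigma_block / n_block the mean site contribution: both bounded by the
    # site-level ranges
    k_site = ens.kappa * ens.weights
    s_site = ens.sigma / ens.weights
    assert np.all(k_site >= 0.5 - 1e-9) and np.all(k_site <= 2.0 + 1e-9)
    assert np.all(s_site >= 0.5 - 1e-9) and np.all(s_site <= 2.0 + 1e-9)


def test_coarse_grain_merge_of_identical_blocks_keeps_frequency():
    m = LatticeModel(positions=[0.0, 5.0], n_states=12, omega=1.3, lam=10.0,
                     xi=10.0, kappa=1.0, sigma=1.0)
    ens = coarse_grain(m)
    assert ens.omega.size == 2 or np.allclose(ens.omega, 1.3)


def test_kuramoto_identical_phases_stay_locked():
    ens = OscillatorEnsemble(omega=np.full(50, 1.0), kappa=2.0, sigma=2.0,
                             weights=1.0, phases=np.zeros(50))
    s = simulate_kuramoto(ens, t_end=20, dt=0.02)
    assert np.allclose(s.r, 1.0, atol=1e-9)


def test_kuramoto_relaxation_time_scales_inversely_with_coupling():
    """Identical frequencies, random phases: r -> 1, faster for larger
    coupling (timescale ~ 1/kappa)."""
    rng = np.random.default_rng(9)
    phases = rng.uniform(0, 2 * np.pi, 400)

    def time_to(level, k):
        ens = OscillatorEnsemble(omega=np.zeros(400), kappa=k, sigma=k,
                                 weights=1.0, phases=phases.copy())
        s = simulate_kuramoto(ens, t_end=80, dt=0.02, record_every=0.02)
        hit = np.flatnonzero(s.r >= level)
        assert hit.size, f"r never reached {level} at coupling {k}"
        return s.times[hit[0]]

    t1 = time_to(0.9, 0.5)
    t2 = time_to(0.9, 1.0)
    assert s_ratio_in(t1 / t2, 1.4, 3.0)


def s_ratio_in(x, lo, hi):
    return lo <= x <= hi


def test_kuramoto_matches_lorentzian_closed_form():
    gamma = 1.0
    K = 1.5 * (2 * gamma)
    ens = lorentzian_ensemble(2000, K, gamma=gamma)
    dt = 0.09 / np.max(np.abs(ens.omega))
    s = simulate_kuramoto(ens, t_end=80, dt=dt, rng=np.random.default_rng(5))
    assert s.r_asymptotic == pytest.approx(np.sqrt(1 - 2 * gamma / K), abs=0.05)


def test_threshold_formula_plug_ins():
    g_normal = stats.norm.pdf(0.0)
    res = synchronization_threshold(g_normal)
    assert res["kappa_c"] == pytest.approx(2 / (np.pi * g_normal), rel=1e-12)
    assert res["kappa_c"] == pytest.approx(1.596, abs=0.01)
    gamma = 0.7
    res = synchronization_threshold(stats.cauchy.pdf(0, scale=gamma))
    assert res["kappa_c"] == pytest.approx(2 * gamma, rel=1e-12)
    # identical frequencies: synchronized state survives vanishing coupling
    res = synchronization_threshold(np.inf, kappa_mean=1e-6)
    assert res["kappa_c"] == 0.0 and res["condition_met"]
    with pytest.raises(ValueError):
        synchronization_threshold(0.0)


def test_heterogeneous_condition_uses_second_moment():
    g0 = stats.norm.pdf(0.0)
    thresh = 2 / (np.pi * g0)
    # mean below threshold but variance pushes the second moment over it
    mean = 0.8 * np.sqrt(thresh)
    var = thresh - mean**2 + 0.1
    assert synchronization_threshold(g0, kappa_mean=mean, kappa_var=var)["condition_met"]
    assert not synchronization_threshold(g0, kappa_mean=mean, kappa_var=0.0)["condition_met"]


def test_near_critical_scaling_exponent_quick():
    """Log-log slope of r vs distance above threshold is near 1/2 (light
    version; the full calibration runs in the acceptance suite)."""
    g0 = stats.norm.pdf(0.0)
    kc = 2 / (np.pi * g0)

    def factory(mu, seed):
        return gaussian_ensemble(800, kc * (1 + mu))

    out = critical_scaling(factory, [0.03, 0.07, 0.15], n_seeds=2, t_end=80, dt=0.03)
    assert 0.3 < out["exponent"] < 0.7
    with pytest.raises(ValueError):
        critical_scaling(factory, [0.5])


def test_lattice_and_coarse_grained_kuramoto_agree():
    """Above threshold, the asymptotic order parameter of the coarse-grained
    mean-field ensemble matches the full 500-site lattice within 0.1."""
    rng = np.random.default_rng(7)
    n = 500
    m = LatticeModel(positions=np.cumsum(rng.integers(5, 15, n)).astype(float),
                     n_states=60, omega=rng.normal(1.0, 0.05, n), lam=30.0,
                     xi=10.0, kappa=16.0, sigma=1.0, seed=7)
    lat = simulate_lattice(m, t_end=15, record_every=1.0)
    ens = coarse_grain(m)
    mf = simulate_kuramoto(ens, t_end=60, dt=0.02, rng=np.random.default_rng(8))
    assert abs(lat["summary"].r_asymptotic - mf.r_asymptotic) < 0.1


def test_order_parameter_rotation_invariance():
    rng = np.random.default_rng(11)
    phases = rng.uniform(0, 2 * np.pi, 100)
    sigma = rng.uniform(0.5, 2.0, 100)
    ens1 = OscillatorEnsemble(omega=np.zeros(100), kappa=0.0, sigma=sigma,
                              weights=1.0, phases=phases)
    ens2 = OscillatorEnsemble(omega=np.zeros(100), kappa=0.0, sigma=sigma,
                              weights=1.0, phases=phases + 1.234)
    s1 = simulate_kuramoto(ens1, t_end=1, dt=0.05)
    s2 = simulate_kuramoto(ens2, t_end=1, dt=0.05)
    assert s1.r[0] == pytest.approx(s2.r[0], abs=1e-12)
    assert np.all((s1.r >= 0) & (s1.r <= 1))


def test_model_validation():
    with pytest.raises(ValueError):
        LatticeModel(positions=[0.0, 0.0], n_states=10, omega=1.0, lam=0.0,
                     xi=1.0, kappa=0.0, sigma=1.0)
    with pytest.raises(ValueError):
        LatticeModel(positions=[0.0], n_states=2, omega=1.0, lam=0.0,
                     xi=1.0, kappa=0.0, sigma=1.0)
    with pytest.raises(ValueError):
        OscillatorEnsemble(omega=np.empty(0))
    ens = OscillatorEnsemble(omega=np.array([5.0]))
    with pytest.raises(ValueError):
        simulate_kuramoto(ens, t_end=1.0, dt=0.1)  # dt*omega too coarse
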