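"""Delayed turnover model: fixed points, limit cycles, Hopf threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosc.dde import (DelayModelParams, HillParams, Trajectory, hopf_delay,
                      hopf_threshold_scan, integrate_dde, linearized_threshold,
                      oscillation_summary)


@pytest.mark.parametrize("u0,v0", [(1.0, 0.7), (2.0, 0.0)])
def test_stationary_solutions_are_held_fixed(u0, v0):
    """Constant states on the u=1 branch and the unmethylated branch (v=0)
    stay exactly constant under integration."""
    traj = integrate_dde(DelayModelParams(delta_tau=3.0, u0=u0, v0=v0, t_max=100.0))
    assert np.allclose(traj.u, u0, atol=1e-12)
    assert np.allclose(traj.v, v0, atol=1e-12)


def test_limit_cycle_amplitude_independent_of_integration_time():
    """Above threshold the orbit converges to a limit cycle: the last-10-cycle
    amplitude is unchanged (1%) when the integration time doubles."""
    p1 = DelayModelParams(delta_tau=8.0, u0=1.6, v0=0.4, t_max=500.0)
    p2 = DelayModelParams(delta_tau=8.0, u0=1.6, v0=0.4, t_max=1000.0)
    s1 = oscillation_summary(integrate_dde(p1))
    s2 = oscillation_summary(integrate_dde(p2))
    assert s1.oscillating and s2.oscillating
    assert s1.amplitude_v == pytest.approx(s2.amplitude_v, rel=0.01)
    assert s1.period == pytest.approx(s2.period, rel=0.01)


def test_oscillation_summary_on_closed_form_sinusoid():
    t = np.arange(0, 200, 0.01)
    v = 1 + 0.3 * np.sin(2 * np.pi * t / 5.0)
    traj = Trajectory(times=t, u=v.copy(), v=v, delta_tau=0.0)
    s = oscillation_summary(traj)
    assert s.oscillating
    assert s.period == pytest.approx(5.0, rel=0.01)
    assert s.amplitude_v == pytest.approx(0.6, rel=0.01)


def test_constant_trajectory_reports_not_oscillating():
    t = np.arange(0, 100, 0.01)
    traj = Trajectory(times=t, u=np.ones_like(t), v=np.full_like(t, 0.5), delta_tau=0.0)
    s = oscillation_summary(traj)
    assert not s.oscillating
    assert s.amplitude_v == pytest.approx(0.0, abs=1e-12)


def test_oscillation_summary_rejects_nan():
    t = np.arange(0, 10, 0.01)
    v = np.full_like(t, np.nan)
    with pytest.raises(ValueError):
        oscillation_summary(Trajectory(times=t, u=v, v=v, delta_tau=0.0))


def test_period_grows_linearly_with_delay():
    """Linear regression of period on delay over the super-critical range has
    R^2 > 0.95."""
    delays = np.arange(6.0, 12.1, 1.0)
    periods = []
    for d in delays:
        s = oscillation_summary(integrate_dde(
            DelayModelParams(delta_tau=d, u0=1.6, v0=0.4, t_max=600.0)))
        assert s.oscillating
        periods.append(s.period)
    periods = np.asarray(periods)
    slope, icept = np.polyfit(delays, periods, 1)
    resid = periods - (icept + slope * delays)
    r2 = 1 - resid.var() / periods.var()
    assert r2 > 0.95
    assert slope > 0


def test_delayed_conservation_invariant():
    """u + v + trailing integral of v is conserved to integrator tolerance."""
    p = DelayModelParams(delta_tau=8.0, u0=1.6, v0=0.4, t_max=300.0)
    traj = integrate_dde(p)
    c = traj.conserved()
    dt = traj.times[1] - traj.times[0]
    drift = np.abs(c - (p.u0 + p.v0 + p.delta_tau * p.v0)).max()
    assert drift < 10 * dt**2 * p.t_max
    assert c[0] == pytest.approx(p.u0 + p.v0 + p.delta_tau * p.v0, rel=1e-6)


def test_parameter_validation():
    with pytest.raises(ValueError):
        DelayModelParams(delta_tau=-1.0)
    with pytest.raises(ValueError):
        DelayModelParams(delta_tau=2.0, u0=-0.5)
    with pytest.raises(ValueError):
        DelayModelParams(delta_tau=5.0, dt=1.0)  # coarser than delta_tau/10
    with pytest.raises(ValueError):
        integrate_dde(DelayModelParams(delta_tau=3.0, t_max=100.0), variant="hill")


def test_epsilon_raises_oscillation_threshold():
    """Non-autocatalytic de novo methylation stabilizes the fixed point:
    the onset delay increases with epsilon."""
    grid = np.arange(4.0, 8.01, 0.5)
    base = hopf_threshold_scan(
        DelayModelParams(delta_tau=0.0, u0=1.6, v0=0.4, t_max=600.0), grid)
    eps = hopf_threshold_scan(
        DelayModelParams(delta_tau=0.0, u0=1.6, v0=0.4, epsilon=0.2, t_max=600.0),
        grid, variant="linear_denovo")
    assert base["threshold"] is not None
    assert eps["threshold"] is None or eps["threshold"] > base["threshold"]


def test_subcritical_grid_reports_absent_threshold():
    grid = np.arange(0.0, 1.01, 0.25)
    res = hopf_threshold_scan(
        DelayModelParams(delta_tau=0.0, u0=1.6, v0=0.4, t_max=200.0), grid)
    assert res["threshold"] is None
    assert np.all(res["amplitudes"] < 1e-3)


def test_linearized_threshold_classifications():
    assert linearized_threshold(0.4, 0.0)["stable"]
    assert not linearized_threshold(0.4, 20.0)["stable"]
    with pytest.raises(ValueError):
        linearized_threshold(-0.1, 5.0)


def test_characteristic_oracle_matches_simulation_threshold():
    """The rightmost characteristic root of the linearization about
    (u=1, v_bar) flips sign at the closed-form crossing delay, and the
    self-consistent crossing for the standard history (1.6, 0.4) agrees with
    the nonlinear scan onset within one grid step."""
    dstar = hopf_delay(0.4)
    assert dstar == pytest.approx(5.086, abs=0.01)
    assert linearized_threshold(0.4, dstar - 0.2)["stable"]
    assert not linearized_threshold(0.4, dstar + 0.2)["stable"]

    # conservation ties the asymptotic level to the delay:
    # 1 + v_bar (1 + d) = u0 + v0 (1 + d)  =>  v_bar(d) = v0 + (u0-1)/(1+d)
    u0, v0 = 1.6, 0.4

    def gap(d):
        return hopf_delay(v0 + (u0 - 1) / (1 + d)) - d

    lo, hi = 3.0, 7.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    d_self = 0.5 * (lo + hi)

    grid = np.arange(4.0, 6.51, 0.25)
    amps = []
    for d in grid:
        s = oscillation_summary(integrate_dde(
            DelayModelParams(delta_tau=float(d), u0=u0, v0=v0, t_max=1000.0)))
        amps.append(s.amplitude_v if s.oscillating else 0.0)
    onset = grid[np.argmax(np.asarray(amps) > 1e-3)]
    assert abs(onset - d_self) <= 0.25 + 1e-9


def test_hill_variant_bounded_and_distinct_from_baseline():
    p = DelayModelParams(delta_tau=6.0, u0=1.6, v0=0.4, t_max=200.0,
                         hill=HillParams(A=1.0, B=1.0, m=1, n=1))
    hill = integrate_dde(p, variant="hill")
    base = integrate_dde(DelayModelParams(delta_tau=6.0, u0=1.6, v0=0.4, t_max=200.0))
    assert np.all(hill.u >= 0) and np.all(hill.v >= 0)
    assert np.all(np.isfinite(hill.u)) and hill.v.max() < 50
    assert not np.allclose(hill.v[-1000:], base.v[-1000:], atol=1e-3)


def test_time_dependent_rates_variant_runs_nonnegative():
    p = DelayModelParams(delta_tau=6.0, u0=1.6, v0=0.4, t_max=200.0)
    traj = integrate_dde(p, variant="time_dependent_rates")
    assert np.all(traj.u >= 0) and np.all(traj.v >= 0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    u0=st.floats(0.5, 2.5),
    v0=st.floats(0.1, 1.5),
    dtau=st.floats(0.5, 6.0),
)
def test_nonnegativity_and_conservation_property(u0, v0, dtau):
    p = DelayModelParams(delta_tau=dtau, u0=u0, v0=v0, t_max=80.0)
    traj = integrate_dde(p)
    assert np.all(traj.u >= 0) and np.all(traj.v >= 0)
    c = traj.conserved()
    assert np.abs(c - c[0]).max() < 1e-3 * max(1.0, c[0])
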