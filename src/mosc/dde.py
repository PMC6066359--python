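"""Time-delayed DNA methylation turnover model.

Dimensionless delay system for the genome-averaged concentrations of
unmodified (u) and methylated (v) cytosines,

    u'(tau) = v(tau - dtau) - u(tau) v(tau)
    v'(tau) = u(tau) v(tau) - v(tau)

where the single parameter ``dtau`` (the dimensionless delay, conversion rate
times the demethylation delay) controls a Hopf bifurcation to sustained
oscillations.  Structural variants add non-autocatalytic de novo methylation
(``epsilon``), Hill-type nonlinear conversion, or time-dependent multiplicative
rate schedules.

Integration uses the method of steps with fixed-step classical Runge-Kutta
and linear interpolation of the stored delayed state at half-steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._jit import njit

__all__ = [
    "HillParams",
    "DelayModelParams",
    "Trajectory",
    "OscillationSummary",
    "integrate_dde",
    "oscillation_summary",
    "hopf_threshold_scan",
    "linearized_threshold",
    "hopf_delay",
]

VARIANTS = ("baseline", "linear_denovo", "hill", "time_dependent_rates")

_BASELINE, _LINEAR, _HILL, _SCHEDULED = 0, 1, 2, 3


@dataclass(frozen=True)
class HillParams:
    """Thresholds (A, B) and integer exponents (m, n) of the Hill variant."""

    A: float = 1.0
    B: float = 1.0
    m: int = 2
    n: int = 2

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("Hill thresholds A, B must be positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("Hill exponents m, n must be >= 1")


@dataclass(frozen=True)
class DelayModelParams:
    """Parameters of the dimensionless delayed turnover model.

    ``delta_tau`` is the dimensionless delay; ``epsilon`` the relative
    strength of non-autocatalytic de novo methylation; ``(u0, v0)`` the
    constant pre-history on [-delta_tau, 0].
    """

    delta_tau: float
    u0: float = 1.6
    v0: float = 0.4
    epsilon: float = 0.0
    hill: Optional[HillParams] = None
    t_max: float = 1000.0
    dt: Optional[float] = None
    #: constant value of v on [-delta_tau, 0); defaults to v0.  Zero models a
    #: system with no demethylation intermediates in transit at tau = 0.
    history_v: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta_tau < 0:
            raise ValueError("delta_tau must be >= 0")
        if self.u0 < 0 or self.v0 < 0:
            raise ValueError("history (u0, v0) must be non-negative")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.t_max < 10 * self.delta_tau:
            raise ValueError("t_max must be at least 10 * delta_tau")
        if self.history_v is not None and self.history_v < 0:
            raise ValueError("history_v must be non-negative")
        if self.dt is not None:
            if self.dt <= 0:
                raise ValueError("dt must be positive")
            if self.delta_tau > 0 and self.dt > self.delta_tau / 10:
                raise ValueError("dt too coarse: require dt <= delta_tau / 10")

    def resolve_step(self) -> tuple[float, int]:
        """Return (dt, lag_steps) with the delay an exact multiple of dt."""
        dt = self.dt
        if dt is None:
            dt = min(self.delta_tau / 200, 0.005) if self.delta_tau > 0 else 0.005
        if self.delta_tau == 0:
            return dt, 0
        lag = max(10, int(round(self.delta_tau / dt)))
        return self.delta_tau / lag, lag


@dataclass
class Trajectory:
    """Integrated (u, v) series on an evenly spaced time grid."""

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    delta_tau: float
    u0: float = np.nan
    v0: float = np.nan
    history_v: float = np.nan

    def conserved(self) -> np.ndarray:
        """u + v + trailing-window integral of v (trapezoidal).

        Constant over time for the baseline variant; the initial value is
        u0 + v0 + delta_tau * v0 for a constant history.
        """
        dt = self.times[1] - self.times[0]
        lag = int(round(self.delta_tau / dt))
        vh = self.v0 if np.isnan(self.history_v) else self.history_v
        v_ext = np.concatenate([np.full(lag, vh), self.v])
        csum = np.concatenate([[0.0], np.cumsum(0.5 * (v_ext[1:] + v_ext[:-1]) * dt)])
        integral = csum[lag:] - csum[:-lag] if lag else np.zeros_like(self.v)
        return self.u + self.v + integral


@dataclass
class OscillationSummary:
    oscillating: bool
    period: float = np.nan
    amplitude_u: float = np.nan
    amplitude_v: float = np.nan
    n_cycles_used: int = 0


@njit(cache=False)
def _integrate_core(u0, v0, vh, dt, n_steps, lag, variant, eps, hA, hB, hm, hn, sm, sd):
    """RK4 method-of-steps core.  sm/sd are rate schedules on the extended
    grid (index 0 corresponds to tau = -lag*dt)."""
    u = np.empty(n_steps + 1)
    v = np.empty(n_steps + 1)
    u[0] = u0
    v[0] = v0

    for i in range(n_steps):
        # delayed v at the three stage times (constant pre-history = v0)
        if lag > 0:
            j = i - lag
            vd1 = v[j] if j >= 0 else vh
            jn = j + 1
            vdn = v[jn] if jn >= 0 else vh
            vd2 = 0.5 * (vd1 + vdn)
            vd4 = vdn
        else:
            vd1 = v[i]
            vd2 = 0.0  # replaced per-stage below
            vd4 = 0.0

        if variant == _SCHEDULED:
            s_m1 = sm[i + lag]
            s_m4 = sm[i + lag + 1]
            s_m2 = 0.5 * (s_m1 + s_m4)
            s_d1 = sd[i + lag]
            s_d4 = sd[i + lag + 1]
            s_d2 = 0.5 * (s_d1 + s_d4)
            # schedule at the delayed times
            s_dd1 = sd[i]
            s_dd4 = sd[i + 1]
            s_dd2 = 0.5 * (s_dd1 + s_dd4)
        else:
            s_m1 = s_m2 = s_m4 = 1.0
            s_d1 = s_d2 = s_d4 = 1.0
            s_dd1 = s_dd2 = s_dd4 = 1.0

        ui = u[i]
        vi = v[i]
        du = dv = 0.0
        k1u = k1v = k2u = k2v = k3u = k3v = k4u = k4v = 0.0

        for stage in range(4):
            if stage == 0:
                us, vs, vds = ui, vi, vd1
                s_ms, s_ds, s_dds = s_m1, s_d1, s_dd1
            elif stage == 1:
                us, vs = ui + 0.5 * dt * du, vi + 0.5 * dt * dv
                vds = vd2 if lag > 0 else vs
                s_ms, s_ds, s_dds = s_m2, s_d2, s_dd2
            elif stage == 2:
                us, vs = ui + 0.5 * dt * du, vi + 0.5 * dt * dv
                vds = vd2 if lag > 0 else vs
                s_ms, s_ds, s_dds = s_m2, s_d2, s_dd2
            else:
                us, vs = ui + dt * du, vi + dt * dv
                vds = vd4 if lag > 0 else vs
                s_ms, s_ds, s_dds = s_m4, s_d4, s_dd4

            if variant == _HILL:
                uv = us * vs
                meth = uv**hm / (hB**hm + uv**hm)
                prod = vds**hn / (hA**hn + vds**hn)
                loss = vs**hn / (hA**hn + vs**hn)
                du = prod - meth
                dv = meth - loss
            else:
                meth = s_ms * us * (vs + eps)
                du = s_dds * vds - meth
                dv = meth - s_ds * vs

            if stage == 0:
                k1u, k1v = du, dv
            elif stage == 1:
                k2u, k2v = du, dv
            elif stage == 2:
                k3u, k3v = du, dv
            else:
                k4u, k4v = du, dv

        un = ui + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
        vn = vi + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        # exact dynamics preserve non-negativity; clamp integrator round-off
        if un < 0 and un > -1e-9:
            un = 0.0
        if vn < 0 and vn > -1e-9:
            vn = 0.0
        u[i + 1] = un
        v[i + 1] = vn

    return u, v


def integrate_dde(
    params: DelayModelParams,
    variant: str = "baseline",
    rate_schedules: Optional[tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]] = None,
) -> Trajectory:
    """Integrate the delayed turnover model on [0, t_max].

    Parameters
    ----------
    params
        Model parameters; the history is the constant (u0, v0) on
        [-delta_tau, 0].
    variant
        One of ``baseline``, ``linear_denovo`` (uses ``params.epsilon``),
        ``hill`` (requires ``params.hill``) or ``time_dependent_rates``
        (multiplicative schedules on the methylation and demethylation
        terms; default schedule is a logistic ramp).
    rate_schedules
        Optional pair of vectorized callables ``(s_meth(tau), s_demeth(tau))``
        for the ``time_dependent_rates`` variant.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "hill" and params.hill is None:
        raise ValueError("variant='hill' requires params.hill")

    dt, lag = params.resolve_step()
    n_steps = int(round(params.t_max / dt))
    code = VARIANTS.index(variant)
    eps = params.epsilon if variant == "linear_denovo" else 0.0

    if variant == "time_dependent_rates":
        tau_ext = (np.arange(n_steps + lag + 1) - lag) * dt
        if rate_schedules is None:
            ramp = 1.0 / (1.0 + np.exp(-(tau_ext - 0.1 * params.t_max) / (0.05 * params.t_max)))
            sm = 0.5 + ramp
            sd = np.ones_like(tau_ext)
        else:
            sm = np.asarray(rate_schedules[0](tau_ext), dtype=float)
            sd = np.asarray(rate_schedules[1](tau_ext), dtype=float)
        if np.any(sm < 0) or np.any(sd < 0):
            raise ValueError("rate schedules must be non-negative")
    else:
        sm = np.ones(1)
        sd = np.ones(1)

    hill = params.hill or HillParams()
    vh = params.v0 if params.history_v is None else params.history_v
    u, v = _integrate_core(
        params.u0, params.v0, vh, dt, n_steps, lag, code, eps,
        hill.A, hill.B, hill.m, hill.n, sm, sd,
    )
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times=times, u=u, v=v, delta_tau=lag * dt, u0=params.u0,
                      v0=params.v0, history_v=vh)


def _extrema(times: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Times and values of local extrema (sign changes of the discrete
    derivative, i.e. roots of dy/dtau)."""
    dy = np.diff(y)
    sign = np.sign(dy)
    # ignore flat segments
    nz = sign != 0
    idx = np.flatnonzero(nz)
    if idx.size < 2:
        return np.empty(0), np.empty(0)
    s = sign[idx]
    change = np.flatnonzero(s[1:] * s[:-1] < 0)
    ext_i = idx[change] + 1  # grid index of the extremum sample
    return times[ext_i], y[ext_i]


def oscillation_summary(
    traj: Trajectory,
    n_last_cycles: int = 10,
    amp_tol: float = 1e-3,
    sustain_tol: float = 0.05,
) -> OscillationSummary:
    """Period and amplitude of the asymptotic oscillation of a trajectory.

    The period is the mean spacing between next-nearest roots of dv/dtau,
    the amplitudes the mean absolute difference of u resp. v at consecutive
    extrema, both averaged over the last ``n_last_cycles`` cycles.  A
    trajectory whose amplitude is below ``amp_tol``, or whose amplitude
    drifts by more than ``sustain_tol`` between the two preceding
    ``n_last_cycles`` windows (a decaying spiral), reports
    ``oscillating=False``.
    """
    if traj.times.size == 0 or np.any(~np.isfinite(traj.v)):
        raise ValueError("trajectory is empty or contains non-finite values")

    t_ext, v_ext = _extrema(traj.times, traj.v)
    need = 2 * n_last_cycles + 1
    if t_ext.size < 2 * need:
        # not enough cycles for a sustained-oscillation call
        amp = float(np.mean(np.abs(np.diff(v_ext)))) if v_ext.size >= 2 else 0.0
        return OscillationSummary(oscillating=False, amplitude_v=amp, amplitude_u=amp)

    last = np.abs(np.diff(v_ext[-need:]))
    prev = np.abs(np.diff(v_ext[-2 * need + 1:-need + 1]))
    amp_v = float(np.mean(last))
    amp_prev = float(np.mean(prev))

    tu_ext, u_ext = _extrema(traj.times, traj.u)
    amp_u = float(np.mean(np.abs(np.diff(u_ext[-need:])))) if u_ext.size >= need else 0.0

    t_win = t_ext[-need:]
    period = float(np.mean(t_win[2:] - t_win[:-2]))

    sustained = amp_v > amp_tol and abs(amp_v - amp_prev) <= sustain_tol * max(amp_v, 1e-300)
    return OscillationSummary(
        oscillating=bool(sustained),
        period=period,
        amplitude_u=amp_u,
        amplitude_v=amp_v,
        n_cycles_used=n_last_cycles,
    )


def hopf_threshold_scan(
    params: DelayModelParams,
    delta_tau_grid: Sequence[float],
    amp_tol: float = 1e-3,
    variant: str = "baseline",
) -> dict:
    """Scan the delay for the onset of sustained oscillations.

    Returns a dict with the smallest grid delay whose asymptotic amplitude
    exceeds ``amp_tol`` (``None`` if the grid is entirely sub-critical)
    together with the per-grid-point amplitudes and periods.
    """
    grid = np.asarray(delta_tau_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("delta_tau_grid must be non-empty and increasing")
    amplitudes = np.zeros(grid.size)
    periods = np.full(grid.size, np.nan)
    threshold = None
    for k, dtau in enumerate(grid):
        p = DelayModelParams(
            delta_tau=float(dtau), u0=params.u0, v0=params.v0,
            epsilon=params.epsilon, hill=params.hill,
            t_max=params.t_max, dt=params.dt,
        )
        summ = oscillation_summary(integrate_dde(p, variant=variant), amp_tol=amp_tol)
        if summ.oscillating:
            amplitudes[k] = summ.amplitude_v
            periods[k] = summ.period
            if threshold is None:
                threshold = float(dtau)
    return {"threshold": threshold, "grid": grid, "amplitudes": amplitudes, "periods": periods}


def hopf_delay(v_bar: float) -> Optional[float]:
    """Closed-form delay at which the linearization about (u=1, v_bar)
    first acquires a purely imaginary eigenvalue pair.

    From the characteristic equation lam^2 + v_bar lam + v_bar(1 - e^{-lam dtau}) = 0
    with lam = i*omega: omega = sqrt(v_bar (2 - v_bar)) and the crossing delay
    is the smallest positive solution of cos(omega dtau) = v_bar - 1,
    sin(omega dtau) = -omega.  Returns None when no crossing exists.
    """
    s = v_bar * (2.0 - v_bar)
    if s <= 0:
        return None
    omega = math.sqrt(s)
    theta = math.atan2(-omega, v_bar - 1.0) % (2.0 * math.pi)
    return theta / omega


def linearized_threshold(v_bar: float, delta_tau: float) -> dict:
    """Local stability of the balanced fixed point (u=1, v_bar) by numerically
    locating the rightmost nontrivial root of the characteristic equation.

    lam = 0 is always a root (neutral mode of the conserved quantity) and is
    excluded from the classification.  Returns
    ``{"stable": bool, "leading_real": float, "leading_root": complex}``.
    """
    if v_bar <= 0:
        raise ValueError("v_bar must be positive")

    def f(lam: complex) -> complex:
        return lam * lam + v_bar * lam + v_bar * (1.0 - np.exp(-lam * delta_tau))

    def fp(lam: complex) -> complex:
        return 2.0 * lam + v_bar + v_bar * delta_tau * np.exp(-lam * delta_tau)

    im_scale = math.pi / max(delta_tau, 0.5)
    starts = [
        complex(re, im)
        for re in (-1.0, -0.4, -0.1, 0.05, 0.3, 0.8)
        for im in np.arange(0.0, 4.0 * im_scale + 1e-9, 0.5 * im_scale)
    ]
    roots: list[complex] = []
    for z0 in starts:
        z = z0
        ok = False
        for _ in range(80):
            d = fp(z)
            if abs(d) < 1e-14:
                break
            step = f(z) / d
            z = z - step
            if abs(step) < 1e-13:
                ok = True
                break
        if ok and abs(f(z)) < 1e-9:
            if z.imag < 0:
                z = z.conjugate()
            if not any(abs(z - r) < 1e-6 for r in roots):
                roots.append(z)
    nontrivial = [r for r in roots if abs(r) > 1e-7]
    if not nontrivial:
        raise RuntimeError(
            f"characteristic root search did not converge (v_bar={v_bar}, "
            f"delta_tau={delta_tau}, {len(roots)} trivial roots found)"
        )
    lead = max(nontrivial, key=lambda r: r.real)
    return {"stable": lead.real < 0.0, "leading_real": float(lead.real), "leading_root": lead}
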