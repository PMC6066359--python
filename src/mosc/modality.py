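"""Cross-cell methylation distributions during global de novo methylation.

During exit from pluripotency each cell gains methylation along a sigmoid
trajectory m(dt) = 1/(1 + exp(-dt)), where dt is the (dimensionless) time
since that cell's onset of de novo methylation.  Cells differ in onset, so at
population time tau the elapsed times dt are distributed as g(dt; tau) and the
observable cross-cell density of global methylation m is the mixture

    p(m, tau) = integral f(m; m(dt)) g(dt; tau) d(dt)

with f(m; mbar) the steady-state conditional distribution around the mean.
Three generative scenarios differ in the shapes of g and f:

- ``unimodal_onset``: Gaussian onsets, Gaussian f -> p unimodal at all times.
- ``bimodal_onset``: two-component onset mixture (early lineage segregation)
  -> p bimodal only at intermediate times.
- ``oscillatory``: oscillations put extra mass at the extremes, so f is a
  symmetric two-Gaussian mixture split by the amplitude A -> p bimodal at
  early and late times but unimodal in between, where onset variability
  overshadows the oscillation amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate as _integrate
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "ModalityModel",
    "mean_trajectory",
    "population_density",
    "classify_modality",
    "modality_signature",
    "variance_asymptotics",
    "mean_level_variance",
]

SCENARIOS = ("unimodal_onset", "bimodal_onset", "oscillatory")


def mean_trajectory(delta_tau):
    """Sigmoid global methylation m(dt) = 1 / (1 + exp(-dt))."""
    return _stats.logistic.cdf(delta_tau)


@dataclass(frozen=True)
class ModalityModel:
    """Generative model for the cross-cell methylation density p(m, tau).

    Onset spread is ``onset_sd`` around mean elapsed time ``tau - onset_mu``
    (cells start de novo methylation at N(onset_mu, onset_sd^2)); for
    ``bimodal_onset`` two onset components at onset_mu +- onset_split/2 are
    used.  ``A`` is the peak-to-peak oscillation amplitude, ``sigma`` and
    ``sigma1`` the widths of the two mixture components of f (equal weights).
    The per-cell sigmoid is shifted by ``midpoint`` (cells start near zero
    methylation at onset) and scaled by ``saturation`` (CpG-poor regions
    saturate below full methylation), keeping oscillation extremes inside
    [0, 1].
    """

    scenario: str = "oscillatory"
    A: float = 0.3
    sigma: float = 0.05
    sigma1: Optional[float] = None
    onset_mu: float = 2.0
    onset_sd: float = 1.5
    onset_split: float = 6.0
    weight_hi: float = 0.5
    midpoint: float = 6.0
    saturation: float = 0.8
    m_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 1001))
    n_quad: int = 2001

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.A <= 1:
            raise ValueError("amplitude A must lie in [0, 1]")
        if self.sigma <= 0 or (self.sigma1 is not None and self.sigma1 <= 0):
            raise ValueError("mixture widths must be positive")
        if not 0 <= self.weight_hi <= 1:
            raise ValueError("weight_hi must lie in [0, 1]")

    @property
    def sig1(self) -> float:
        return self.sigma if self.sigma1 is None else self.sigma1

    def conditional(self, m: np.ndarray, mbar: float) -> np.ndarray:
        """f(m; mbar): Gaussian for the non-oscillatory scenarios, symmetric
        two-Gaussian mixture split by the amplitude A for the oscillatory one."""
        if self.scenario == "oscillatory":
            lo = _stats.norm.pdf(m, loc=mbar - self.A / 2, scale=self.sigma)
            hi = _stats.norm.pdf(m, loc=mbar + self.A / 2, scale=self.sig1)
            return (1 - self.weight_hi) * lo + self.weight_hi * hi
        return _stats.norm.pdf(m, loc=mbar, scale=self.sigma)

    def onset_density(self, delta_tau: np.ndarray, tau: float) -> np.ndarray:
        """g(dt; tau) on [0, tau]: elapsed-time density across cells."""
        loc = tau - self.onset_mu
        if self.scenario == "bimodal_onset":
            g = 0.5 * _stats.norm.pdf(delta_tau, loc=loc - self.onset_split / 2, scale=self.onset_sd) \
                + 0.5 * _stats.norm.pdf(delta_tau, loc=loc + self.onset_split / 2, scale=self.onset_sd)
        else:
            g = _stats.norm.pdf(delta_tau, loc=loc, scale=self.onset_sd)
        return g


def population_density(model: ModalityModel, tau: float) -> np.ndarray:
    """p(m, tau) on ``model.m_grid`` by Simpson quadrature over elapsed time.

    The elapsed-time density is truncated to [0, tau] and renormalized; the
    resulting density in m is normalized on the grid.  Raises if the
    quadrature mass is degenerate (grid diagnostics in the message).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    dts = np.linspace(0.0, tau, model.n_quad)
    g = model.onset_density(dts, tau)
    mass = _integrate.simpson(g, x=dts)
    if mass <= 1e-12:
        raise RuntimeError(
            f"onset density has no mass on [0, {tau}]; check onset parameters "
            f"(max g = {g.max():.3g} over {model.n_quad} points)"
        )
    g = g / mass
    mbar = model.saturation * mean_trajectory(dts - model.midpoint)
    m = model.m_grid
    f = model.conditional(m[:, None], mbar[None, :])
    p = _integrate.simpson(f * g[None, :], x=dts, axis=1)
    norm = np.trapezoid(p, m)
    if norm <= 1e-12 or not np.isfinite(norm):
        raise RuntimeError("population density failed to normalize")
    return p / norm


def classify_modality(p: np.ndarray, m_grid: Optional[np.ndarray] = None,
                      rel_prominence: float = 0.05) -> str:
    """'unimodal' or 'bimodal' by counting local maxima with relative
    prominence >= ``rel_prominence`` of the global maximum."""
    p = np.asarray(p, dtype=float)
    if p.size < 3 or np.any(p < -1e-9):
        raise ValueError("density must be a non-negative vector")
    if m_grid is not None:
        total = np.trapezoid(p, m_grid)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"density not normalized (integral = {total:.4f})")
    # pad so boundary modes count as peaks
    padded = np.concatenate([[p.min() - 1e-12], p, [p.min() - 1e-12]])
    peaks, props = _signal.find_peaks(padded, prominence=rel_prominence * p.max())
    return "bimodal" if peaks.size >= 2 else "unimodal"


def modality_signature(model: ModalityModel, tau_grid: Sequence[float]) -> dict:
    """Modality across a tau sweep and its collapsed signature string.

    The signature joins the distinct successive modality labels, e.g.
    ``bimodal-unimodal-bimodal`` for the oscillatory scenario.
    """
    labels = []
    densities = []
    for tau in tau_grid:
        p = population_density(model, float(tau))
        densities.append(p)
        labels.append(classify_modality(p, model.m_grid))
    collapsed = [labels[0]]
    for lab in labels[1:]:
        if lab != collapsed[-1]:
            collapsed.append(lab)
    return {
        "tau": np.asarray(tau_grid, dtype=float),
        "modality": labels,
        "signature": "-".join(collapsed),
        "densities": np.asarray(densities),
    }


def variance_asymptotics(mu: float, sigma2: float, regime: str,
                         n_mc: int = 100_000, seed: int = 0) -> dict:
    """Closed-form Var(mbar) across cells in the early/late asymptotic
    regimes, with a Monte-Carlo estimate of the exact variance.

    With elapsed times dt ~ N(mu, sigma2) and u = exp(-dt), the early regime
    (mbar near 0, u large) has mbar ~ 1/u and the late regime (mbar near 1,
    u small) has mbar ~ 1 - u; both give lognormal-moment closed forms
    u(mu)^{-+2} * exp(sigma2) * (exp(sigma2) - 1).  A warning flag is set
    when mbar(mu) is further than 0.1 from the regime's boundary.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if regime not in ("early", "late"):
        raise ValueError("regime must be 'early' or 'late'")
    u_mu = np.exp(-mu)
    factor = np.exp(sigma2) * (np.expm1(sigma2))
    closed = (u_mu**-2 if regime == "early" else u_mu**2) * factor
    rng = np.random.default_rng(seed)
    dts = rng.normal(mu, np.sqrt(sigma2), size=n_mc)
    mc = float(np.var(mean_trajectory(dts)))
    mbar_mu = mean_trajectory(mu)
    boundary = 0.0 if regime == "early" else 1.0
    return {
        "closed_form": float(closed),
        "monte_carlo": mc,
        "in_validity_regime": bool(abs(mbar_mu - boundary) <= 0.1),
    }


def mean_level_variance(tau_grid: Sequence[float], onset_mu: float = 0.0,
                        onset_sd: float = 1.0, n_quad: int = 4001) -> np.ndarray:
    """Exact Var(mbar) across cells as population time tau sweeps.

    Elapsed times are N(tau - onset_mu, onset_sd^2) (untruncated); the
    variance of the sigmoid of a Gaussian rises, peaks once, and falls."""
    out = np.empty(len(tau_grid))
    for k, tau in enumerate(tau_grid):
        x = np.linspace(-8, 8, n_quad) * onset_sd + (tau - onset_mu)
        g = _stats.norm.pdf(x, loc=tau - onset_mu, scale=onset_sd)
        mb = mean_trajectory(x)
        m1 = np.trapezoid(mb * g, x)
        m2 = np.trapezoid(mb**2 * g, x)
        out[k] = m2 - m1**2
    return out
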