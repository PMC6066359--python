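"""Delayed stochastic simulation of methylation turnover with scBS-seq noise.

Counts of unmodified (C) and methylated (M) cytosines in a genomic region
evolve by two reactions: autocatalytic methylation C+M -> 2M with propensity
alpha*C*M, and demethylation initiation with propensity beta*M, which removes
one M immediately and schedules the reappearance of one C a fixed delay
delta_t later (the in-transit pool of excision/repair intermediates).  This
is the delayed-Gillespie reading of the time-delayed master equation; queued
intermediates are inert.

Sequencing noise follows the single-cell bisulfite model: a region is
observed through s informative CpGs with s drawn from a discretized
exponential (mean 14.3) truncated below at 5, and the number of positive
calls k is Binomial(s, r) at true rate r = M/(C+M).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._jit import njit

__all__ = [
    "TurnoverParams",
    "ReadNoiseModel",
    "TurnoverPath",
    "simulate_delayed_turnover",
    "ensemble_rates",
    "sample_reads",
    "rate_distribution",
    "truncated_coverage_mean",
]


@dataclass(frozen=True)
class TurnoverParams:
    alpha: float = 0.001
    beta: float = 1.0
    delta_t: float = 6.0
    C0: int = 3400
    M0: int = 400
    t_end: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.delta_t) < 0:
            raise ValueError("alpha, beta, delta_t must be >= 0")
        if self.C0 < 0 or self.M0 < 0:
            raise ValueError("C0, M0 must be non-negative integers")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")


@dataclass(frozen=True)
class ReadNoiseModel:
    """Coverage and read-noise model for single-cell bisulfite data."""

    coverage_mean: float = 14.3
    min_coverage: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")

    def sample_coverage(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw coverages: ceil of an exponential (rejection below the
        truncation point)."""
        out = np.empty(size, dtype=np.int64)
        filled = 0
        while filled < size:
            draw = np.ceil(rng.exponential(self.coverage_mean, size=2 * (size - filled))).astype(np.int64)
            draw = draw[draw >= self.min_coverage]
            take = min(draw.size, size - filled)
            out[filled:filled + take] = draw[:take]
            filled += take
        return out


def truncated_coverage_mean(noise: ReadNoiseModel) -> float:
    """Exact mean of ceil(Exp(mean)) conditioned on >= min_coverage.

    ceil of an exponential is geometric; by memorylessness the conditional
    mean is (min_coverage - 1) + 1/(1 - q) with q = exp(-1/mean).
    """
    q = np.exp(-1.0 / noise.coverage_mean)
    return (noise.min_coverage - 1) + 1.0 / (1.0 - q)


@dataclass
class TurnoverPath:
    """Event-resolved sample path of the delayed birth-death process."""

    times: np.ndarray
    C: np.ndarray
    M: np.ndarray
    in_transit: np.ndarray

    def rate(self) -> np.ndarray:
        """Observed methylation fraction M/(C+M), in-transit excluded."""
        denom = self.C + self.M
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.M / denom, np.nan)


@njit(cache=False)
def _gillespie_paths(alpha, beta, delta_t, C0, M0, t_end, timepoints, n_paths, seed):
    """Delayed Gillespie; records (C, M, transit) at the requested timepoints
    for each path.  Fixed delay makes the completion queue FIFO."""
    np.random.seed(seed)
    n_t = timepoints.shape[0]
    outC = np.empty((n_paths, n_t), dtype=np.int64)
    outM = np.empty((n_paths, n_t), dtype=np.int64)
    outQ = np.empty((n_paths, n_t), dtype=np.int64)
    qcap = C0 + M0 + 1
    queue = np.empty(qcap)
    for p in range(n_paths):
        C = C0
        M = M0
        head = 0
        tail = 0  # queue holds completion times, FIFO
        t = 0.0
        k = 0
        while k < n_t:
            a_meth = alpha * C * M
            a_dem = beta * M
            a0 = a_meth + a_dem
            t_next_q = queue[head % qcap] if tail > head else np.inf
            if a0 > 0.0:
                t_react = t - np.log(np.random.random()) / a0
            else:
                t_react = np.inf
            t_event = t_react if t_react < t_next_q else t_next_q
            # record all timepoints passed before the next event
            while k < n_t and timepoints[k] < t_event:
                outC[p, k] = C
                outM[p, k] = M
                outQ[p, k] = tail - head
                k += 1
            if t_event == np.inf or k >= n_t:
                break
            t = t_event
            if t_react < t_next_q:
                if np.random.random() * a0 < a_meth:
                    C -= 1
                    M += 1
                else:
                    M -= 1
                    queue[tail % qcap] = t + delta_t
                    tail += 1
            else:
                C += 1
                head += 1
    return outC, outM, outQ


def simulate_delayed_turnover(params: TurnoverParams) -> TurnoverPath:
    """One event-resolved sample path of the delayed turnover process.

    Exact in distribution: between events the propensities are constant,
    and the fixed-delay completion queue is first-in-first-out.
    """
    rng = np.random.default_rng(params.seed)
    t = 0.0
    C, M = params.C0, params.M0
    queue: list[float] = []
    times = [0.0]
    Cs, Ms, Qs = [C], [M], [0]
    while t < params.t_end:
        a_meth = params.alpha * C * M
        a_dem = params.beta * M
        a0 = a_meth + a_dem
        t_next_q = queue[0] if queue else np.inf
        t_react = t + rng.exponential(1.0 / a0) if a0 > 0 else np.inf
        t_event = min(t_react, t_next_q)
        if t_event > params.t_end or t_event == np.inf:
            break
        t = t_event
        if t_react <= t_next_q:
            if rng.random() * a0 < a_meth:
                C, M = C - 1, M + 1
            else:
                M -= 1
                queue.append(t + params.delta_t)
        else:
            C += 1
            queue.pop(0)
        times.append(t)
        Cs.append(C)
        Ms.append(M)
        Qs.append(len(queue))
    return TurnoverPath(
        times=np.asarray(times), C=np.asarray(Cs), M=np.asarray(Ms),
        in_transit=np.asarray(Qs),
    )


def ensemble_rates(
    params: TurnoverParams,
    timepoints: Sequence[float],
    n_paths: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """True rates M/(C+M) for an ensemble of paths at fixed timepoints.

    Returns an (n_paths, n_timepoints) array.  Timepoints must lie within
    [0, t_end].
    """
    tp = np.asarray(timepoints, dtype=float)
    if np.any(tp < 0) or np.any(tp > params.t_end):
        raise ValueError("timepoints must lie within [0, t_end]")
    order = np.argsort(tp)
    tp_sorted = tp[order]
    s = params.seed if seed is None else seed
    C, M, _ = _gillespie_paths(
        params.alpha, params.beta, params.delta_t,
        params.C0, params.M0, params.t_end, tp_sorted, n_paths, s,
    )
    denom = C + M
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, M / denom, np.nan)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return r[:, inv]


def sample_reads(true_rate, noise: ReadNoiseModel, rng: Optional[np.random.Generator] = None) -> dict:
    """Observe true methylation rates through the coverage/binomial model.

    ``true_rate`` may be a scalar or array; returns ``{"k": ..., "s": ...}``
    with matching shape.
    """
    r = np.asarray(true_rate, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("true_rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    s = noise.sample_coverage(rng, size=r.size).reshape(r.shape)
    k = rng.binomial(s, r)
    if np.ndim(true_rate) == 0:
        return {"k": int(k), "s": int(s)}
    return {"k": k, "s": s}


def rate_distribution(
    params: TurnoverParams,
    noise: ReadNoiseModel,
    n_sims: int,
    timepoints: Sequence[float],
    bins: int = 20,
    seed: Optional[int] = None,
) -> dict:
    """Per-timepoint histograms of observed rates k/s over simulated paths.

    One (k, s) draw per simulation per timepoint; histograms are normalized
    to probabilities over ``bins`` equal bins on [0, 1].
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    tp = np.asarray(timepoints, dtype=float)
    rates = ensemble_rates(params, tp, n_sims, seed=seed)
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)
    edges = np.linspace(0.0, 1.0, bins + 1)
    hists = np.zeros((tp.size, bins))
    observed = np.full_like(rates, np.nan)
    for j in range(tp.size):
        r = rates[:, j]
        valid = np.isfinite(r)
        obs = sample_reads(r[valid], noise, rng=rng)
        kr = obs["k"] / obs["s"]
        observed[valid, j] = kr
        h, _ = np.histogram(kr, bins=edges)
        hists[j] = h / max(h.sum(), 1)
    return {"timepoints": tp, "bin_edges": edges, "hist": hists, "observed": observed}
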