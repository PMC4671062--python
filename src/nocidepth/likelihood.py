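"""Maximum-likelihood estimation of (threshold, depth) with response delays.

The classical method assumes the first spike occurs exactly when the receptor
reaches its threshold temperature.  Here that assumption is relaxed: the
latency tau_i of stimulus i decomposes as

    tau_i = t*_i(T, gamma) + Delta_i,      Delta_i >= 0,

where t*_i is the threshold-crossing time under the forward model and the
delays Delta_i are i.i.d. exponential with rate ``lambda`` (default 1; its
exact value does not change the ranking of parameter constellations).  The
log likelihood is

    L(T, gamma) = sum_i [ log(lambda) - lambda * Delta_i(T, gamma) ],

defined only where every delay is nonnegative (the feasible region); an
infeasible constellation carries likelihood -inf.  Maximizing L is
equivalent to minimizing the total delay, so for monotone (ramp/step)
stimuli the optimum always lies on the feasibility boundary where the
smallest delay is exactly zero.  :func:`mle_fit` exploits this: the boundary
depth for a trial threshold T has the closed form
``gamma = sqrt(tau_i) * erfcinv((T - T0)/(T_s(tau_i) - T0))`` per stimulus,
reducing the search to a dense 1-D grid in T followed by Brent refinement.
In the zero-delay limit the estimate coincides with the classical
intersection solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfcinv

from .classical import Recording
from .thermal import (
    StimulusTrace,
    running_surface_max,
    threshold_time,
    threshold_times_paired,
)

#: Delays more negative than this are infeasible; smaller violations are
#: numerical noise from root finding and are clipped to zero.
FEASIBILITY_ATOL = 1e-6


@dataclass(frozen=True)
class DelayVector:
    """Per-stimulus delays between threshold crossing and first spike."""

    delays: np.ndarray
    rate_lambda: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        object.__setattr__(self, "delays", d)
        if np.any(d < 0):
            raise ValueError("delays must be nonnegative")
        if self.rate_lambda <= 0:
            raise ValueError("rate_lambda must be positive")


@dataclass
class MLEstimate:
    """Joint maximum-likelihood estimate for one neuron."""

    T_threshold: float | None
    gamma: float | None
    loglik: float
    delays: DelayVector | None
    converged: bool
    D: float | None = None  # filled by callers via the priors module
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "T_threshold_C": self.T_threshold,
            "gamma_sqrt_s": self.gamma,
            "depth_mm": self.D,
            "depth_um": None if self.D is None else self.D * 1e3,
            "loglik": self.loglik,
            "delays_s": None if self.delays is None
            else [float(x) for x in self.delays.delays],
            "rate_lambda": None if self.delays is None else self.delays.rate_lambda,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


@dataclass(frozen=True)
class MLESearchConfig:
    """Deterministic search settings for :func:`mle_fit`."""

    n_temp: int = 400
    gamma_max: float = 3.2  # ~ gamma(2 x assumed 1 mm skin thickness)
    refine_xatol: float = 1e-7
    t_tol: float = 1e-9


def delay_of(T_threshold: float, gamma: float, trace: StimulusTrace,
             latency: float, T0: float, t_tol: float = 1e-9) -> float | None:
    """Delay latency - t* implied by (T_threshold, gamma); None if infeasible.

    Infeasible means the threshold is never crossed within the trace or the
    implied delay is negative.
    """
    t_star = threshold_time(T_threshold, T0, gamma, trace, t_tol=t_tol)
    if not np.isfinite(t_star):
        return None
    d = latency - t_star
    if d < -FEASIBILITY_ATOL:
        return None
    return max(d, 0.0)


def log_likelihood(T_threshold: float, gamma: float, recording: Recording,
                   rate_lambda: float = 1.0) -> float:
    """Exponential-delay log likelihood; -inf outside the feasible region."""
    if rate_lambda <= 0:
        raise ValueError("rate_lambda must be positive")
    if T_threshold <= recording.T0:
        return -np.inf
    total = 0.0
    for trace, tau in zip(recording.traces, recording.latencies):
        d = delay_of(T_threshold, gamma, trace, tau, recording.T0)
        if d is None:
            return -np.inf
        total += np.log(rate_lambda) - rate_lambda * d
    return float(total)


def gamma_on_curve(trace: StimulusTrace, T0: float, latency: float,
                   T_threshold: float, gamma_max: float = 50.0) -> float:
    """Largest gamma at which stimulus ``trace`` can have crossed
    ``T_threshold`` by ``latency`` (i.e. the consistency-curve depth).

    Closed form for monotone stimuli; bisection on the threshold-crossing
    time otherwise.  Returns 0.0 when even a surface receptor could not have
    crossed.
    """
    peak = running_surface_max(trace, latency)
    ratio = (T_threshold - T0) / (peak - T0) if peak > T0 else np.inf
    if ratio >= 1.0:
        return 0.0
    if trace.is_monotone:
        return float(np.sqrt(latency) * erfcinv(ratio))
    lo, hi = 0.0, gamma_max
    if threshold_time(T_threshold, T0, hi, trace) <= latency:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if threshold_time(T_threshold, T0, mid, trace) <= latency:
            lo = mid
        else:
            hi = mid
    return lo


def _boundary_gamma(recording: Recording, T: float, gamma_max: float) -> float:
    g = min(gamma_on_curve(tr, recording.T0, tau, T)
            for tr, tau in zip(recording.traces, recording.latencies))
    return float(min(max(g, 0.0), gamma_max))


def mle_fit(recording: Recording, rate_lambda: float = 1.0,
            config: MLESearchConfig | None = None) -> MLEstimate:
    """Joint MLE of (T_threshold, gamma) under the exponential-delay model.

    Dense threshold grid over the feasible range, boundary-gamma evaluation,
    then bounded Brent refinement of the threshold.  Deterministic given the
    configuration; ties on the grid resolve toward smaller gamma.
    """
    if config is None:
        config = MLESearchConfig()
    if recording.n_stimuli < 2:
        raise ValueError("mle_fit needs at least 2 stimuli")
    if rate_lambda <= 0:
        raise ValueError("rate_lambda must be positive")
    T0 = recording.T0
    n = recording.n_stimuli

    # Feasible thresholds: each stimulus must have reached T at the surface
    # by its latency, so T <= min_i max_{t<=tau_i} T_s_i(t).
    T_hi = min(running_surface_max(tr, tau)
               for tr, tau in zip(recording.traces, recording.latencies))
    if T_hi <= T0 + 1e-9:
        return MLEstimate(
            T_threshold=None, gamma=None, loglik=-np.inf, delays=None,
            converged=False,
            diagnostics={"reason": "empty feasible region",
                         "T_upper_bound": T_hi, "T0": T0})

    T_grid = np.linspace(T0 + (T_hi - T0) * 1e-4, T_hi, config.n_temp)
    g_grid = np.array([_boundary_gamma(recording, T, config.gamma_max)
                       for T in T_grid])
    # Every (T, boundary-gamma) point is feasible by construction (the
    # smallest delay is exactly zero there); the paired threshold times are
    # grid-interpolated, so negative residuals of interpolation size are
    # clipped rather than treated as infeasibility.
    total_delay = np.zeros(len(T_grid))
    crossed = np.ones(len(T_grid), dtype=bool)
    for trace, tau in zip(recording.traces, recording.latencies):
        t_star = threshold_times_paired(trace, T0, g_grid, T_grid)
        crossed &= np.isfinite(t_star)
        total_delay += np.clip(tau - t_star, 0.0, None)
    obj = np.where(crossed, n * np.log(rate_lambda) - rate_lambda * total_delay,
                   -np.inf)
    if not np.any(np.isfinite(obj)):
        return MLEstimate(
            T_threshold=None, gamma=None, loglik=-np.inf, delays=None,
            converged=False,
            diagnostics={"reason": "no feasible grid point",
                         "T_upper_bound": T_hi})

    # ties toward smaller gamma = larger T: scan the grid from the top
    best = len(obj) - 1 - int(np.argmax(obj[::-1]))

    def neg_scalar(T: float) -> float:
        g = _boundary_gamma(recording, T, config.gamma_max)
        total = 0.0
        for trace, tau in zip(recording.traces, recording.latencies):
            ts = threshold_time(T, T0, g, trace, t_tol=config.t_tol)
            d = tau - ts
            if not np.isfinite(ts) or d < -FEASIBILITY_ATOL:
                return np.inf
            total += max(d, 0.0)
        return -(n * np.log(rate_lambda) - rate_lambda * total)

    lo = T_grid[max(best - 1, 0)]
    hi = T_grid[min(best + 1, len(T_grid) - 1)]
    T_hat = float(T_grid[best])
    best_val = -float(obj[best])
    if hi > lo:
        res = minimize_scalar(neg_scalar, bounds=(lo, hi), method="bounded",
                              options={"xatol": config.refine_xatol})
        if res.fun < best_val:
            T_hat, best_val = float(res.x), float(res.fun)

    g_hat = _boundary_gamma(recording, T_hat, config.gamma_max)
    delays = []
    for trace, tau in zip(recording.traces, recording.latencies):
        d = delay_of(T_hat, g_hat, trace, tau, T0, t_tol=config.t_tol)
        if d is None:  # numerically on the wrong side of the boundary
            g_hat = max(g_hat - 1e-9, 0.0)
            d = delay_of(T_hat, g_hat, trace, tau, T0, t_tol=config.t_tol)
        delays.append(0.0 if d is None else d)
    loglik = float(n * np.log(rate_lambda) - rate_lambda * sum(delays))
    return MLEstimate(
        T_threshold=T_hat, gamma=g_hat, loglik=loglik,
        delays=DelayVector(np.array(delays), rate_lambda),
        converged=True,
        diagnostics={"T_upper_bound": float(T_hi), "n_temp": config.n_temp,
                     "gamma_max": config.gamma_max})
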