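"""Heat conduction from a surface electrode to a nociceptor ending in skin.

The forward model treats skin as a semi-infinite homogeneous solid at a
uniform baseline temperature ``T0``.  When the surface is held at temperature
``T_s``, the temperature experienced by a receptor at normalized depth
``gamma`` a time ``t`` after stimulus onset follows the first-order Henriques
solution of the one-dimensional heat equation,

    T(gamma, t) = T0 + (T_s - T0) * erfc(gamma / sqrt(t)),

where ``gamma = x / (2 sqrt(alpha_eff))`` for physical depth ``x`` and
effective thermal diffusivity ``alpha_eff = k / (rho c)`` (conductivity k,
density rho, specific heat c).  Time-varying surface stimuli (ramps) are
handled quasi-statically: the expression above is evaluated with the
instantaneous surface temperature, which is accurate while heat conduction to
the receptor depth is fast relative to the ramp.  A finite-difference solver
of the full diffusion PDE (:func:`pde_oracle`) quantifies the quasi-static
error; it serves as an independent oracle in tests and is never used by the
estimators.

Two bookkeeping conventions for the diffusivity are supported.  Under
``"standard"``, ``alpha = k/(rho c)`` and the diffusion equation reads
``dT/dt = alpha d2T/dx2``.  Under ``"paper_sqrt"`` (the default),
``alpha = sqrt(k/(rho c))`` and the equation reads
``dT/dt = alpha**2 d2T/dx2``.  The two are equivalent: the effective
diffusivity entering every temperature and depth formula is ``k/(rho c)``
either way.  Units are SI internally; depths cross the API boundary in mm,
temperatures in degrees Celsius, and ``gamma`` carries units of sqrt(seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

PAPER_SQRT = "paper_sqrt"
STANDARD = "standard"
CONVENTIONS = (PAPER_SQRT, STANDARD)

#: Sentinel returned by :func:`threshold_time` when the threshold temperature
#: is never reached within the stimulus trace.  An explicit value (not an
#: exception) because the likelihood must handle parameter regions where no
#: crossing occurs.
NEVER = float("inf")


class ThermalDomainError(ValueError):
    """Physically meaningless argument (t <= 0, negative gamma, ...)."""


class TraceRangeError(ValueError):
    """Query time outside the support of a stimulus trace."""


class ConfigurationError(ValueError):
    """Invalid numerical configuration (e.g. unstable PDE step sizes)."""


# ---------------------------------------------------------------------------
# stimulus traces


@dataclass(frozen=True)
class StimulusTrace:
    """Sampled surface-temperature time series for one heat stimulus.

    ``times`` are seconds from stimulus onset (strictly increasing, starting
    at 0); ``temperatures`` are the applied surface temperatures in deg C.
    """

    times: np.ndarray
    temperatures: np.ndarray
    ramp_duration: float | None = None
    hold_duration: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temperatures", temps)
        if times.ndim != 1 or temps.ndim != 1 or len(times) != len(temps):
            raise ValueError("times and temperatures must be 1-D and equal length")
        if len(times) < 2:
            raise ValueError("a stimulus trace needs at least 2 samples")
        if times[0] != 0.0:
            raise ValueError("trace must start at t = 0 (stimulus onset)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(temps < 0.0) or np.any(temps > 100.0):
            raise ValueError("surface temperatures must lie in [0, 100] degC")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def is_monotone(self) -> bool:
        """True if the surface temperature never decreases over the trace."""
        return bool(np.all(np.diff(self.temperatures) >= -1e-12))

    @classmethod
    def step(cls, T0: float, T_step: float, duration: float,
             rise_time: float = 1e-6) -> "StimulusTrace":
        """Idealized step stimulus: T0 at onset, T_step after ``rise_time``."""
        return cls(
            times=np.array([0.0, rise_time, duration]),
            temperatures=np.array([T0, T_step, T_step]),
            ramp_duration=rise_time,
            hold_duration=duration - rise_time,
        )

    @classmethod
    def ramp_hold(cls, T0: float, T_peak: float, ramp_duration: float,
                  hold_duration: float, dt: float = 0.02) -> "StimulusTrace":
        """Linear ramp T0 -> T_peak over ``ramp_duration``, then constant hold."""
        if ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        t_ramp = np.arange(0.0, ramp_duration, dt)
        t_hold = np.arange(ramp_duration, ramp_duration + hold_duration, dt)
        times = np.unique(np.concatenate(
            [t_ramp, [ramp_duration], t_hold, [ramp_duration + hold_duration]]))
        temps = np.where(
            times <= ramp_duration,
            T0 + (T_peak - T0) * times / ramp_duration,
            T_peak,
        )
        return cls(times=times, temperatures=temps,
                   ramp_duration=ramp_duration, hold_duration=hold_duration)


def surface_temp_at(trace: StimulusTrace, t):
    """Surface temperature at time ``t`` (scalar or array), linear interpolation."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > trace.duration + 1e-9):
        raise TraceRangeError(
            f"time {t!r} outside trace support [0, {trace.duration}]")
    out = np.interp(t_arr, trace.times, trace.temperatures)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# diffusivity and depth coordinates


def alpha_from_krc(k: float, rho: float, c: float,
                   convention: str = PAPER_SQRT) -> float:
    """Thermal diffusivity from conductivity, density, and specific heat.

    ``standard`` returns the textbook ``k / (rho c)`` (m^2/s); ``paper_sqrt``
    returns ``sqrt(k / (rho c))``, the square-root form paired with the
    diffusion equation written as dT/dt = alpha^2 d2T/dx2.
    """
    if k <= 0 or rho <= 0 or c <= 0:
        raise ThermalDomainError("k, rho, c must all be strictly positive")
    ratio = k / (rho * c)
    if convention == STANDARD:
        return ratio
    if convention == PAPER_SQRT:
        return float(np.sqrt(ratio))
    raise ConfigurationError(f"unknown diffusivity convention {convention!r}")


def effective_diffusivity(alpha: float, convention: str = PAPER_SQRT) -> float:
    """The diffusivity entering the heat equation, ``k/(rho c)``, in m^2/s."""
    if alpha <= 0:
        raise ThermalDomainError("diffusivity must be strictly positive")
    if convention == STANDARD:
        return alpha
    if convention == PAPER_SQRT:
        return alpha * alpha
    raise ConfigurationError(f"unknown diffusivity convention {convention!r}")


def gamma_from_depth(depth_mm: float, alpha_eff: float) -> float:
    """Normalized depth gamma = x / (2 sqrt(alpha_eff)), x in mm, gamma in s^1/2."""
    if depth_mm < 0:
        raise ThermalDomainError("depth must be nonnegative")
    return depth_mm * 1e-3 / (2.0 * np.sqrt(alpha_eff))


def depth_from_gamma(gamma: float, alpha_eff: float) -> float:
    """Physical depth in mm from normalized depth gamma (s^1/2)."""
    if gamma < 0:
        raise ThermalDomainError("gamma must be nonnegative")
    return 2.0 * gamma * np.sqrt(alpha_eff) * 1e3


@dataclass(frozen=True)
class SkinParams:
    """Homogeneous one-layer thermal parameters of skin (SI units).

    k: W m^-1 K^-1, rho: kg m^-3, c: J kg^-1 K^-1.  Optional layer
    thicknesses (mm) support the two-layer depth decomposition in
    :mod:`nocidepth.priors`.
    """

    k: float
    rho: float
    c: float
    D_e: float | None = None
    D_d: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0 or self.rho <= 0 or self.c <= 0:
            raise ThermalDomainError("skin parameters must be strictly positive")

    def alpha(self, convention: str = PAPER_SQRT) -> float:
        return alpha_from_krc(self.k, self.rho, self.c, convention)

    def alpha_eff(self) -> float:
        """Effective diffusivity k/(rho c) in m^2/s, convention independent."""
        return self.k / (self.rho * self.c)


#: Midpoints of the literature ranges for (k, rho, c); the default one-layer
#: skin when no other information is available.
MIDPOINT_SKIN = SkinParams(k=0.095, rho=1158.0, c=825.0)


@dataclass(frozen=True)
class DepthCoordinates:
    """A (gamma, D) pair with its baseline temperature."""

    gamma: float
    D: float
    T0: float

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.D < 0:
            raise ThermalDomainError("gamma and D must be nonnegative")
        if (self.gamma == 0) != (self.D == 0):
            raise ThermalDomainError("gamma == 0 iff D == 0")


# ---------------------------------------------------------------------------
# temperature at depth and threshold-crossing times


def attenuated_temperature(T_surface, T0, gamma, t):
    """Quasi-static temperature at normalized depth ``gamma`` at time ``t``.

    T0 + (T_surface - T0) * erfc(gamma / sqrt(t)); equals T_surface at
    gamma = 0 and decays to T0 as gamma grows.  Broadcasts over arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    g_arr = np.asarray(gamma, dtype=float)
    if np.any(t_arr <= 0):
        raise ThermalDomainError("t must be strictly positive")
    if np.any(g_arr < 0):
        raise ThermalDomainError("gamma must be nonnegative")
    out = T0 + (np.asarray(T_surface, dtype=float) - T0) * erfc(g_arr / np.sqrt(t_arr))
    if np.isscalar(t) and np.isscalar(gamma) and np.isscalar(T_surface):
        return float(out)
    return out


def _time_grid(trace: StimulusTrace, n_extra: int = 400) -> np.ndarray:
    """Scan grid for locating threshold crossings: trace samples plus a
    geometric refinement near onset (the erfc factor varies fastest there)."""
    extra = np.geomspace(1e-8, trace.duration, n_extra)
    return np.unique(np.concatenate([trace.times[1:], extra]))


def depth_temperature(trace: StimulusTrace, T0: float, gamma: float, t):
    """Quasi-static temperature at depth for times within the trace support."""
    return attenuated_temperature(surface_temp_at(trace, t), T0, gamma, t)


def running_surface_max(trace: StimulusTrace, t: float) -> float:
    """Largest surface temperature attained up to (and including) time t."""
    ts = trace.times[trace.times <= t]
    peak = float(np.max(trace.temperatures[: len(ts)])) if len(ts) else -np.inf
    return max(peak, surface_temp_at(trace, t))


def threshold_time(T_threshold: float, T0: float, gamma: float,
                   trace: StimulusTrace, t_tol: float = 1e-9) -> float:
    """Smallest t > 0 at which the temperature at depth reaches T_threshold.

    Returns :data:`NEVER` (inf) if the threshold is not crossed within the
    trace.  Bracketing on a scan grid followed by Brent refinement.
    """
    if T_threshold <= T0:
        raise ThermalDomainError("threshold must exceed the baseline temperature")
    if gamma < 0:
        raise ThermalDomainError("gamma must be nonnegative")
    grid = _time_grid(trace)
    theta = attenuated_temperature(
        np.interp(grid, trace.times, trace.temperatures), T0, gamma, grid)
    peaks = np.maximum.accumulate(theta)
    if peaks[-1] < T_threshold:
        return NEVER
    idx = int(np.searchsorted(peaks, T_threshold, side="left"))
    lo = grid[idx - 1] if idx > 0 else min(grid[0] * 0.5, 1e-12)
    hi = grid[idx]

    def f(t: float) -> float:
        return depth_temperature(trace, T0, gamma, t) - T_threshold

    if f(lo) >= 0.0:  # crossed essentially at onset
        return float(lo)
    if f(hi) <= 0.0:  # grid point is the crossing within tolerance
        return float(hi)
    return float(brentq(f, lo, hi, xtol=t_tol))


def threshold_times_paired(trace: StimulusTrace, T0: float,
                           gammas: np.ndarray, thresholds: np.ndarray,
                           n_extra: int = 400) -> np.ndarray:
    """Vectorized first-crossing times for paired (gamma, threshold) arrays.

    Crossings are located on the scan grid and linearly interpolated within
    the bracketing interval (adequate for likelihood evaluation; use
    :func:`threshold_time` where sub-microsecond precision matters).
    """
    g = np.atleast_1d(np.asarray(gammas, dtype=float))
    thr = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if g.shape != thr.shape:
        raise ValueError("gammas and thresholds must have matching shapes")
    ts = _time_grid(trace, n_extra)
    surf = np.interp(ts, trace.times, trace.temperatures)
    theta = T0 + (surf[None, :] - T0) * erfc(g[:, None] / np.sqrt(ts)[None, :])
    peaks = np.maximum.accumulate(theta, axis=1)
    out = np.full(g.shape, NEVER)
    n_t = len(ts)
    for r in range(len(g)):
        idx = int(np.searchsorted(peaks[r], thr[r], side="left"))
        if idx >= n_t:
            continue
        if idx == 0:
            t_prev, m_prev = 0.0, T0
        else:
            t_prev, m_prev = ts[idx - 1], peaks[r, idx - 1]
        m_cur = peaks[r, idx]
        if m_cur > m_prev:
            out[r] = t_prev + (thr[r] - m_prev) / (m_cur - m_prev) * (ts[idx] - t_prev)
        else:
            out[r] = ts[idx]
    return out


def threshold_time_table(trace: StimulusTrace, T0: float,
                         gammas: np.ndarray, thresholds: np.ndarray,
                         n_extra: int = 400) -> np.ndarray:
    """First-crossing times on the (gamma x threshold) cross-product grid.

    Returns a ``(len(gammas), len(thresholds))`` matrix with inf where the
    threshold is never crossed.  Computed row-by-row to bound memory.
    """
    g = np.asarray(gammas, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    ts = _time_grid(trace, n_extra)
    surf = np.interp(ts, trace.times, trace.temperatures)
    sqrt_ts = np.sqrt(ts)
    out = np.full((len(g), len(thr)), NEVER)
    n_t = len(ts)
    for r, gr in enumerate(g):
        theta = T0 + (surf - T0) * erfc(gr / sqrt_ts)
        peaks = np.maximum.accumulate(theta)
        idx = np.searchsorted(peaks, thr, side="left")
        ok = idx < n_t
        ii = idx[ok]
        t_prev = np.where(ii > 0, ts[np.maximum(ii - 1, 0)], 0.0)
        m_prev = np.where(ii > 0, peaks[np.maximum(ii - 1, 0)], T0)
        m_cur = peaks[ii]
        t_cur = ts[ii]
        denom = m_cur - m_prev
        frac = np.where(denom > 0, (thr[ok] - m_prev) / np.where(denom > 0, denom, 1.0), 1.0)
        out[r, ok] = t_prev + np.clip(frac, 0.0, 1.0) * (t_cur - t_prev)
    return out


# ---------------------------------------------------------------------------
# finite-difference PDE oracle


def pde_oracle(trace: StimulusTrace, alpha: float,
               depth_grid_mm: Sequence[float], time_grid: Sequence[float],
               convention: str = PAPER_SQRT, nx: int = 400,
               dt: float | None = None, safety: float = 0.45) -> np.ndarray:
    """Explicit finite-difference solution of the one-layer diffusion equation.

    Dirichlet boundary: the trace at x = 0; T0 (the trace's onset value) as
    initial and far-field condition.  Returns temperatures with shape
    ``(len(time_grid), len(depth_grid_mm))``.  Used only as a validation
    oracle for the Henriques approximation.
    """
    a = effective_diffusivity(alpha, convention)
    x_req = np.asarray(depth_grid_mm, dtype=float) * 1e-3
    t_req = np.asarray(time_grid, dtype=float)
    if np.any(t_req < 0) or np.any(t_req > trace.duration + 1e-9):
        raise TraceRangeError("requested times outside trace support")
    t_end = float(np.max(t_req)) if len(t_req) else 0.0
    # domain deep enough that the far boundary never matters
    L = max(3.0 * float(np.max(x_req, initial=1e-4)),
            8.0 * np.sqrt(a * max(t_end, 1e-6)))
    dx = L / nx
    dt_stable = safety * dx * dx / a
    if dt is None:
        dt = dt_stable
    elif dt > 0.5 * dx * dx / a:
        raise ConfigurationError(
            f"explicit scheme unstable: dt={dt} exceeds 0.5*dx^2/alpha={0.5 * dx * dx / a:.3g}")
    n_steps = int(np.ceil(t_end / dt)) if t_end > 0 else 0
    if n_steps * nx > 2e8:
        raise ConfigurationError("PDE discretization too large; coarsen the grids")
    T0 = float(trace.temperatures[0])
    x = np.linspace(0.0, L, nx + 1)
    field = np.full(nx + 1, T0)
    r = a * dt / (dx * dx)

    order = np.argsort(t_req)
    results = np.empty((len(t_req), len(x_req)))
    prev_field = field.copy()
    t_now = 0.0
    qi = 0
    # serve any queries at t = 0
    while qi < len(order) and t_req[order[qi]] <= 0.0:
        results[order[qi]] = np.interp(x_req, x, field)
        qi += 1
    for _ in range(n_steps):
        prev_field[:] = field
        t_next = t_now + dt
        field[1:-1] = field[1:-1] + r * (field[2:] - 2 * field[1:-1] + field[:-2])
        field[0] = surface_temp_at(trace, min(t_next, trace.duration))
        field[-1] = T0
        while qi < len(order) and t_req[order[qi]] <= t_next + 1e-15:
            w = (t_req[order[qi]] - t_now) / dt
            snap = (1 - w) * prev_field + w * field
            results[order[qi]] = np.interp(x_req, x, snap)
            qi += 1
        t_now = t_next
        if qi == len(order):
            break
    while qi < len(order):  # queries at exactly t_end after rounding
        results[order[qi]] = np.interp(x_req, x, field)
        qi += 1
    return results
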