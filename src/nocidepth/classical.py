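"""Classical deterministic depth/threshold estimation by curve intersection.

For each stimulus, every (depth, threshold) pair consistent with the observed
first-spike latency lies on a curve in the (gamma, T) plane: assuming the
neuron fired exactly when its threshold was reached, the threshold implied by
depth gamma is the attenuated surface temperature at the latency,

    T(gamma) = T0 + (T_s(tau) - T0) * erfc(gamma / sqrt(tau)).

With several stimuli of different ramp rates the curves should share a common
intersection -- the neuron's (gamma, T).  Real recordings often violate this;
the outcome is classified as ``single`` (all pairwise intersections
coincide), ``triangle`` (three close intersections, estimate = centroid),
``partial`` (exactly one pairwise intersection, provisional estimate only),
or ``none``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

from .thermal import (
    MIDPOINT_SKIN,
    ConfigurationError,
    StimulusTrace,
    TraceRangeError,
    attenuated_temperature,
    depth_from_gamma,
    gamma_from_depth,
    surface_temp_at,
)

STATUS_SINGLE = "single"
STATUS_TRIANGLE = "triangle"
STATUS_PARTIAL = "partial"
STATUS_NONE = "none"

#: Default coincidence tolerance for ``single`` (deg C, mm).
POINT_TOL = (0.2, 0.02)
#: Default diameter tolerance for ``triangle`` (deg C, mm); looser than
#: POINT_TOL so that "three close points" remains distinguishable from a
#: genuine single intersection.
TRIANGLE_TOL = (1.0, 0.1)


class DegenerateCurvesError(ValueError):
    """Two identical consistency curves (same stimulus and latency twice)."""


@dataclass(frozen=True)
class Recording:
    """A neuron's stimuli and conduction-corrected first-spike latencies."""

    traces: tuple
    latencies: np.ndarray
    T0: float
    neuron_id: str = "unknown"

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        lat = np.asarray(self.latencies, dtype=float)
        object.__setattr__(self, "traces", traces)
        object.__setattr__(self, "latencies", lat)
        if len(traces) != len(lat):
            raise ValueError("one latency per stimulus required")
        if len(traces) < 2:
            raise ValueError("a recording needs at least 2 stimuli")
        for i, (tr, tau) in enumerate(zip(traces, lat)):
            if not isinstance(tr, StimulusTrace):
                raise TypeError(f"stimulus {i} is not a StimulusTrace")
            if not (0.0 < tau <= tr.duration):
                raise ValueError(
                    f"latency {tau} of stimulus {i} outside trace support "
                    f"(0, {tr.duration}]")
            if abs(tr.temperatures[0] - self.T0) > 0.5:
                raise ValueError(
                    f"stimulus {i} does not start at the baseline temperature")

    @property
    def n_stimuli(self) -> int:
        return len(self.traces)

    @property
    def max_surface_temp(self) -> float:
        return float(max(np.max(t.temperatures) for t in self.traces))

    def subset(self, indices) -> "Recording":
        idx = list(indices)
        return Recording(
            traces=tuple(self.traces[i] for i in idx),
            latencies=self.latencies[idx],
            T0=self.T0,
            neuron_id=self.neuron_id,
        )


@dataclass(frozen=True)
class ThresholdCurve:
    """Consistency curve of one stimulus in the (gamma, threshold) plane."""

    gammas: np.ndarray
    thresholds: np.ndarray
    stimulus_index: int
    latency: float
    surface_temp: float
    T0: float

    def threshold_at(self, gamma: float) -> float:
        """Exact (not gridded) threshold at a given gamma."""
        return self.T0 + (self.surface_temp - self.T0) * float(
            erfc(gamma / np.sqrt(self.latency)))


@dataclass
class ClassicalEstimate:
    """Outcome of the intersection method for one neuron."""

    status: str
    T_threshold: float | None = None
    gamma: float | None = None
    D: float | None = None
    intersections: list = field(default_factory=list)
    provisional: tuple | None = None
    n_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "T_threshold_C": self.T_threshold,
            "gamma_sqrt_s": self.gamma,
            "depth_mm": self.D,
            "depth_um": None if self.D is None else self.D * 1e3,
            "intersections": [[float(g), float(T)] for g, T in self.intersections],
            "provisional": None if self.provisional is None
            else [float(self.provisional[0]), float(self.provisional[1])],
            "n_pairs": self.n_pairs,
        }


def default_gamma_grid(alpha_eff: float | None = None, n: int = 2000,
                       max_depth_mm: float = 5.0) -> np.ndarray:
    """Geometric gamma grid over [0, gamma(max_depth_mm)], 2000 points."""
    if alpha_eff is None:
        alpha_eff = MIDPOINT_SKIN.alpha_eff()
    g_hi = gamma_from_depth(max_depth_mm, alpha_eff)
    return np.concatenate([[0.0], np.geomspace(g_hi * 1e-4, g_hi, n - 1)])


def threshold_curve(trace: StimulusTrace, latency: float, T0: float,
                    gamma_grid: np.ndarray, stimulus_index: int = 0) -> ThresholdCurve:
    """Consistency curve of one stimulus evaluated on a gamma grid."""
    if not (0.0 < latency <= trace.duration):
        raise TraceRangeError(f"latency {latency} outside trace support")
    surf = surface_temp_at(trace, latency)
    thresholds = attenuated_temperature(
        surf, T0, np.asarray(gamma_grid, dtype=float),
        np.full(len(gamma_grid), latency))
    return ThresholdCurve(
        gammas=np.asarray(gamma_grid, dtype=float), thresholds=thresholds,
        stimulus_index=stimulus_index, latency=float(latency),
        surface_temp=float(surf), T0=float(T0))


def pairwise_intersection(curve_a: ThresholdCurve, curve_b: ThresholdCurve,
                          refine: bool = True) -> tuple | None:
    """First (gamma, T) crossing of two consistency curves, or None.

    Sign changes of the threshold difference are located on the shared grid
    and refined by Brent's method on the continuous difference.
    """
    if not np.array_equal(curve_a.gammas, curve_b.gammas):
        raise ValueError("curves must share a common gamma grid")
    d = curve_a.thresholds - curve_b.thresholds
    if float(np.max(np.abs(d))) < 1e-12:
        raise DegenerateCurvesError(
            "identical consistency curves (same stimulus and latency twice)")
    g = curve_a.gammas

    def diff(x: float) -> float:
        return curve_a.threshold_at(x) - curve_b.threshold_at(x)

    # every curve decays to T0 as gamma grows; exact ties there are the
    # common asymptote (erfc underflow), not an intersection
    asymptote_tol = 0.01

    for j in range(len(g) - 1):
        if d[j] == 0.0:
            if curve_a.thresholds[j] > curve_a.T0 + asymptote_tol:
                return float(g[j]), curve_a.threshold_at(float(g[j]))
            continue
        if d[j] * d[j + 1] < 0.0:
            if refine:
                gx = float(brentq(diff, g[j], g[j + 1], xtol=1e-12))
            else:
                gx = float(g[j] - d[j] * (g[j + 1] - g[j]) / (d[j + 1] - d[j]))
            if curve_a.threshold_at(gx) > curve_a.T0 + asymptote_tol:
                return gx, curve_a.threshold_at(gx)
            return None
    if d[-1] == 0.0 and curve_a.thresholds[-1] > curve_a.T0 + asymptote_tol:
        return float(g[-1]), curve_a.threshold_at(float(g[-1]))
    return None


def classify_and_estimate(recording: Recording,
                          alpha_eff: float | None = None,
                          point_tol: tuple = POINT_TOL,
                          triangle_tol: tuple = TRIANGLE_TOL,
                          gamma_grid: np.ndarray | None = None) -> ClassicalEstimate:
    """Intersect all consistency curves and classify the outcome.

    ``alpha_eff`` (m^2/s) converts gamma to physical depth for the
    depth-space tolerance components and the reported D; defaults to the
    literature-midpoint skin.
    """
    if recording.n_stimuli < 2:
        raise ConfigurationError("classification needs at least 2 stimuli")
    if alpha_eff is None:
        alpha_eff = MIDPOINT_SKIN.alpha_eff()
    if gamma_grid is None:
        gamma_grid = default_gamma_grid(alpha_eff)

    curves = [threshold_curve(tr, tau, recording.T0, gamma_grid, i)
              for i, (tr, tau) in enumerate(zip(recording.traces,
                                                recording.latencies))]
    points = []
    n_pairs = 0
    n_degenerate = 0
    for a, b in itertools.combinations(curves, 2):
        try:
            pt = pairwise_intersection(a, b)
        except DegenerateCurvesError:
            # Two crossings in the hold phase see the same surface history
            # under the quasi-static model, so their curves coincide; the
            # pair carries no intersection information.
            n_degenerate += 1
            continue
        n_pairs += 1
        if pt is not None:
            points.append(pt)

    def diameter(pts):
        gs = np.array([p[0] for p in pts])
        Ts = np.array([p[1] for p in pts])
        Ds = np.array([depth_from_gamma(gv, alpha_eff) for gv in gs])
        return float(np.ptp(Ts)), float(np.ptp(Ds))

    est = ClassicalEstimate(status=STATUS_NONE, intersections=points,
                            n_pairs=n_pairs)
    if len(points) == n_pairs and points:
        dT, dD = diameter(points)
        if dT <= point_tol[0] and dD <= point_tol[1]:
            g_hat = float(np.mean([p[0] for p in points]))
            est.status = STATUS_SINGLE
            est.gamma = g_hat
            est.T_threshold = float(np.mean([p[1] for p in points]))
            est.D = depth_from_gamma(g_hat, alpha_eff)
            return est
        if recording.n_stimuli == 3 and dT <= triangle_tol[0] and dD <= triangle_tol[1]:
            g_hat = float(np.mean([p[0] for p in points]))
            est.status = STATUS_TRIANGLE
            est.gamma = g_hat
            est.T_threshold = float(np.mean([p[1] for p in points]))
            est.D = depth_from_gamma(g_hat, alpha_eff)
            return est
    if len(points) == 1:
        est.status = STATUS_PARTIAL
        est.provisional = points[0]
        return est
    return est
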