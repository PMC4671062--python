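"""Marginal-likelihood model comparison with stimulus-exclusion candidates.

A recorded first spike may not be a response to the stimulus at all but a
spontaneous discharge.  To decide, the full model M1 (every first spike is
stimulus driven, exponential delays) is compared against exclusion models
M2_i in which the first spike of stimulus i is a spontaneous event of a
Poisson process with rate lambda_s, and only the remaining stimuli constrain
(T, gamma).  Each candidate is scored by its marginal likelihood

    E[M] = integral L(data | T, gamma, M) p(T) p(gamma) dT dgamma,

with p(T) the Normal threshold prior and p(gamma) the Gaussian-mixture
approximation of the induced depth prior.  Treating the excluded latency as a
fixed observation (a Dirac likelihood component) makes the outlier factor
separable: it is the expectation of the exponential density at the excluded
latency over the lambda_s prior (Uniform(0.01, 2) s^-1 by default, an
assumption recorded in the output metadata).  Evidences are normalized to
weights summing to 1 and the maximum-evidence candidate is selected; the
normalized full-model weight L_full is the per-neuron outlier signature.

Integration is trapezoidal over a (T, gamma) grid.  Because the likelihood
is maximal on, and discontinuous across, the feasibility boundary
(min_i Delta_i = 0), the exact boundary depth for each threshold slice is
appended as an integration node; without it the trapezoid error would be
first order in the grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .classical import Recording
from .likelihood import MLEstimate, gamma_on_curve, mle_fit
from .priors import DEFAULT_PRIOR, PriorContext, monte_carlo_depth
from .thermal import threshold_time_table

FULL = "full"
EXCLUDE = "exclude"


@dataclass(frozen=True)
class CandidateModel:
    kind: str
    excluded_stimulus: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (FULL, EXCLUDE):
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        if (self.kind == EXCLUDE) != (self.excluded_stimulus is not None):
            raise ValueError("exclusion models need a stimulus index")

    def label(self) -> str:
        return "M1" if self.kind == FULL else f"M2_{self.excluded_stimulus}"


@dataclass(frozen=True)
class EvidenceConfig:
    """Grid sizes and the lambda_s prior for evidence integration."""

    n_temp: int = 150
    n_gamma: int = 150
    gamma_max: float = 3.2
    T_max: float | None = None          # default: max recorded surface temp
    lambda_s_range: tuple = (0.01, 2.0)  # s^-1, spontaneous-rate prior
    lambda_s_points: int = 200
    rate_lambda: float = 1.0
    table_n_gamma: int = 400
    table_n_temp: int = 320


@dataclass
class ModelEvidence:
    """Evidences, normalized weights, and the selected candidate."""

    candidates: list
    evidences: np.ndarray
    weights: np.ndarray
    selected: CandidateModel | None
    l_full_weight: float
    estimate: MLEstimate | None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "candidates": [c.label() for c in self.candidates],
            "evidences": [float(e) for e in self.evidences],
            "weights": [float(w) for w in self.weights],
            "selected": None if self.selected is None else self.selected.label(),
            "l_full_weight": float(self.l_full_weight),
            "estimate": None if self.estimate is None else self.estimate.to_dict(),
            "diagnostics": self.diagnostics,
        }


def spontaneous_rate_expectation(latency: float, lam_range: tuple = (0.01, 2.0),
                                 n_points: int = 200) -> float:
    """E_{lambda_s}[ lambda_s exp(-lambda_s tau) ] under a uniform rate prior.

    The separable outlier factor of an exclusion model: the exponential
    first-spike density at the excluded latency, averaged over the
    spontaneous-rate prior by trapezoidal integration.
    """
    lo, hi = lam_range
    lam = np.linspace(lo, hi, n_points)
    return float(np.trapezoid(lam * np.exp(-lam * latency), lam) / (hi - lo))


class _TStarTables:
    """Per-stimulus lookup tables of the threshold-crossing time t*(gamma, T)."""

    def __init__(self, recording: Recording, cfg: EvidenceConfig):
        T0 = recording.T0
        T_max = cfg.T_max if cfg.T_max is not None else recording.max_surface_temp
        self.g_axis = np.linspace(0.0, cfg.gamma_max, cfg.table_n_gamma)
        self.T_axis = np.linspace(T0 + 1e-6, T_max, cfg.table_n_temp)
        self.tables = []
        for trace in recording.traces:
            tab = threshold_time_table(trace, T0, self.g_axis, self.T_axis)
            # inflate never-crossed entries so interpolation near the frontier
            # lands on the infeasible side rather than poisoning neighbors
            tab = np.where(np.isfinite(tab), tab, 10.0 * trace.duration)
            self.tables.append(tab)

    def t_star(self, i: int, gammas: np.ndarray, T: float) -> np.ndarray:
        """Bilinear interpolation of t* for stimulus i at fixed threshold T."""
        T_axis, g_axis = self.T_axis, self.g_axis
        j = int(np.clip(np.searchsorted(T_axis, T) - 1, 0, len(T_axis) - 2))
        w = (T - T_axis[j]) / (T_axis[j + 1] - T_axis[j])
        w = float(np.clip(w, 0.0, 1.0))
        col_lo = np.interp(gammas, g_axis, self.tables[i][:, j])
        col_hi = np.interp(gammas, g_axis, self.tables[i][:, j + 1])
        return (1 - w) * col_lo + w * col_hi


def _retained_evidence(recording: Recording, retained: list, prior_ctx,
                       cfg: EvidenceConfig, tables: _TStarTables) -> float:
    """Trapezoidal integral of likelihood x priors over (T, gamma) for the
    retained stimuli, with the exact feasibility-boundary node per T slice."""
    T0 = recording.T0
    lam = cfg.rate_lambda
    m = len(retained)
    T_grid = tables.T_axis if cfg.n_temp == cfg.table_n_temp else np.linspace(
        T0 + 1e-6, tables.T_axis[-1], cfg.n_temp)
    g_grid = np.linspace(0.0, cfg.gamma_max, cfg.n_gamma)
    shift = m * np.log(lam)  # upper bound of the retained log likelihood
    slices = np.zeros(len(T_grid))
    for j, T in enumerate(T_grid):
        g_b = min(gamma_on_curve(recording.traces[i], T0,
                                 recording.latencies[i], T)
                  for i in retained)
        g_b = min(g_b, cfg.gamma_max)
        if g_b <= 0.0:
            continue
        nodes = np.append(g_grid[g_grid < g_b], g_b)
        loglik = np.full(len(nodes), m * np.log(lam))
        ok = np.ones(len(nodes), dtype=bool)
        for i in retained:
            d = recording.latencies[i] - tables.t_star(i, nodes, T)
            ok &= d > -1e-3  # interpolation tolerance at the boundary node
            loglik -= lam * np.clip(d, 0.0, None)
        integrand = np.where(ok, np.exp(loglik - shift), 0.0) \
            * prior_ctx.gamma_pdf(nodes)
        slices[j] = np.trapezoid(integrand, nodes) * prior_ctx.threshold_pdf(T)
    return float(np.exp(shift) * np.trapezoid(slices, T_grid))


def marginal_likelihood_full(recording: Recording, prior_ctx,
                             cfg: EvidenceConfig | None = None,
                             tables: _TStarTables | None = None) -> float:
    """Evidence of the full model M1 (all first spikes stimulus driven)."""
    cfg = cfg or EvidenceConfig()
    tables = tables or _TStarTables(recording, cfg)
    return _retained_evidence(recording, list(range(recording.n_stimuli)),
                              prior_ctx, cfg, tables)


def marginal_likelihood_exclude(recording: Recording, i: int, prior_ctx,
                                cfg: EvidenceConfig | None = None,
                                tables: _TStarTables | None = None) -> float:
    """Evidence of M2_i: stimulus i's first spike is a spontaneous event."""
    cfg = cfg or EvidenceConfig()
    tables = tables or _TStarTables(recording, cfg)
    retained = [j for j in range(recording.n_stimuli) if j != i]
    base = _retained_evidence(recording, retained, prior_ctx, cfg, tables)
    outlier = spontaneous_rate_expectation(
        float(recording.latencies[i]), cfg.lambda_s_range, cfg.lambda_s_points)
    return base * outlier


@lru_cache(maxsize=1)
def _default_prior_context() -> PriorContext:
    return PriorContext.from_spec(DEFAULT_PRIOR, seed=0)


def select_model(recording: Recording, prior_ctx: PriorContext | None = None,
                 cfg: EvidenceConfig | None = None,
                 fit_estimate: bool = True) -> ModelEvidence:
    """Score all candidates, normalize evidences, and select the maximum.

    Candidates are the full model and every single-stimulus exclusion.  The
    reported estimate is the MLE under the selected model's retained stimuli,
    with depth converted by Monte-Carlo averaging over the thermal priors.
    """
    if recording.n_stimuli < 3:
        raise ValueError("model selection needs at least 3 stimuli")
    cfg = cfg or EvidenceConfig()
    if prior_ctx is None:
        prior_ctx = _default_prior_context()
    tables = _TStarTables(recording, cfg)

    candidates = [CandidateModel(FULL)] + [
        CandidateModel(EXCLUDE, i) for i in range(recording.n_stimuli)]
    evidences = np.array(
        [marginal_likelihood_full(recording, prior_ctx, cfg, tables)]
        + [marginal_likelihood_exclude(recording, i, prior_ctx, cfg, tables)
           for i in range(recording.n_stimuli)])

    diagnostics = {
        "lambda_s_prior": {"family": "uniform",
                           "range_per_s": list(cfg.lambda_s_range),
                           "assumed": True},
        "grid": {"n_temp": cfg.n_temp, "n_gamma": cfg.n_gamma,
                 "gamma_max": cfg.gamma_max},
    }
    total = float(np.sum(evidences))
    if total <= 0.0:
        return ModelEvidence(
            candidates=candidates, evidences=evidences,
            weights=np.zeros_like(evidences), selected=None,
            l_full_weight=0.0, estimate=None,
            diagnostics={**diagnostics,
                         "reason": "all candidate evidences are zero"})
    weights = evidences / total
    best = int(np.argmax(evidences))
    selected = candidates[best]

    estimate = None
    if fit_estimate:
        if selected.kind == FULL:
            estimate = mle_fit(recording, cfg.rate_lambda)
        else:
            retained = [j for j in range(recording.n_stimuli)
                        if j != selected.excluded_stimulus]
            estimate = mle_fit(recording.subset(retained), cfg.rate_lambda)
        if estimate.converged and estimate.gamma is not None:
            estimate.D = monte_carlo_depth(estimate.gamma, prior_ctx.spec,
                                           n=20_000, seed=0)
    return ModelEvidence(
        candidates=candidates, evidences=evidences, weights=weights,
        selected=selected, l_full_weight=float(weights[0]),
        estimate=estimate, diagnostics=diagnostics)
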