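"""Ground-truth simulator of the ramped-heat stimulation experiment.

Generates the stimulation protocol (three linear ramps 32 -> 48 deg C over
16 s, 4 s, and 2 s, each followed by a 10 s hold), computes each stimulus's
threshold-crossing time for a neuron with known depth and threshold under
the same quasi-static forward model used by the estimators, and produces
first-spike latencies as

    latency = t* + Delta,   Delta ~ Exponential(delay_rate),

optionally raced against a spontaneous (Poisson-process) spike time drawn
from Exponential(outlier_rate): the earlier of the two events is recorded,
and ground-truth metadata flags which one won.  Delay draws that would land
beyond the end of the trace are redrawn (the recorded delay distribution is
truncated to the trace support).  Everything is reproducible from explicit
seeds, making the simulator the test bed for parameter-recovery and
outlier-detection studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classical import Recording
from .priors import DEFAULT_PRIOR, PriorSpec
from .thermal import (
    NEVER,
    SkinParams,
    StimulusTrace,
    gamma_from_depth,
    threshold_time,
)

#: The default stimulation protocol: (T0, T_peak, ramp durations, hold).
PROTOCOL_T0 = 32.0
PROTOCOL_T_PEAK = 48.0
PROTOCOL_RAMPS = (16.0, 4.0, 2.0)
PROTOCOL_HOLD = 10.0


@dataclass(frozen=True)
class GroundTruthNeuron:
    """A simulated nociceptor with known parameters."""

    D_true: float                 # receptor depth, mm
    T_threshold_true: float       # deg C
    skin: SkinParams = field(default_factory=lambda: SkinParams(0.095, 1158.0, 825.0))
    delay_rate: float = 1.0       # s^-1; np.inf => zero delays
    outlier_rate: float | None = None  # s^-1 spontaneous-spike rate, or None

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("depth must be nonnegative")
        if self.delay_rate <= 0:
            raise ValueError("delay_rate must be positive")
        if self.outlier_rate is not None and self.outlier_rate <= 0:
            raise ValueError("outlier_rate must be positive when set")

    @property
    def gamma_true(self) -> float:
        return gamma_from_depth(self.D_true, self.skin.alpha_eff())


@dataclass(frozen=True)
class SimulatedRecording:
    """A recording together with its generative ground truth."""

    recording: Recording | None
    neuron: GroundTruthNeuron
    threshold_times: np.ndarray   # t* per stimulus (inf if never crossed)
    delays: np.ndarray            # drawn stimulus-driven delays
    spontaneous_times: np.ndarray # drawn spontaneous spike times (inf if none)
    outlier_flags: np.ndarray     # True where the spontaneous spike won
    non_responsive: bool = False

    @property
    def has_outlier(self) -> bool:
        return bool(np.any(self.outlier_flags))


def make_protocol(T0: float = PROTOCOL_T0, T_peak: float = PROTOCOL_T_PEAK,
                  ramp_durations=PROTOCOL_RAMPS, hold: float = PROTOCOL_HOLD,
                  dt: float = 0.02) -> list[StimulusTrace]:
    """Linear ramp-and-hold traces; defaults reproduce the recording protocol."""
    if T_peak <= T0:
        raise ValueError("T_peak must exceed T0")
    if any(r <= 0 for r in ramp_durations):
        raise ValueError("ramp durations must be positive")
    return [StimulusTrace.ramp_hold(T0, T_peak, r, hold, dt=dt)
            for r in ramp_durations]


def simulate_recording(neuron: GroundTruthNeuron, protocol: list[StimulusTrace],
                       seed: int = 0, neuron_id: str = "sim",
                       max_redraws: int = 1000) -> SimulatedRecording:
    """Draw one recording for a ground-truth neuron.

    For each stimulus the stimulus-driven first spike is t* plus an
    exponential delay (redrawn if beyond the trace end); if an outlier
    process is active, an independent spontaneous spike time competes and
    the earlier event is recorded.
    """
    rng = np.random.default_rng(seed)
    T0 = float(protocol[0].temperatures[0])
    n = len(protocol)
    t_stars = np.empty(n)
    delays = np.full(n, np.nan)
    spont = np.full(n, np.inf)
    flags = np.zeros(n, dtype=bool)
    latencies = np.full(n, np.nan)

    for i, trace in enumerate(protocol):
        t_stars[i] = threshold_time(neuron.T_threshold_true, T0,
                                    neuron.gamma_true, trace)
        driven = np.inf
        if np.isfinite(t_stars[i]):
            if np.isinf(neuron.delay_rate):
                delays[i] = 0.0
            else:
                for _ in range(max_redraws):
                    d = rng.exponential(1.0 / neuron.delay_rate)
                    if t_stars[i] + d <= trace.duration:
                        delays[i] = d
                        break
            if np.isfinite(delays[i]):
                driven = t_stars[i] + delays[i]
        if neuron.outlier_rate is not None:
            s = rng.exponential(1.0 / neuron.outlier_rate)
            if s <= trace.duration:
                spont[i] = s
        event = min(driven, spont[i])
        if np.isfinite(event):
            latencies[i] = event
            flags[i] = spont[i] < driven

    if np.any(~np.isfinite(latencies)):
        return SimulatedRecording(
            recording=None, neuron=neuron, threshold_times=t_stars,
            delays=delays, spontaneous_times=spont, outlier_flags=flags,
            non_responsive=True)
    recording = Recording(traces=tuple(protocol), latencies=latencies,
                          T0=T0, neuron_id=neuron_id)
    return SimulatedRecording(
        recording=recording, neuron=neuron, threshold_times=t_stars,
        delays=delays, spontaneous_times=spont, outlier_flags=flags)


def draw_neuron(prior: PriorSpec, rng: np.random.Generator,
                protocol: list[StimulusTrace], delay_rate: float = 1.0,
                outlier_rate: float | None = None, margin_s: float = 1.0,
                max_tries: int = 200) -> GroundTruthNeuron:
    """Draw (D, T, skin) from the priors, rejecting constellations whose
    threshold is not crossed (with a latency margin) under every stimulus."""
    T0 = float(protocol[0].temperatures[0])
    for _ in range(max_tries):
        D_mm = float(prior.sample_depth_um(rng, 1)[0]) * 1e-3
        T_thr = float(prior.sample_threshold(rng, 1)[0])
        k, rho, c = prior.sample_krc(rng, 1)
        skin = SkinParams(float(k[0]), float(rho[0]), float(c[0]))
        if not (T0 + 1.0 < T_thr):
            continue
        neuron = GroundTruthNeuron(D_true=D_mm, T_threshold_true=T_thr,
                                   skin=skin, delay_rate=delay_rate,
                                   outlier_rate=outlier_rate)
        crossings = [threshold_time(T_thr, T0, neuron.gamma_true, tr)
                     for tr in protocol]
        if all(np.isfinite(t) and t <= tr.duration - margin_s
               for t, tr in zip(crossings, protocol)):
            return neuron
    raise RuntimeError("could not draw a responsive neuron from the priors")


def simulate_cohort(n_neurons: int, neuron_prior: PriorSpec = DEFAULT_PRIOR,
                    outlier_fraction: float = 0.0, seed: int = 0,
                    protocol: list[StimulusTrace] | None = None,
                    delay_rate: float = 1.0,
                    outlier_rate: float = 1.0) -> list[SimulatedRecording]:
    """Simulate a cohort of neurons drawn from the priors.

    Each neuron independently receives an active spontaneous-outlier process
    with probability ``outlier_fraction``.  Reproducible given ``seed``.
    """
    if not (0.0 <= outlier_fraction <= 1.0):
        raise ValueError("outlier_fraction must be in [0, 1]")
    if protocol is None:
        protocol = make_protocol()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_neurons):
        has_outlier = bool(rng.random() < outlier_fraction)
        neuron = draw_neuron(neuron_prior, rng, protocol,
                             delay_rate=delay_rate,
                             outlier_rate=outlier_rate if has_outlier else None)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        out.append(simulate_recording(neuron, protocol, seed=sim_seed,
                                      neuron_id=f"sim-{i:03d}"))
    return out


def inject_outlier(sim: SimulatedRecording, index: int, seed: int,
                   rate: float = 1.0) -> SimulatedRecording:
    """Replace one latency with a spontaneous-process draw (ground truth kept).

    Useful for controlled outlier-detection studies: the replacement is an
    Exponential(rate) spike time truncated to the trace support.
    """
    if sim.recording is None:
        raise ValueError("cannot inject an outlier into a non-responsive recording")
    rng = np.random.default_rng(seed)
    trace = sim.recording.traces[index]
    for _ in range(1000):
        s = rng.exponential(1.0 / rate)
        if 0.0 < s <= trace.duration:
            break
    latencies = sim.recording.latencies.copy()
    latencies[index] = s
    flags = sim.outlier_flags.copy()
    flags[index] = True
    spont = sim.spontaneous_times.copy()
    spont[index] = s
    recording = Recording(traces=sim.recording.traces, latencies=latencies,
                          T0=sim.recording.T0,
                          neuron_id=sim.recording.neuron_id + "+outlier")
    return replace(sim, recording=recording, outlier_flags=flags,
                   spontaneous_times=spont)
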