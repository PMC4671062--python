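import numpy as np
import pytest

from nocidepth import (
    MIDPOINT_SKIN,
    Recording,
    StimulusTrace,
    gamma_from_depth,
    make_protocol,
    threshold_time,
)
from nocidepth.priors import DEFAULT_PRIOR, PriorContext
from nocidepth.simulate import draw_neuron, simulate_recording


@pytest.fixture(scope="session")
def alpha_mid() -> float:
    return MIDPOINT_SKIN.alpha_eff()


@pytest.fixture(scope="session")
def protocol():
    return make_protocol()


def build_step_recording(D_mm: float, T_threshold: float, alpha_eff: float,
                         step_temps=(43.0, 45.0, 47.0, 49.0), T0: float = 32.0,
                         duration: float = 30.0):
    """Noise-free recording from constant (step) surface stimuli: latencies
    are the exact threshold-crossing times of the forward model."""
    gamma = gamma_from_depth(D_mm, alpha_eff)
    traces = tuple(StimulusTrace.step(T0, Ts, duration) for Ts in step_temps)
    latencies = np.array([threshold_time(T_threshold, T0, gamma, tr)
                          for tr in traces])
    rec = Recording(traces=traces, latencies=latencies, T0=T0,
                    neuron_id="step-sim")
    return rec, gamma


@pytest.fixture(scope="session")
def fig_recording(alpha_mid):
    """The worked example: receptor at 0.3 mm depth, 38.8 degC threshold,
    probed with four supra-threshold step stimuli."""
    return build_step_recording(0.3, 38.8, alpha_mid)


@pytest.fixture(scope="session")
def noise_free_sims(protocol):
    """Ten prior-drawn neurons simulated in the zero-delay limit."""
    rng = np.random.default_rng(2024)
    sims = []
    for _ in range(10):
        neuron = draw_neuron(DEFAULT_PRIOR, rng, protocol, delay_rate=np.inf)
        sims.append(simulate_recording(neuron, protocol,
                                       seed=int(rng.integers(2**31 - 1))))
    return sims


@pytest.fixture(scope="session")
def prior_ctx():
    return PriorContext.from_spec(DEFAULT_PRIOR, seed=0)
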