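"""Forward thermal model: erfc attenuation, crossing times, PDE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.special import erfc

from nocidepth.thermal import (
    NEVER,
    ConfigurationError,
    StimulusTrace,
    ThermalDomainError,
    TraceRangeError,
    alpha_from_krc,
    attenuated_temperature,
    depth_from_gamma,
    effective_diffusivity,
    gamma_from_depth,
    pde_oracle,
    surface_temp_at,
    threshold_time,
    threshold_times_paired,
)


class TestAttenuatedTemperature:
    def test_zero_depth_returns_surface(self):
        assert attenuated_temperature(48.0, 32.0, 0.0, 1.0) == pytest.approx(48.0)

    def test_infinite_depth_returns_baseline(self):
        assert attenuated_temperature(48.0, 32.0, 100.0, 1.0) == pytest.approx(
            32.0, abs=1e-9)

    def test_half_attenuation_at_erfc_inverse(self):
        # independent inversion of erfc with a root finder: erfc(g*) = 0.5
        g_star = brentq(lambda g: erfc(g) - 0.5, 0.0, 3.0, xtol=1e-14)
        assert attenuated_temperature(48.0, 32.0, g_star, 1.0) == pytest.approx(
            40.0, abs=1e-10)

    @pytest.mark.parametrize("bad_t, bad_g", [(0.0, 0.1), (-1.0, 0.1), (1.0, -0.1)])
    def test_domain_errors(self, bad_t, bad_g):
        with pytest.raises(ThermalDomainError):
            attenuated_temperature(48.0, 32.0, bad_g, bad_t)

    # argument ranges keep erfc well above float underflow so that strict
    # ordering is meaningful numerically
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(g1=st.floats(0.0, 1.5), dg=st.floats(1e-3, 1.0),
           t=st.floats(0.5, 30.0))
    def test_strictly_decreasing_in_gamma(self, g1, dg, t):
        hot = attenuated_temperature(48.0, 32.0, g1, t)
        deeper = attenuated_temperature(48.0, 32.0, g1 + dg, t)
        assert deeper < hot

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(g=st.floats(1e-2, 1.5), t1=st.floats(0.5, 20.0),
           dt=st.floats(1e-2, 20.0))
    def test_strictly_increasing_in_time(self, g, t1, dt):
        assert attenuated_temperature(48.0, 32.0, g, t1 + dt) \
            > attenuated_temperature(48.0, 32.0, g, t1)


class TestSurfaceTrace:
    def test_linear_ramp_interpolation(self):
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 16.0, 10.0)
        assert surface_temp_at(tr, 0.0) == pytest.approx(32.0)
        assert surface_temp_at(tr, 16.0) == pytest.approx(48.0)
        assert surface_temp_at(tr, 8.0) == pytest.approx(40.0)

    def test_out_of_range_time_raises(self):
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 16.0, 10.0)
        with pytest.raises(TraceRangeError):
            surface_temp_at(tr, 30.0)

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            StimulusTrace(times=np.array([1.0, 2.0]),
                          temperatures=np.array([32.0, 48.0]))
        with pytest.raises(ValueError):
            StimulusTrace(times=np.array([0.0, 2.0, 1.0]),
                          temperatures=np.array([32.0, 40.0, 48.0]))
        with pytest.raises(ValueError):
            StimulusTrace(times=np.array([0.0, 1.0]),
                          temperatures=np.array([32.0, 120.0]))


class TestThresholdTime:
    def test_step_stimulus_closed_form(self):
        # for a constant surface temperature T_s the crossing time is
        # t* = (gamma/u)^2 with erfc(u) = (T_thr - T0)/(T_s - T0)
        T0, Ts, T_thr, gamma = 32.0, 48.0, 40.0, 0.3
        u = brentq(lambda x: erfc(x) - (T_thr - T0) / (Ts - T0), 0.0, 5.0,
                   xtol=1e-14)
        expected = (gamma / u) ** 2
        tr = StimulusTrace.step(T0, Ts, 30.0)
        got = threshold_time(T_thr, T0, gamma, tr)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_surface_neuron_fires_at_step_onset(self):
        tr = StimulusTrace.step(32.0, 48.0, 30.0)
        assert threshold_time(32.1, 32.0, 0.0, tr) <= tr.times[1]

    def test_never_crossed_sentinel(self):
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 2.0, 1.0)
        assert threshold_time(47.9, 32.0, 2.0, tr) == NEVER

    def test_threshold_below_baseline_rejected(self):
        tr = StimulusTrace.step(32.0, 48.0, 30.0)
        with pytest.raises(ThermalDomainError):
            threshold_time(31.0, 32.0, 0.1, tr)

    def test_paired_batch_agrees_with_scalar(self):
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 4.0, 10.0)
        gammas = np.array([0.05, 0.3, 0.6, 0.9])
        thresholds = np.array([36.0, 39.0, 41.0, 43.0])
        batch = threshold_times_paired(tr, 32.0, gammas, thresholds)
        scalar = [threshold_time(T, 32.0, g, tr)
                  for g, T in zip(gammas, thresholds)]
        np.testing.assert_allclose(batch, scalar, atol=5e-3)

    def test_ramp_crossing_matches_pde_oracle(self, alpha_mid):
        # shallow receptor on the 16 s ramp: quasi-static crossing time
        # agrees with the full diffusion solution to 2 %
        gamma, T_thr = 0.05, 40.0
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 16.0, 10.0)
        depth_mm = depth_from_gamma(gamma, alpha_mid)
        times = np.linspace(0.1, 16.0, 320)
        field = pde_oracle(tr, alpha_mid, [depth_mm], times,
                           convention="standard")
        t_cross = float(np.interp(T_thr, field[:, 0], times))
        t_quasi = threshold_time(T_thr, 32.0, gamma, tr)
        assert t_quasi == pytest.approx(t_cross, rel=0.02)


class TestPDEOracle:
    def test_step_matches_analytic_erfc(self, alpha_mid):
        # semi-infinite solid with a constant boundary: exact solution is
        # T0 + (Ts - T0) erfc(x / (2 sqrt(alpha t)))
        T0, Ts = 32.0, 48.0
        tr = StimulusTrace.step(T0, Ts, 10.0)
        depths_mm = np.array([0.1, 0.3, 0.6])
        times = np.array([0.5, 2.0, 5.0])
        field = pde_oracle(tr, alpha_mid, depths_mm, times,
                          convention="standard", nx=600)
        x = depths_mm * 1e-3
        for i, t in enumerate(times):
            exact = T0 + (Ts - T0) * erfc(x / (2 * np.sqrt(alpha_mid * t)))
            rel = np.abs(field[i] - exact) / (Ts - T0)
            assert np.max(rel) < 0.01

    def test_boundary_is_trace_exactly(self, alpha_mid):
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 4.0, 2.0)
        times = np.array([1.0, 3.0, 5.0])
        field = pde_oracle(tr, alpha_mid, [0.0], times, convention="standard")
        np.testing.assert_allclose(field[:, 0], surface_temp_at(tr, times),
                                   atol=0.05)

    def test_interior_approaches_steady_state(self, alpha_mid):
        tr = StimulusTrace.step(32.0, 48.0, 60.0)
        times = np.array([5.0, 20.0, 60.0])
        field = pde_oracle(tr, alpha_mid, [0.2], times, convention="standard")
        assert np.all(np.diff(field[:, 0]) > 0)
        assert field[-1, 0] > 46.0

    def test_unstable_step_size_rejected(self, alpha_mid):
        tr = StimulusTrace.step(32.0, 48.0, 10.0)
        with pytest.raises(ConfigurationError):
            pde_oracle(tr, alpha_mid, [0.3], [1.0], convention="standard",
                       nx=400, dt=10.0)

    def test_quasi_static_error_bound_on_ramp(self, alpha_mid):
        # documented accuracy of the quasi-static evaluation on the 16 s
        # ramp protocol (error relative to the instantaneous temperature
        # rise, t >= 2 s): <= 5 % for shallow receptors (gamma <= 0.05
        # s^1/2) and growing roughly linearly with gamma thereafter
        tr = StimulusTrace.ramp_hold(32.0, 48.0, 16.0, 10.0)
        times = np.linspace(2.0, 26.0, 60)

        def max_rel(gamma):
            depth_mm = depth_from_gamma(gamma, alpha_mid)
            field = pde_oracle(tr, alpha_mid, [depth_mm], times,
                               convention="standard")
            quasi = attenuated_temperature(
                surface_temp_at(tr, times), 32.0,
                np.full(len(times), gamma), times)
            return float(np.max(np.abs(field[:, 0] - quasi) / (quasi - 32.0)))

        assert max_rel(0.02) < 0.05
        assert max_rel(0.05) < 0.05
        assert max_rel(0.2) < 0.20  # documented growth with depth


class TestDiffusivityConventions:
    def test_identity_and_examples(self):
        assert alpha_from_krc(1.0, 1.0, 1.0, "paper_sqrt") == pytest.approx(1.0)
        std = alpha_from_krc(0.09, 1150.0, 800.0, "standard")
        assert std == pytest.approx(0.09 / (1150 * 800), rel=1e-12)
        assert std == pytest.approx(9.78e-8, rel=1e-3)
        assert alpha_from_krc(0.09, 1150.0, 800.0, "paper_sqrt") \
            == pytest.approx(np.sqrt(std), rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ThermalDomainError):
            alpha_from_krc(0.0, 1150.0, 800.0)
        with pytest.raises(ConfigurationError):
            alpha_from_krc(0.09, 1150.0, 800.0, convention="bogus")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(D=st.floats(0.0, 5.0),
           convention=st.sampled_from(["paper_sqrt", "standard"]))
    def test_depth_gamma_roundtrip(self, D, convention):
        alpha = alpha_from_krc(0.095, 1158.0, 825.0, convention)
        a_eff = effective_diffusivity(alpha, convention)
        assert depth_from_gamma(gamma_from_depth(D, a_eff), a_eff) \
            == pytest.approx(D, abs=1e-12)

    def test_effective_diffusivity_is_convention_invariant(self):
        k, rho, c = 0.12, 1180.0, 900.0
        a1 = effective_diffusivity(alpha_from_krc(k, rho, c, "standard"),
                                   "standard")
        a2 = effective_diffusivity(alpha_from_krc(k, rho, c, "paper_sqrt"),
                                   "paper_sqrt")
        assert a1 == pytest.approx(a2, rel=1e-12)
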