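"""Prior densities, Monte-Carlo depth conversion, gamma-prior mixture."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.optimize import brentq

from nocidepth.priors import (
    DEFAULT_PRIOR,
    GammaPriorMixture,
    PriorSpec,
    alternative_prior_specs,
    compose_two_layer_gamma,
    fit_gamma_prior,
    fit_mixture,
    gamma_samples,
    monte_carlo_depth,
    sample_skin_params,
    two_layer_depth,
)


class TestSampling:
    def test_reproducible_and_in_range(self):
        a = sample_skin_params(DEFAULT_PRIOR, 50, seed=3)
        b = sample_skin_params(DEFAULT_PRIOR, 50, seed=3)
        assert all(x.k == y.k and x.rho == y.rho and x.c == y.c
                   for x, y in zip(a, b))
        for s in a:
            assert 0.05 <= s.k <= 0.14
            assert 1116 <= s.rho <= 1200
            assert 700 <= s.c <= 950

    def test_degenerate_prior_gives_constant_samples(self):
        spec = PriorSpec(k_range=(0.1, 0.1), rho_range=(1150.0, 1150.0),
                         c_range=(800.0, 800.0))
        samples = sample_skin_params(spec, 10, seed=0)
        assert all(s.k == 0.1 and s.rho == 1150.0 and s.c == 800.0
                   for s in samples)

    def test_sample_means_near_range_midpoints(self):
        n = 100_000
        samples = sample_skin_params(DEFAULT_PRIOR, n, seed=1)
        ks = np.array([s.k for s in samples])
        half_width = (0.14 - 0.05) / 2
        se = half_width / np.sqrt(3) / np.sqrt(n)
        assert abs(ks.mean() - 0.095) < 3 * se


class TestDepthPrior:
    def test_density_proper_and_shaped(self):
        for name, spec in alternative_prior_specs().items():
            mass, _ = integrate.quad(spec.depth_pdf, 0.0, 5000.0, limit=200)
            assert mass == pytest.approx(1.0, abs=1e-6), name
        # Beta(4.75, 2.25): mode at 0.75 * D_max, heavier tail toward zero
        spec = DEFAULT_PRIOR
        grid = np.linspace(1.0, spec.D_max_um - 1.0, 4001)
        pdf = spec.depth_pdf(grid)
        assert grid[np.argmax(pdf)] == pytest.approx(0.75 * spec.D_max_um,
                                                     rel=0.01)
        assert spec.depth_dist().mean() < 0.75 * spec.D_max_um

    def test_threshold_prior_proper(self):
        mass, _ = integrate.quad(DEFAULT_PRIOR.threshold_pdf, 0.0, 100.0)
        assert mass == pytest.approx(1.0, abs=1e-6)


class TestMonteCarloDepth:
    def test_zero_gamma_is_zero_depth(self):
        assert monte_carlo_depth(0.0, DEFAULT_PRIOR, n=1000, seed=0) == 0.0

    def test_point_mass_prior_is_exact(self):
        spec = PriorSpec(k_range=(0.1, 0.1), rho_range=(1150.0, 1150.0),
                         c_range=(800.0, 800.0))
        expected = 2 * 0.5 * np.sqrt(0.1 / (1150 * 800)) * 1e3
        assert monte_carlo_depth(0.5, spec, n=100, seed=0) \
            == pytest.approx(expected, rel=1e-12)

    def test_linear_in_gamma(self):
        d1 = monte_carlo_depth(0.4, DEFAULT_PRIOR, n=20_000, seed=5)
        d2 = monte_carlo_depth(0.8, DEFAULT_PRIOR, n=20_000, seed=5)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_self_consistent_across_sample_sizes(self):
        coarse = monte_carlo_depth(0.5, DEFAULT_PRIOR, n=10_000, seed=2)
        fine = monte_carlo_depth(0.5, DEFAULT_PRIOR, n=1_000_000, seed=3)
        # Monte-Carlo standard error of the coarse estimate
        rng = np.random.default_rng(2)
        k, rho, c = DEFAULT_PRIOR.sample_krc(rng, 10_000)
        draws = 2 * 0.5 * np.sqrt(k / (rho * c)) * 1e3
        se = draws.std() / np.sqrt(len(draws))
        assert abs(coarse - fine) < 4 * se


class TestTwoLayerComposition:
    A_E = 8.0e-8  # epidermal diffusivity, m^2/s
    A_D = 1.2e-7  # dermal diffusivity, m^2/s

    def test_shallow_gamma_stays_single_layer(self):
        gamma_small = 0.05e-3 / (2 * np.sqrt(self.A_E))  # 0.05 mm deep
        assert compose_two_layer_gamma(gamma_small, 0.1, self.A_E, self.A_D,
                                       convention="standard") == 0.0
        assert two_layer_depth(gamma_small, 0.1, self.A_E, self.A_D,
                               convention="standard") \
            == pytest.approx(0.05, rel=1e-9)

    def test_homogeneous_limit_reduces_to_single_layer(self):
        gamma = 0.6
        total = two_layer_depth(gamma, 0.1, self.A_E, self.A_E,
                                convention="standard")
        single = 2 * gamma * np.sqrt(self.A_E) * 1e3
        assert total == pytest.approx(single, rel=1e-12)

    def test_matches_root_finder_oracle(self):
        gamma, D_e = 0.9, 0.1

        def residual(D_d_mm):
            return (D_e * 1e-3 / (2 * np.sqrt(self.A_E))
                    + D_d_mm * 1e-3 / (2 * np.sqrt(self.A_D)) - gamma)

        oracle = brentq(residual, 0.0, 10.0, xtol=1e-12)
        got = compose_two_layer_gamma(gamma, D_e, self.A_E, self.A_D,
                                      convention="standard")
        assert got == pytest.approx(oracle, rel=1e-9)


class TestGammaPriorMixture:
    def test_bic_selects_one_component_for_gaussian_data(self):
        rng = np.random.default_rng(11)
        samples = rng.normal(0.5, 0.05, size=4000)
        mix = fit_mixture(samples, seed=0)
        assert mix.meta["n_components_bic"] == 1

    def test_fitted_mixture_is_proper_and_matches_moments(self):
        mix = fit_gamma_prior(DEFAULT_PRIOR, n_samples=20_000, seed=4)
        mass, _ = integrate.quad(mix.pdf, -2.0, 5.0, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-6)
        samples = gamma_samples(DEFAULT_PRIOR, 20_000, 4)
        se = samples.std() / np.sqrt(len(samples))
        assert abs(mix.mean() - samples.mean()) < 3 * se

    def test_forced_component_count_and_serialization(self):
        mix = fit_gamma_prior(DEFAULT_PRIOR, n_samples=5_000, seed=0, force_k=3)
        assert mix.n_components == 3
        back = GammaPriorMixture.from_json(mix.to_json())
        np.testing.assert_allclose(back.weights, mix.weights)
        np.testing.assert_allclose(back.means, mix.means)
        np.testing.assert_allclose(back.sds, mix.sds)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            GammaPriorMixture(weights=np.array([0.5, 0.4]),
                              means=np.array([0.1, 0.2]),
                              sds=np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            fit_gamma_prior(DEFAULT_PRIOR, n_samples=100)
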