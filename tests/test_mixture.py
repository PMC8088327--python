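"""Mixture likelihood and EM engine."""

import math

import numpy as np
import pytest
from scipy.stats import norm, t as student_t

from conftest import make_dataset
from ivmix.exceptions import EmptyClusterError, IvmixError
from ivmix.mixture import (
    EMPTY_CLUSTER_TOL,
    JunkComponent,
    MixtureParams,
    component_log_density,
    e_step,
    fit_em_multistart,
    fit_em_single_start,
    initialize_parameters,
    junk_component_params,
    m_step,
    mixture_log_likelihood,
)


class TestJunkComponent:
    def test_direct_arithmetic(self):
        j = junk_component_params(np.array([-1.0, 0.0, 2.0]), np.array([0.1, 0.2, 0.3]))
        assert j.mu == pytest.approx(1 / 3)
        assert j.psi == pytest.approx(3.6)
        assert j.nu == 4

    def test_single_observation(self):
        j = junk_component_params(np.array([0.5]), np.array([0.2]))
        assert (j.mu, j.psi) == (0.5, pytest.approx(0.4))

    def test_degenerate_range(self):
        j = junk_component_params(np.full(4, 2.5), np.array([0.1, 0.3, 0.2, 0.05]))
        assert j.mu == 2.5
        assert j.psi == pytest.approx(0.6)

    def test_empty_input_rejected(self):
        with pytest.raises(IvmixError):
            junk_component_params(np.array([]), np.array([]))

    def test_log_density_matches_scipy_location_scale_t(self):
        j = JunkComponent(mu=0.3, psi=2.1, nu=4.0)
        x = np.linspace(-10, 10, 25)
        np.testing.assert_allclose(
            j.log_density(x),
            student_t.logpdf(x, df=4, loc=0.3, scale=2.1),
            atol=1e-12,
        )


class TestComponentLogDensity:
    def test_standard_normal_at_mode(self):
        assert component_log_density(0.0, "null", sigma_j=1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_t4_density_at_mode(self):
        # standard t4 density at 0 is Gamma(2.5)/(sqrt(4 pi) Gamma(2)) = 0.375
        j = JunkComponent(mu=1.0, psi=2.0, nu=4.0)
        assert component_log_density(1.0, "junk", junk=j) == pytest.approx(
            math.log(0.375 / 2.0)
        )

    def test_junk_density_symmetric_about_mu(self):
        j = JunkComponent(mu=-0.7, psi=1.3, nu=4.0)
        for c in (0.1, 1.0, 7.5):
            assert component_log_density(-0.7 + c, "junk", junk=j) == pytest.approx(
                component_log_density(-0.7 - c, "junk", junk=j)
            )

    def test_substantive_mean_is_used(self):
        got = component_log_density(0.9, 0.5, sigma_j=0.2)
        assert got == pytest.approx(norm.logpdf(0.9, 0.5, 0.2))

    def test_non_finite_x_rejected(self):
        with pytest.raises(IvmixError):
            component_log_density(math.inf, "null", sigma_j=1.0)


def _params(means, props, junk):
    return MixtureParams(
        cluster_means=np.asarray(means, float),
        proportions=np.asarray(props, float),
        junk=junk,
    )


class TestLogLikelihood:
    def test_single_component_reduction(self):
        data = make_dataset([0.3], 0.2)
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        params = _params([], [1.0, 0.0], junk)
        assert mixture_log_likelihood(data, params) == pytest.approx(
            norm.logpdf(0.3, 0.0, 0.2)
        )

    def test_additivity_over_observations(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 1, 6)
        sigma = rng.uniform(0.1, 0.5, 6)
        junk = junk_component_params(theta, sigma)
        params = _params([0.5], [0.3, 0.5, 0.2], junk)
        total = mixture_log_likelihood(make_dataset(theta, sigma), params)
        parts = sum(
            mixture_log_likelihood(make_dataset([t], [s]), params)
            for t, s in zip(theta, sigma)
        )
        assert total == pytest.approx(parts, abs=1e-10)

    def test_matches_term_by_term_oracle(self):
        """Direct densities summed without log-sum-exp, K=2 on 5 points."""
        theta = np.array([-0.9, -0.1, 0.05, 0.6, 2.4])
        sigma = np.array([0.2, 0.1, 0.15, 0.25, 0.3])
        data = make_dataset(theta, sigma)
        junk = junk_component_params(theta, sigma)
        means = [-0.8, 0.7]
        props = [0.25, 0.2, 0.35, 0.2]
        params = _params(means, props, junk)
        oracle = 0.0
        for t_j, s_j in zip(theta, sigma):
            mix = props[0] * norm.pdf(t_j, 0.0, s_j)
            mix += props[1] * norm.pdf(t_j, means[0], s_j)
            mix += props[2] * norm.pdf(t_j, means[1], s_j)
            mix += props[3] * student_t.pdf(t_j, df=4, loc=junk.mu, scale=junk.psi)
            oracle += math.log(mix)
        assert mixture_log_likelihood(data, params) == pytest.approx(oracle, abs=1e-10)

    def test_bad_proportions_rejected(self):
        data = make_dataset([0.3], 0.2)
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        with pytest.raises(IvmixError, match="sum to 1"):
            _params([], [0.9, 0.2], junk)


class TestInitialization:
    def test_kmeans_recovers_separated_centres(self, rng):
        theta = np.r_[rng.normal(-5, 0.1, 10), rng.normal(5, 0.1, 10)]
        data = make_dataset(theta, 0.1)
        params = initialize_parameters(data, 2, rng)
        assert abs(params.cluster_means[0] + 5) < 0.2
        assert abs(params.cluster_means[1] - 5) < 0.2

    def test_null_plus_junk_mass_in_documented_range(self, rng):
        data = make_dataset(rng.normal(0, 1, 30), 0.2)
        for _ in range(50):
            params = initialize_parameters(data, 2, rng)
            mass = params.proportions[0] + params.proportions[-1]
            assert 0.1 < mass < 0.8

    @pytest.mark.parametrize("K", [0, 1, 3])
    def test_proportions_normalized(self, rng, K):
        data = make_dataset(rng.normal(0, 1, 20), 0.2)
        params = initialize_parameters(data, K, rng)
        assert params.proportions.sum() == pytest.approx(1.0, abs=1e-10)
        assert params.K == K

    def test_k_larger_than_j_rejected(self, rng):
        data = make_dataset([0.1, 0.2], 0.1)
        with pytest.raises(IvmixError):
            initialize_parameters(data, 3, rng)


class TestESteps:
    def test_rows_sum_to_one(self, rng):
        data = make_dataset(rng.normal(0, 2, 40), rng.uniform(0.05, 0.5, 40))
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        params = _params([-1.0, 1.5], [0.2, 0.3, 0.3, 0.2], junk)
        resp = e_step(data, params)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)

    def test_point_at_cluster_mean_with_tiny_se_is_certain(self):
        theta = np.array([1.0, 0.0])
        sigma = np.array([1e-6, 0.1])
        data = make_dataset(theta, sigma)
        junk = junk_component_params(theta, sigma)
        params = _params([1.0], [0.3, 0.4, 0.3], junk)
        resp = e_step(data, params)
        assert resp[0, 1] > 0.999

    def test_duplicate_components_share_responsibility(self, rng):
        data = make_dataset(rng.normal(0.5, 0.3, 15), 0.2)
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        params = _params([0.5, 0.5], [0.2, 0.3, 0.3, 0.2], junk)
        resp = e_step(data, params)
        np.testing.assert_allclose(resp[:, 1], resp[:, 2], atol=1e-12)


class TestMStep:
    def test_unweighted_mean_with_equal_ses(self):
        data = make_dataset([0.4, 0.6], 0.1)
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        resp = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        params, empty = m_step(data, resp, junk)
        assert params.cluster_means[0] == pytest.approx(0.5)
        assert empty == ()

    def test_ivw_weighting(self):
        data = make_dataset([0.0, 1.0], [0.1, 0.2])
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        resp = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        params, _ = m_step(data, resp, junk)
        assert params.cluster_means[0] == pytest.approx((0 * 100 + 1 * 25) / 125)

    def test_uniform_responsibilities_give_uniform_proportions(self, rng):
        K = 2
        data = make_dataset(rng.normal(0, 1, 12), 0.2)
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        resp = np.full((12, K + 2), 1.0 / (K + 2))
        params, _ = m_step(data, resp, junk)
        np.testing.assert_allclose(params.proportions, 1.0 / (K + 2), atol=1e-12)

    def test_empty_cluster_keeps_previous_mean_or_raises(self):
        data = make_dataset([0.4, 0.6], 0.1)
        junk = junk_component_params(data.theta_hat, data.sigma_hat)
        resp = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert resp[:, 1].sum() < EMPTY_CLUSTER_TOL
        with pytest.raises(EmptyClusterError):
            m_step(data, resp, junk)
        params, empty = m_step(data, resp, junk, prev_means=np.array([0.33]))
        assert params.cluster_means[0] == 0.33
        assert empty == (1,)


class TestEMFitting:
    def test_loglik_history_is_non_decreasing(self, rng, two_cluster_data):
        init = initialize_parameters(two_cluster_data, 2, rng)
        fit = fit_em_single_start(two_cluster_data, 2, init)
        assert np.all(np.diff(fit.log_likelihood_history) >= -1e-8)

    def test_recovers_well_separated_clusters(self, rng, two_cluster_data):
        init = initialize_parameters(two_cluster_data, 2, rng)
        fit = fit_em_single_start(two_cluster_data, 2, init)
        assert abs(fit.params.cluster_means[0] + 1) < 0.05
        assert abs(fit.params.cluster_means[1] - 1) < 0.05

    def test_infinite_delta_stops_after_one_iteration_pair(self, rng, two_cluster_data):
        init = initialize_parameters(two_cluster_data, 2, rng)
        fit = fit_em_single_start(two_cluster_data, 2, init, delta=math.inf)
        assert fit.converged and fit.n_iterations == 1

    def test_final_states_are_consistent(self, rng, two_cluster_data):
        """Stored log-likelihood and responsibilities match the parameters."""
        fit = fit_em_multistart(two_cluster_data, 2, n_starts=5, seed=11)
        assert mixture_log_likelihood(two_cluster_data, fit.params) == pytest.approx(
            fit.log_likelihood, abs=1e-8
        )
        np.testing.assert_allclose(
            e_step(two_cluster_data, fit.params), fit.responsibilities, atol=1e-10
        )
        assert np.all(np.diff(fit.params.cluster_means) >= 0)
        assert fit.params.proportions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_ivw_limit_with_tiny_ses(self):
        """With near-zero SEs at the exact means, EM reaches the per-group IVW."""
        rng = np.random.default_rng(5)
        theta = np.r_[np.full(10, -1.0), np.full(10, 1.0)]
        sigma = rng.uniform(1e-4, 2e-4, 20)
        data = make_dataset(theta, sigma)
        fit = fit_em_multistart(data, 2, n_starts=5, seed=3)
        w = sigma**-2
        ivw_lo = np.sum(theta[:10] * w[:10]) / np.sum(w[:10])
        ivw_hi = np.sum(theta[10:] * w[10:]) / np.sum(w[10:])
        np.testing.assert_allclose(
            fit.params.cluster_means, [ivw_lo, ivw_hi], atol=1e-6
        )

    def test_multistart_determinism_and_max_contract(self, two_cluster_data):
        f1 = fit_em_multistart(two_cluster_data, 2, n_starts=6, seed=99)
        f2 = fit_em_multistart(two_cluster_data, 2, n_starts=6, seed=99)
        np.testing.assert_array_equal(f1.params.cluster_means, f2.params.cluster_means)
        np.testing.assert_array_equal(f1.responsibilities, f2.responsibilities)
        assert f1.log_likelihood == f2.log_likelihood

        # the selected start is at least as good as any single fixed start
        ss = np.random.SeedSequence(99)
        for child in ss.spawn(6):
            rng = np.random.default_rng(child)
            init = initialize_parameters(
                two_cluster_data, 2, rng, junk=f1.params.junk
            )
            single = fit_em_single_start(two_cluster_data, 2, init)
            assert f1.log_likelihood >= single.log_likelihood - 1e-9

    def test_single_start_reduction(self, two_cluster_data):
        multi = fit_em_multistart(two_cluster_data, 2, n_starts=1, seed=42)
        ss = np.random.SeedSequence(42)
        rng = np.random.default_rng(ss.spawn(1)[0])
        init = initialize_parameters(two_cluster_data, 2, rng, junk=multi.params.junk)
        single = fit_em_single_start(two_cluster_data, 2, init)
        assert multi.log_likelihood == single.log_likelihood
        np.testing.assert_array_equal(
            multi.params.cluster_means, single.params.cluster_means
        )
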