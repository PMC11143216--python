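"""Closed-form marginalization: reductions, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tavrisk._math import sigmoid
from tavrisk.core import complete_log_joint
from tavrisk.marginal import (
    MAX_MISSING_BINARY,
    marginal_log_joint,
    mc_marginal_oracle,
    mc_predictive_oracle,
    predictive_outcome,
    sigmoid_gaussian_expectation,
)
from tavrisk.schema import (MissingnessPattern, ModelParams, Observation,
                            PriorParams, TabularSchema)

from conftest import sample_observation


class TestSigmoidGaussianExpectation:
    def test_symmetry_at_zero_mean(self):
        for v in (0.0, 1.0, 10.0, 25.0):
            assert sigmoid_gaussian_expectation(0.0, v) == pytest.approx(0.5)

    def test_degenerate_variance_recovers_sigmoid(self):
        m = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(sigmoid_gaussian_expectation(m, 0.0),
                                   sigmoid(m), atol=1e-14)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_gaussian_expectation(0.0, -1e-9)

    def test_quadrature_agreement_at_moderate_arguments(self):
        """At (1, 4): within 0.01 of the Gauss-Hermite reference."""
        nodes, weights = np.polynomial.hermite.hermgauss(64)
        exact = float((sigmoid(1.0 + np.sqrt(8.0) * nodes) * weights).sum()
                      / np.sqrt(np.pi))
        assert abs(float(sigmoid_gaussian_expectation(1.0, 4.0)) - exact) <= 0.01

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(m=st.floats(-6, 6), v1=st.floats(0, 25), v2=st.floats(0, 25))
    def test_monotone_in_mean_and_shrinks_to_half_with_variance(self, m, v1, v2):
        lo, hi = sorted((v1, v2))
        p_lo = float(sigmoid_gaussian_expectation(m, lo))
        p_hi = float(sigmoid_gaussian_expectation(m, hi))
        # growing variance pulls the probability toward 1/2
        assert abs(p_hi - 0.5) <= abs(p_lo - 0.5) + 1e-12
        # monotone increasing in the mean
        p_m2 = float(sigmoid_gaussian_expectation(m + 0.5, lo))
        assert p_m2 >= p_lo - 1e-12


class TestMarginalLogJoint:
    def test_reduces_to_complete_when_nothing_missing(self, small_schema,
                                                      small_instance):
        params, prior = small_instance
        rng = np.random.default_rng(7)
        for _ in range(10):
            obs = sample_observation(rng, params, prior)
            assert marginal_log_joint(obs, params, prior, small_schema) == \
                pytest.approx(complete_log_joint(obs, params, prior,
                                                 small_schema), abs=1e-10)

    def test_single_missing_binary_is_rate_weighted_sum(self, small_schema,
                                                        small_instance):
        params, prior = small_instance
        rng = np.random.default_rng(8)
        obs = sample_observation(rng, params, prior, a_mask=(1, 1, 0, 1))
        parts = []
        for v in (0.0, 1.0):
            a = obs.a.copy()
            a[2] = v
            o = Observation(a, np.ones(4, bool), obs.j, obs.j_mask, True,
                            obs.features, obs.y)
            parts.append(complete_log_joint(o, params, prior, small_schema))
        # each complete evaluation already carries its own log p(a_2 = v)
        expect = np.logaddexp(parts[0], parts[1])
        assert marginal_log_joint(obs, params, prior, small_schema) == \
            pytest.approx(expect, abs=1e-10)

    def test_missing_outcome_directs_to_predictive(self, small_schema,
                                                   small_instance):
        params, prior = small_instance
        obs = sample_observation(np.random.default_rng(9), params, prior)
        obs.y = None
        with pytest.raises(ValueError, match="predictive_outcome"):
            marginal_log_joint(obs, params, prior, small_schema)

    def test_enumeration_limit_enforced(self):
        d = MAX_MISSING_BINARY + 2
        schema = TabularSchema(tuple(f"b{i}" for i in range(d)),
                               ("binary",) * d)
        params = ModelParams(beta=np.zeros((d, 2)), sigma_I=1.0,
                             phi=np.zeros((2, 1)), sigma_J=1.0,
                             alpha_I=np.zeros(2), alpha_A=np.zeros(d), b_Y=0.0)
        prior = PriorParams(mean=np.full(d, np.nan), var=np.full(d, np.nan),
                            rate=np.full(d, 0.5))
        obs = Observation(a=np.full(d, np.nan), a_mask=np.zeros(d, bool),
                          j=np.zeros(1), j_mask=np.ones(1, bool),
                          image_present=False, y=1)
        with pytest.raises(ValueError, match="enumeration"):
            marginal_log_joint(obs, params, prior, schema)

    def test_permutation_invariance(self, small_instance):
        """Reordering covariate dimensions leaves the marginal unchanged."""
        params, prior = small_instance
        schema = TabularSchema(("age", "bmi", "diabetes", "male"),
                               ("continuous", "continuous", "binary", "binary"))
        rng = np.random.default_rng(10)
        obs = sample_observation(rng, params, prior, a_mask=(0, 1, 0, 1),
                                 j_mask=(1, 0), image=False)
        perm = [1, 0, 3, 2]
        schema_p = TabularSchema(tuple(schema.names[i] for i in perm),
                                 tuple(schema.kinds[i] for i in perm))
        params_p = params.copy()
        params_p.beta = params.beta[perm]
        params_p.alpha_A = params.alpha_A[perm]
        prior_p = PriorParams(prior.mean[perm], prior.var[perm],
                              prior.rate[perm])
        obs_p = Observation(obs.a[perm], obs.a_mask[perm], obs.j, obs.j_mask,
                            obs.image_present, obs.features, obs.y)
        assert marginal_log_joint(obs, params, prior, schema) == \
            pytest.approx(marginal_log_joint(obs_p, params_p, prior_p,
                                             schema_p), abs=1e-12)

    def test_normalizes_when_everything_is_missing(self, small_schema,
                                                   small_instance):
        """Sum over Y of the fully-marginal joint is 1 (probit terms cancel
        exactly in the pair)."""
        params, prior = small_instance
        obs = Observation(a=np.full(4, np.nan), a_mask=np.zeros(4, bool),
                          j=np.full(2, np.nan), j_mask=np.zeros(2, bool),
                          image_present=False, y=1)
        obs0 = Observation(obs.a, obs.a_mask, obs.j, obs.j_mask, False, None, 0)
        total = np.exp(marginal_log_joint(obs, params, prior, small_schema)) \
            + np.exp(marginal_log_joint(obs0, params, prior, small_schema))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("a_mask,j_mask,image", [
        ((0, 1, 1, 1), (1, 1), True),
        ((1, 1, 0, 1), (1, 1), True),
        ((1, 1, 1, 1), (1, 1), False),
        ((1, 1, 1, 1), (1, 0), False),
        ((1, 1, 1, 1), (0, 0), False),
        ((0, 1, 0, 1), (1, 0), False),
    ], ids=["cont_A", "bin_A", "image", "image_partJ", "image_noJ", "mixed"])
    def test_monte_carlo_agreement_per_pattern_class(self, small_schema,
                                                     a_mask, j_mask, image):
        """Closed form within 3 MC stderr + certified closure error of the
        exact-sigmoid Monte-Carlo reference, for every pattern class."""
        from tavrisk.experiments import _oracle_instance

        rng = np.random.default_rng(11)
        fails = 0
        for t in range(12):
            params, prior = _oracle_instance(rng)
            obs = sample_observation(rng, params, prior, a_mask, j_mask, image)
            l1 = marginal_log_joint(obs, params, prior, small_schema)
            flip = Observation(obs.a, obs.a_mask, obs.j, obs.j_mask,
                               obs.image_present, obs.features, 1 - obs.y)
            l0 = marginal_log_joint(flip, params, prior, small_schema)
            closed = np.exp(l1)
            p_obs = np.exp(np.logaddexp(l0, l1))
            mc = mc_marginal_oracle(obs, params, prior, small_schema,
                                    n_samples=60_000, seed=100 + t)
            if abs(closed - mc.estimate) > 3 * mc.stderr + 0.01 * p_obs:
                fails += 1
        assert fails <= 1


class TestPredictiveOutcome:
    def test_zero_image_weight_gives_plain_logistic(self, small_schema,
                                                    small_instance):
        params, prior = small_instance
        p0 = params.copy()
        p0.alpha_I = np.zeros(3)
        obs = sample_observation(np.random.default_rng(12), p0, prior,
                                 image=False)
        assert predictive_outcome(obs, p0, prior, small_schema) == \
            pytest.approx(float(sigmoid(obs.a @ p0.alpha_A + p0.b_Y)),
                          abs=1e-10)

    def test_vanishing_feature_noise_gives_plain_logistic(self, small_schema,
                                                          small_instance):
        params, prior = small_instance
        p0 = params.copy()
        p0.sigma_I = 0.0
        obs = sample_observation(np.random.default_rng(13), params, prior,
                                 image=False)
        assert predictive_outcome(obs, p0, prior, small_schema) == \
            pytest.approx(float(sigmoid(obs.a @ p0.alpha_A + p0.b_Y)),
                          abs=1e-10)

    def test_measurements_do_not_move_prediction_when_image_present(
            self, small_schema, small_instance):
        params, prior = small_instance
        rng = np.random.default_rng(14)
        obs = sample_observation(rng, params, prior)
        p1 = predictive_outcome(obs, params, prior, small_schema)
        o2 = Observation(obs.a, obs.a_mask, obs.j + 5.0, obs.j_mask, True,
                         obs.features, obs.y)
        assert predictive_outcome(o2, params, prior, small_schema) == \
            pytest.approx(p1, abs=1e-12)

    def test_posterior_sampling_oracle_image_missing(self, small_schema):
        """With the image missing and J observed, the prediction matches
        E[sigma(.)] under the Gaussian posterior p(f | A, J)."""
        from tavrisk.experiments import _oracle_instance

        rng = np.random.default_rng(15)
        for t in range(6):
            params, prior = _oracle_instance(rng)
            obs = sample_observation(rng, params, prior, image=False)
            closed = predictive_outcome(obs, params, prior, small_schema)
            mc = mc_predictive_oracle(obs, params, prior, small_schema,
                                      n_samples=120_000, seed=t)
            assert abs(closed - mc.estimate) <= max(3 * mc.stderr, 0.01)

    def test_empty_observation_gives_prior_marginal(self, small_schema,
                                                    small_instance):
        params, prior = small_instance
        obs = Observation(a=np.full(4, np.nan), a_mask=np.zeros(4, bool),
                          j=np.full(2, np.nan), j_mask=np.zeros(2, bool),
                          image_present=False)
        p = predictive_outcome(obs, params, prior, small_schema)
        mc = mc_predictive_oracle(obs, params, prior, small_schema,
                                  n_samples=150_000, seed=0)
        assert 0.0 < p < 1.0
        assert abs(p - mc.estimate) <= max(3 * mc.stderr, 0.01)


class TestMCOracle:
    def test_exact_when_nothing_sampled(self, small_schema, small_instance):
        params, prior = small_instance
        obs = sample_observation(np.random.default_rng(16), params, prior)
        mc = mc_marginal_oracle(obs, params, prior, small_schema, 2000, 0)
        assert mc.stderr == 0.0
        assert mc.log_estimate == pytest.approx(
            marginal_log_joint(obs, params, prior, small_schema))

    def test_stderr_shrinks_like_root_n(self, small_schema, small_instance):
        params, prior = small_instance
        obs = sample_observation(np.random.default_rng(17), params, prior,
                                 a_mask=(0, 1, 1, 1), image=False)
        se1 = mc_marginal_oracle(obs, params, prior, small_schema,
                                 20_000, 5).stderr
        se2 = mc_marginal_oracle(obs, params, prior, small_schema,
                                 80_000, 5).stderr
        assert se2 == pytest.approx(se1 / 2, rel=0.25)

    def test_minimum_sample_size_enforced(self, small_schema, small_instance):
        params, prior = small_instance
        obs = sample_observation(np.random.default_rng(18), params, prior)
        with pytest.raises(ValueError):
            mc_marginal_oracle(obs, params, prior, small_schema, 10, 0)


def test_missingness_pattern_from_observation(small_schema, small_instance):
    params, prior = small_instance
    obs = sample_observation(np.random.default_rng(19), params, prior,
                             a_mask=(0, 1, 0, 1), j_mask=(1, 0), image=False)
    pat = MissingnessPattern.of(obs, small_schema)
    assert pat.missing_cont_a == (0,)
    assert pat.missing_bin_a == (2,)
    assert pat.missing_j == (1,)
    assert pat.image_missing
    assert not pat.empty
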