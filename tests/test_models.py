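"""Covariance structures, structural equations, priors, log posterior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import psi

from abnma.models import (
    ModelSpec,
    ParameterState,
    PriorConfig,
    ch_contrast_cov,
    contrast_variance,
    derived_contrasts,
    diagonal_arm_cov,
    linear_predictor,
    log_posterior,
    model2_ab_arm_cov,
    model4_ch_cov,
    p_matrix,
    rho_lower_bound,
    sample_prior,
    sigma_c_from_arm,
)
from abnma.network import ArmRecord, Network


class TestCovarianceStructures:
    def test_p_matrix(self):
        np.testing.assert_allclose(
            p_matrix(2, 0.5), [[1.0, 0.5], [0.5, 1.0]]
        )
        np.testing.assert_allclose(p_matrix(1, 0.9), [[1.0]])
        np.testing.assert_allclose(p_matrix(3, 0.0), np.eye(3))

    def test_ch_contrast_cov(self):
        np.testing.assert_allclose(
            ch_contrast_cov(0.04, 3), [[0.04, 0.02], [0.02, 0.04]]
        )
        np.testing.assert_allclose(ch_contrast_cov(0.7, 2), [[0.7]])
        with pytest.raises(ValueError):
            ch_contrast_cov(-1.0, 3)

    def test_model2_ab_arm_cov(self):
        np.testing.assert_allclose(
            model2_ab_arm_cov(1.0, 2), [[0.5, 0.0], [0.0, 0.5]]
        )
        np.testing.assert_allclose(model2_ab_arm_cov(0.0, 4), np.zeros((4, 4)))

    def test_model4_ch_cov(self):
        np.testing.assert_allclose(model4_ch_cov(1.0, 1.0, 3), np.ones((3, 3)))
        np.testing.assert_allclose(model4_ch_cov(0.5, 0.0, 3), 0.5 * np.eye(3))
        np.testing.assert_allclose(
            model4_ch_cov(2.0, 0.75, 2), [[2.0, 1.5], [1.5, 2.0]]
        )
        with pytest.raises(ValueError, match="rho_a"):
            model4_ch_cov(1.0, -0.9, 3)

    def test_contrast_variance(self):
        assert contrast_variance(np.diag([3.0, 4.0]), 1, 2) == pytest.approx(7.0)
        assert contrast_variance(np.eye(4), 2, 4) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            contrast_variance(np.eye(2), 1, 1)

    def test_sigma_c_from_arm(self):
        assert sigma_c_from_arm(1.0, 1.0) == 0.0
        assert sigma_c_from_arm(0.5, 0.0) == 1.0
        assert sigma_c_from_arm(2.0, -0.5) == 6.0

    def test_diagonal_form_implies_large_contrast_heterogeneity(self):
        # the rejected diagonal structure forces every contrast variance to
        # exceed each arm variance
        S = diagonal_arm_cov([0.3, 0.5, 0.8], 3)
        for k in range(1, 4):
            for j in range(k + 1, 4):
                assert contrast_variance(S, k, j) > max(S[k - 1, k - 1],
                                                        S[j - 1, j - 1])

    @given(
        st.floats(0.01, 5.0),
        st.floats(-0.1, 0.99),
        st.integers(2, 8),
    )
    @settings(max_examples=100, deadline=None)
    def test_eq13_identity(self, sigma_a2, rho, K):
        """Contrast variance of the compound-symmetry arm covariance equals
        2*sigma_a^2*(1-rho) for every treatment pair."""
        if rho <= rho_lower_bound(K):
            rho = 0.5 * (rho_lower_bound(K) + 1.0)
        S = model4_ch_cov(sigma_a2, rho, K)
        expected = sigma_c_from_arm(sigma_a2, rho)
        for k in range(1, K + 1):
            for j in range(1, K + 1):
                if j != k:
                    assert contrast_variance(S, k, j) == pytest.approx(expected)

    @given(st.floats(0.01, 5.0), st.integers(3, 8))
    @settings(max_examples=50, deadline=None)
    def test_ch_pairwise_variance_constant(self, sigma_c2, K):
        """Every pairwise contrast has the same heterogeneity variance under
        the common-heterogeneity structure (including pairs without the
        reference treatment)."""
        S = ch_contrast_cov(sigma_c2, K)  # covariance of (delta_2..delta_K)
        full = np.zeros((K, K))
        full[1:, 1:] = S  # delta_1 = 0
        for k in range(1, K + 1):
            for j in range(1, K + 1):
                if j != k:
                    assert contrast_variance(full, k, j) == pytest.approx(
                        sigma_c2
                    )
        # AB form of model 2 implies the same contrast variances
        Sa = model2_ab_arm_cov(sigma_c2, K)
        assert contrast_variance(Sa, 1, K) == pytest.approx(sigma_c2)


class TestModelSpec:
    def test_model1_nch_unsupported(self):
        with pytest.raises(ValueError, match="model 1 supports CH only"):
            ModelSpec(model=1, heterogeneity="NCH")

    def test_default_forms(self):
        assert ModelSpec(2).form == "CB"
        assert ModelSpec(4).form == "AB"

    def test_roundtrip_dict(self):
        spec = ModelSpec(4, heterogeneity="NCH",
                         priors=PriorConfig(het_location=-3.0))
        again = ModelSpec.from_dict(spec.to_dict())
        assert again == spec


def _toy_network():
    return Network(
        arms=(
            ArmRecord(1, 1, 3, 20),
            ArmRecord(1, 2, 8, 20),
            ArmRecord(2, 1, 4, 25),
            ArmRecord(2, 3, 9, 25),
        )
    )


class TestLinearPredictor:
    def test_model1_reference_arm_is_intercept(self):
        net = _toy_network()
        state = ParameterState(
            alpha={1: -1.0, 2: -0.5},
            delta={1: {2: 0.7}, 2: {3: 0.4}},
            mu_c=np.array([0.0, 0.5, 0.5]),
            sigma_c2=0.04,
        )
        spec = ModelSpec(1)
        assert linear_predictor(spec, state, net, 1, 1) == -1.0
        assert linear_predictor(spec, state, net, 1, 2) == pytest.approx(-0.3)

    def test_model2_contrast_addition(self):
        net = _toy_network()
        state = ParameterState(
            alpha={1: -1.0, 2: -0.5},
            delta={1: {2: 0.5}, 2: {3: 0.4}},
            mu_c=np.array([0.0, 0.5, 0.5]),
            sigma_c2=0.04,
        )
        assert linear_predictor(
            ModelSpec(2), state, net, 1, 2
        ) == pytest.approx(-0.5)

    def test_unknown_treatment_rejected(self):
        net = _toy_network()
        state = ParameterState(alpha={1: 0.0}, delta={1: {2: 0.0}})
        with pytest.raises(ValueError, match="treatment"):
            linear_predictor(ModelSpec(1), state, net, 1, 9)

    def test_model1_equals_model2_when_reference_observed(self):
        """On studies containing treatment 1, models 1 and 2 give identical
        arm log odds under the identity parameter mapping."""
        net = _toy_network()
        state = ParameterState(
            alpha={1: -1.2, 2: -0.4},
            delta={1: {2: 0.9}, 2: {3: -0.2}},
            mu_c=np.array([0.0, 0.5, 0.3]),
            sigma_c2=0.1,
        )
        for sid in (1, 2):
            for k in net.design_of(sid):
                assert linear_predictor(
                    ModelSpec(1), state, net, sid, k
                ) == pytest.approx(
                    linear_predictor(ModelSpec(2), state, net, sid, k)
                )


class TestLogPosterior:
    def test_binomial_term_is_exact(self):
        """At theta = 0 an arm with y=1, n=2 contributes log C(2,1)*0.25 =
        log(0.5); verified by decomposing the full log posterior."""
        from scipy.stats import norm

        net = Network(
            arms=(ArmRecord(1, 1, 1, 2), ArmRecord(1, 2, 1, 2))
        )
        state = ParameterState(
            alpha={1: 0.0},
            delta={1: {2: 0.0}},
            mu_c=np.array([0.0, 0.0]),
            sigma_c2=0.04,
        )
        spec = ModelSpec(1)
        lp = log_posterior(spec, state, net)
        pr = spec.priors
        non_binomial = (
            norm.logpdf(0.0, 0.0, 0.2)  # delta | mu, sigma_c
            + pr.logp_location([0.0])  # alpha
            + pr.logp_location([0.0])  # mu_c[2]
            + pr.logp_log_sigma_c2(math.log(0.04))
        )
        assert lp - non_binomial == pytest.approx(2 * math.log(0.5), abs=1e-9)

    def test_infinite_theta_gives_minus_inf(self):
        net = _toy_network()
        state = ParameterState(
            alpha={1: np.inf, 2: 0.0},
            delta={1: {2: 0.0}, 2: {3: 0.0}},
            mu_c=np.zeros(3),
            sigma_c2=0.1,
        )
        assert log_posterior(ModelSpec(1), state, net) == -np.inf

    def test_model1_model2_differ_by_constant(self):
        """Describing all possible arms (model 2) instead of observed arms
        (model 1) changes the posterior by a data-independent constant when
        every study contains treatment 1 (here: zero)."""
        net = _toy_network()
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(5):
            alpha = {1: rng.normal(), 2: rng.normal()}
            delta = {1: {2: rng.normal()}, 2: {3: rng.normal()}}
            mu = np.array([0.0, rng.normal(), rng.normal()])
            s2 = float(rng.uniform(0.05, 1.0))
            st1 = ParameterState(alpha=alpha, delta=delta, mu_c=mu, sigma_c2=s2)
            lp1 = log_posterior(ModelSpec(1), st1, net)
            lp2 = log_posterior(ModelSpec(2), st1, net)
            diffs.append(lp2 - lp1)
        assert np.ptp(diffs) < 1e-9

    def test_relabeling_invariance(self):
        """Swapping the labels of two non-reference treatments consistently
        in data and parameters leaves the model 2 posterior unchanged."""
        net = _toy_network()
        swapped = Network(
            arms=tuple(
                ArmRecord(a.study_id, {2: 3, 3: 2}.get(a.treatment_id,
                                                       a.treatment_id),
                          a.events, a.size)
                for a in net.arms
            )
        )
        state = ParameterState(
            alpha={1: -1.0, 2: -0.4},
            delta={1: {2: 0.6}, 2: {3: -0.1}},
            mu_c=np.array([0.0, 0.5, 0.2]),
            sigma_c2=0.3,
        )
        state_sw = ParameterState(
            alpha={1: -1.0, 2: -0.4},
            delta={1: {3: 0.6}, 2: {2: -0.1}},
            mu_c=np.array([0.0, 0.2, 0.5]),
            sigma_c2=0.3,
        )
        spec = ModelSpec(2)
        assert log_posterior(spec, state, net) == pytest.approx(
            log_posterior(spec, state_sw, swapped)
        )

    def test_model4_forms_agree(self):
        """The CB and AB forms of model 4 assign the same density to the
        same arm log-odds configuration (up to the reparameterized latent
        bookkeeping)."""
        net = _toy_network()
        mu_a = np.array([-1.0, -0.6, -0.4])
        theta = {1: {1: -1.1, 2: -0.5}, 2: {1: -0.9, 3: -0.2}}
        st_ab = ParameterState(theta=theta, mu_a=mu_a, sigma_c2=0.4, rho_a=0.5)
        st_cb = ParameterState(
            alpha={1: -1.1, 2: -0.9},
            delta={1: {2: 0.6}, 2: {3: 0.7}},
            mu_a1=-1.0,
            mu_c=np.array([0.0, 0.4, 0.6]),
            sigma_c2=0.4,
            rho_a=0.5,
        )
        lp_ab = log_posterior(ModelSpec(4, form="AB"), st_ab, net)
        lp_cb = log_posterior(ModelSpec(4, form="CB"), st_cb, net)
        # identical theta surface and a unit-Jacobian reparameterization of
        # the latent vector => identical joint density
        assert lp_ab == pytest.approx(lp_cb, abs=1e-9)


class TestDerivedContrasts:
    def test_model4_difference(self):
        spec = ModelSpec(4)
        state = ParameterState(mu_a=np.array([-1.0, -0.5, -0.5]))
        np.testing.assert_allclose(
            derived_contrasts(spec, state), [0.0, 0.5, 0.5]
        )

    def test_location_invariance(self):
        spec = ModelSpec(4)
        mu = np.array([-1.0, -0.2, 0.3, 1.1])
        a = derived_contrasts(spec, ParameterState(mu_a=mu))
        b = derived_contrasts(spec, ParameterState(mu_a=mu + 2.7))
        np.testing.assert_allclose(a, b)

    def test_passthrough_other_models(self):
        spec = ModelSpec(2)
        state = ParameterState(mu_c=np.array([0.0, 0.4, -0.1]))
        np.testing.assert_allclose(
            derived_contrasts(spec, state), [0.0, 0.4, -0.1]
        )


class TestPriors:
    def test_fixed_effect_prior_moments(self):
        frame = sample_prior(ModelSpec(2), 10_000, seed=1, K=3)
        x = frame["mu_c[2]"]
        sd = math.sqrt(1000.0)
        assert abs(x.mean()) < 3 * sd / 100.0
        assert x.std() == pytest.approx(sd, rel=0.05)

    def test_ch_heterogeneity_prior_location(self):
        pr = PriorConfig()
        frame = sample_prior(ModelSpec(2, priors=pr), 10_000, seed=2, K=3)
        logv = np.log(frame["cvar[2,3]"])
        assert logv.mean() == pytest.approx(pr.het_location, abs=0.06)
        assert logv.std() == pytest.approx(pr.het_scale, rel=0.05)

    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec(2, heterogeneity="NCH"),
            ModelSpec(4, heterogeneity="NCH"),
        ],
        ids=["contrast-IW", "arm-IW"],
    )
    def test_nch_prior_matches_ch_log_contrast_variance_mean(self, spec):
        """Moment matching: the inverse-Wishart priors give every pairwise
        log contrast variance the same prior mean as the CH lognormal."""
        pr = spec.priors
        frame = sample_prior(spec, 10_000, seed=3, K=3)
        # exact MC tolerance: log of an inverse-gamma quadratic form has
        # sd sqrt(psi'(1.5)), so the mean of 10k draws has se ~ 0.01
        se = math.sqrt(float(np.pi**2 / 2 - 4)) / math.sqrt(10_000)
        for col in ["cvar[1,2]", "cvar[1,3]", "cvar[2,3]"]:
            assert np.log(frame[col]).mean() == pytest.approx(
                pr.het_location, abs=5 * se + 0.02
            )

    def test_model4_ch_prior_two_heterogeneity_quantities(self):
        """Model 4 CH places separate priors on the contrast and arm
        heterogeneity variances; the implied compound-symmetry correlation
        stays inside its positive-definite interval and satisfies the
        variance identity draw by draw."""
        frame = sample_prior(ModelSpec(4), 5000, seed=4, K=3)
        rho = frame["rho_a"].to_numpy()
        lo = rho_lower_bound(3)
        assert rho.min() > lo and rho.max() < 1.0
        np.testing.assert_allclose(
            frame["cvar[2,3]"],
            2.0 * frame["avar[1]"] * (1.0 - rho),
            rtol=1e-10,
        )
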