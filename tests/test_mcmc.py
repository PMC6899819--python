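"""MCMC engine: correctness against oracles, determinism, diagnostics."""

import math

import numpy as np
import pytest
from scipy.special import expit

from abnma.hypodata import ScenarioSpec, generate
from abnma.mcmc import (
    ChainConfig,
    autocorrelation,
    fit,
    mcse_median,
    posterior_slope,
    summarize,
)
from abnma.models import ModelSpec
from abnma.network import ArmRecord, Network

from conftest import short_chains


class TestFit:
    def test_contrast_posterior_matches_quadrature_oracle(self):
        """Model 1 on a single two-arm study: the posterior of the overall
        mean contrast mu_c[2] has a closed quadrature form — integrate the
        exact binomial likelihood over (alpha, delta, log sigma_c^2) and
        mix the conjugate normal mu | delta, sigma.  The MCMC median must
        agree with the oracle median within Monte Carlo error."""
        from scipy.stats import binom, norm

        net = Network(arms=(ArmRecord(1, 1, 3, 12), ArmRecord(1, 2, 8, 12)))
        spec = ModelSpec(1)
        draws = fit(spec, net, short_chains(seed=101, kept=8000))
        med = summarize(draws, "mu_c[2]").median

        pr = spec.priors
        v0 = pr.fixed_effect_sd**2
        agrid = np.linspace(-10, 8, 721)
        dgrid = np.linspace(-7, 9, 641)
        xgrid = np.linspace(
            pr.het_location - 5 * pr.het_scale,
            pr.het_location + 5 * pr.het_scale,
            201,
        )
        ll = binom.logpmf(3, 12, expit(agrid[:, None])) + binom.logpmf(
            8, 12, expit(agrid[:, None] + dgrid[None, :])
        )
        ll += norm.logpdf(agrid[:, None], 0.0, pr.fixed_effect_sd)
        m = ll.max()
        l_delta = m + np.log(np.exp(ll - m).sum(axis=0))  # over alpha
        s2 = np.exp(xgrid)
        # delta | sigma integrated over mu ~ N(0, v0): N(0, sigma^2 + v0)
        logw = (
            l_delta[:, None]
            + norm.logpdf(dgrid[:, None], 0.0, np.sqrt(s2 + v0)[None, :])
            + norm.logpdf(xgrid, pr.het_location, pr.het_scale)[None, :]
        )
        w = np.exp(logw - logw.max())
        w /= w.sum()
        cond_mean = dgrid[:, None] * v0 / (s2 + v0)[None, :]
        cond_sd = np.sqrt(s2 * v0 / (s2 + v0))[None, :] * np.ones_like(w)

        def cdf(q):
            return float((w * norm.cdf((q - cond_mean) / cond_sd)).sum())

        lo_q, hi_q = -5.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo_q + hi_q)
            if cdf(mid) < 0.5:
                lo_q = mid
            else:
                hi_q = mid
        oracle = 0.5 * (lo_q + hi_q)
        tol = 4 * mcse_median(draws, "mu_c[2]") + 0.02
        assert med == pytest.approx(oracle, abs=tol)

    def test_same_seed_identical_draws(self, data_2a):
        net, _ = data_2a
        cfg = ChainConfig(burn_in=200, post_burn_updates=800, thin=4, seed=7)
        a = fit(ModelSpec(3), net, cfg)
        b = fit(ModelSpec(3), net, cfg)
        assert a.draws.equals(b.draws)

    def test_retained_count(self, data_2a):
        net, _ = data_2a
        cfg = ChainConfig(burn_in=100, post_burn_updates=1000, thin=20, seed=1)
        draws = fit(ModelSpec(1), net, cfg)
        assert len(draws.draws) == 50

    def test_model1_multiarm_rejected(self):
        net = Network(
            arms=(
                ArmRecord(1, 1, 1, 10),
                ArmRecord(1, 2, 2, 10),
                ArmRecord(1, 3, 3, 10),
            )
        )
        with pytest.raises(ValueError, match="two-arm"):
            fit(ModelSpec(1), net, ChainConfig(burn_in=10,
                                               post_burn_updates=10, seed=0))

    def test_monitored_parameters_by_model(self, data_2a):
        net, _ = data_2a
        cfg = ChainConfig(burn_in=50, post_burn_updates=100, thin=10, seed=3)
        assert set(fit(ModelSpec(1), net, cfg).parameters) == {
            "mu_c[2]", "mu_c[3]", "sigma_c"
        }
        p3 = set(fit(ModelSpec(3), net, cfg).parameters)
        assert {"mu_a[1]", "sigma_a", "sigma_c"} <= p3
        p4 = set(fit(ModelSpec(4), net, cfg).parameters)
        assert {"mu_a[1]", "mu_a[2]", "mu_a[3]", "sigma_a", "rho_a"} <= p4
        p4n = set(fit(ModelSpec(4, heterogeneity="NCH"), net, cfg).parameters)
        assert {"Sigma_a[1,1]", "Sigma_a[1,3]", "Sigma_a[3,3]"} <= p4n

    def test_true_value_recovered_on_null_dataset(self):
        """Hypothetical data 2a: the Z-Y contrast is truly 0 and the layout
        is balanced, so every model's posterior median is near 0."""
        net, _ = generate(ScenarioSpec(2, "a"))
        draws = fit(ModelSpec(1), net, short_chains(seed=11))
        zy = draws.contrast(3, 2)
        med = float(np.median(zy))
        assert abs(med) < 0.08


@pytest.mark.parametrize("model", [1, 2, 3, 4])
def test_thinned_chain_autocorrelation_below_threshold(data_2a, model):
    """With default-style thinning (every 20th update), all monitored
    parameters of the CH models mix to autocorrelation < 0.2 by lag 4."""
    net, _ = data_2a
    cfg = ChainConfig(burn_in=2000, post_burn_updates=20000, thin=20,
                      seed=770 + model)
    draws = fit(ModelSpec(model), net, cfg)
    for p in draws.parameters:
        assert abs(autocorrelation(draws, p, lag=4)) < 0.2, p


class TestParameterRecoverySmall:
    def test_model2_recovers_known_contrasts(self):
        """Simulated model-2 data with large arms: posterior medians land
        near the generating values."""
        from abnma.hypodata import simulate_ch_network

        net = simulate_ch_network(30, 500, np.array([0.0, 0.5]), 0.3, seed=42)
        draws = fit(ModelSpec(2), net, short_chains(seed=42))
        m2 = summarize(draws, "mu_c[2]")
        m3 = summarize(draws, "mu_c[3]")
        assert m2.ci_low < 0.0 < m2.ci_high or abs(m2.median) < 0.2
        assert abs(m3.median - 0.5) < 0.25


class TestAutocorrelation:
    def test_independent_chain_near_zero(self, rng):
        x = rng.standard_normal(5000)
        assert abs(autocorrelation(x, lag=1)) < 0.05

    def test_ar1_matches_closed_form(self, rng):
        phi = 0.9
        n = 20000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        for lag in (1, 2):
            assert autocorrelation(x, lag=lag) == pytest.approx(
                phi**lag, abs=0.05
            )

    def test_constant_chain_returns_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant chain"):
            assert autocorrelation(np.ones(100), lag=1) == 0.0

    def test_bad_lag_rejected(self, rng):
        with pytest.raises(ValueError):
            autocorrelation(rng.standard_normal(10), lag=0)
        with pytest.raises(ValueError):
            autocorrelation(rng.standard_normal(10), lag=50)


class TestSummarize:
    def test_sequence_quantiles(self):
        s = summarize(np.arange(1.0, 101.0))
        assert s.median == pytest.approx(50.5)
        assert s.ci_low == pytest.approx(3.475)
        assert s.ci_high == pytest.approx(97.525)

    def test_degenerate_draws(self):
        s = summarize(np.full(50, 3.2))
        assert (s.median, s.ci_low, s.ci_high) == (3.2, 3.2, 3.2)

    def test_standard_normal_draws(self, rng):
        s = summarize(rng.standard_normal(100_000))
        assert s.median == pytest.approx(0.0, abs=0.02)
        assert s.ci_low == pytest.approx(-1.96, abs=0.04)
        assert s.ci_high == pytest.approx(1.96, abs=0.04)

    def test_unknown_parameter(self, data_2a):
        net, _ = data_2a
        draws = fit(ModelSpec(1), net,
                    ChainConfig(burn_in=50, post_burn_updates=100, seed=0))
        with pytest.raises(KeyError):
            summarize(draws, "nope")


class TestPosteriorSlope:
    def _draws(self, data_2a, seed=5):
        net, _ = data_2a
        return fit(ModelSpec(1), net,
                   ChainConfig(burn_in=200, post_burn_updates=2000, thin=2,
                               seed=seed))

    def test_exact_linear_relation(self, rng):
        """slope(y = 2x) = 2 via a synthetic draws object."""
        import pandas as pd

        from abnma.mcmc import PosteriorDraws

        x = rng.standard_normal(1000)
        d = PosteriorDraws(
            draws=pd.DataFrame({"x": x, "y": 2 * x}),
            spec=ModelSpec(1),
            config=ChainConfig(burn_in=0, post_burn_updates=1000, thin=1,
                               seed=0),
        )
        assert posterior_slope(d, "y", "x") == pytest.approx(2.0)

    def test_known_covariance(self, rng):
        import pandas as pd

        from abnma.mcmc import PosteriorDraws

        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=60_000)
        d = PosteriorDraws(
            draws=pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}),
            spec=ModelSpec(1),
            config=ChainConfig(burn_in=0, post_burn_updates=60_000, thin=1,
                               seed=0),
        )
        assert posterior_slope(d, "y", "x") == pytest.approx(0.6, abs=0.03)

    def test_zero_variance_rejected(self):
        import pandas as pd

        from abnma.mcmc import PosteriorDraws

        d = PosteriorDraws(
            draws=pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)}),
            spec=ModelSpec(1),
            config=ChainConfig(burn_in=0, post_burn_updates=10, thin=1,
                               seed=0),
        )
        with pytest.raises(ValueError, match="zero variance"):
            posterior_slope(d, "y", "x")


def test_persistence_round_trip(tmp_path, data_2a):
    from abnma.mcmc import PosteriorDraws

    net, _ = data_2a
    draws = fit(ModelSpec(3), net,
                ChainConfig(burn_in=100, post_burn_updates=400, thin=4,
                            seed=9))
    draws.save(tmp_path / "d.csv", tmp_path / "d.json")
    again = PosteriorDraws.load(tmp_path / "d.csv", tmp_path / "d.json")
    assert again.spec == draws.spec
    assert again.config == draws.config
    np.testing.assert_allclose(again.draws.to_numpy(), draws.draws.to_numpy())


def test_default_chain_regime_constants():
    cfg = ChainConfig()
    assert (cfg.burn_in, cfg.post_burn_updates, cfg.thin) == (50_000,
                                                              200_000, 20)
    assert cfg.n_kept == 10_000
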