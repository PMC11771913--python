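"""MCMC probit and spatial probit: samplers, summaries, DIC, effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtri

import crashspat as cs
from crashspat._kernels import seed_kernels, truncnorm_lower, truncnorm_upper
from crashspat.preprocessing import DesignMatrix
from crashspat.spatial_probit import (PosteriorFit, latent_conditional_params,
                                      marginal_effects, reported_effect_pct,
                                      _deviance, fit_report_text, write_trace)

from conftest import simple_design


def make_fit(draws, names=None, rho=None, **kw):
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] == 1:
        draws = draws.T
    names = names or [f"b{j}" for j in range(draws.shape[1])]
    return PosteriorFit("probit" if rho is None else "spatial_probit",
                        names, draws,
                        rho_draws=None if rho is None else np.asarray(rho),
                        n_obs=draws.shape[0], **kw)


class TestTruncatedNormalKernel:
    @pytest.mark.parametrize("mu,lower", [(0.0, 0.0), (-2.5, 0.0), (1.5, 0.0),
                                          (0.0, 3.0)])
    def test_moments_match_scipy(self, mu, lower):
        seed_kernels(123)
        draws = np.array([truncnorm_lower(mu, 1.0, lower)
                          for _ in range(20_000)])
        ref = stats.truncnorm((lower - mu), np.inf, loc=mu, scale=1.0)
        assert draws.min() > lower
        assert draws.mean() == pytest.approx(ref.mean(), abs=0.03)
        assert draws.std() == pytest.approx(ref.std(), abs=0.03)

    def test_upper_is_mirror(self):
        seed_kernels(7)
        a = np.array([truncnorm_upper(1.0, 2.0, 0.0) for _ in range(5000)])
        seed_kernels(7)
        b = np.array([-truncnorm_lower(-1.0, 2.0, 0.0) for _ in range(5000)])
        assert np.array_equal(a, b)


class TestProbit:
    def test_intercept_only_matches_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(600) < 0.65).astype(int)
        d = DesignMatrix(y, np.ones((600, 1)), ["intercept"])
        fit = cs.fit_probit(d, cs.McmcConfig(n_draws=3000, burn_in=500, seed=1))
        phat = y.mean()
        s = fit.summary()
        # MLE of an intercept-only probit is Phi^{-1}(phat)
        assert s.loc["intercept", "mean"] == pytest.approx(ndtri(phat), abs=0.04)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_parameter_recovery_rho_zero(self, seed):
        cfg = cs.SyntheticConfig(
            hotspots=[], background_count=500, bounding_box=(0, 0, 1000, 1000),
            covariate_schema=[cs.Continuous("x1", 0.0, 1.0)],
            beta=[0.5, -1.0], rho=0.0, seed=seed)
        table, _ = cs.generate_crash_table(cfg)
        d = cs.build_design(cs.binarize_severity(table), ["x1"])
        fit = cs.fit_probit(d, cs.McmcConfig(seed=seed))
        assert np.all(np.abs(fit.posterior_mean() - [0.5, -1.0]) < 0.15)

    def test_zero_variance_predictor_posterior_is_prior(self, quick_mcmc):
        rng = np.random.default_rng(3)
        y = (rng.random(200) < 0.5).astype(int)
        X = np.column_stack([np.ones(200), np.zeros(200)])
        d = DesignMatrix(y, X, ["intercept", "dead"])
        cfg = cs.McmcConfig(n_draws=4000, burn_in=500, seed=4)
        fit = cs.fit_probit(d, cfg)
        dead = fit.beta_draws[:, 1]
        # prior is N(0, 100): mean ~ 0, sd ~ 10
        assert abs(dead.mean()) < 1.5
        assert dead.std() == pytest.approx(10.0, rel=0.15)

    def test_constant_response_rejected(self, quick_mcmc):
        d = DesignMatrix(np.ones(50, int), np.ones((50, 1)), ["intercept"])
        with pytest.raises(ValueError):
            cs.fit_probit(d, quick_mcmc)

    def test_reproducible_with_same_seed(self, quick_mcmc):
        d, _, _ = simple_design(n=150, seed=2)
        a = cs.fit_probit(d, quick_mcmc)
        b = cs.fit_probit(d, quick_mcmc)
        assert np.array_equal(a.beta_draws, b.beta_draws)

    def test_latent_sign_consistency(self, quick_mcmc):
        d, _, _ = simple_design(n=150, seed=2)
        assert cs.fit_probit(d, quick_mcmc).latent_sign_ok


class TestSpatialProbit:
    def test_requires_standardized_weights(self, quick_mcmc):
        d, W, _ = simple_design(n=60, seed=1)
        raw = cs.knn_weights(d.coords, 5)
        with pytest.raises(ValueError):
            cs.fit_spatial_probit(d, raw, quick_mcmc)

    def test_rho_draws_inside_support(self, quick_mcmc):
        d, W, _ = simple_design(n=120, rho=0.4, seed=3)
        fit = cs.fit_spatial_probit(d, W, quick_mcmc)
        lo, hi = fit.rho_support
        assert np.all((fit.rho_draws > lo) & (fit.rho_draws < hi))

    def test_reduction_law_conditionals(self):
        # at rho = 0 the latent conditionals are exactly the probit ones
        rng = np.random.default_rng(8)
        n, k = 30, 2
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([0.3, -0.7])
        ystar = rng.standard_normal(n)
        P = np.eye(n)                     # (I - 0*W)'(I - 0*W)
        b = X @ beta                      # (I - 0*W)' X beta
        m, s = latent_conditional_params(P, b, ystar)
        assert np.allclose(m, X @ beta)
        assert np.allclose(s, 1.0)

    def test_reproducible_with_same_seed(self, quick_mcmc):
        d, W, _ = simple_design(n=100, rho=0.3, seed=4)
        a = cs.fit_spatial_probit(d, W, quick_mcmc)
        b = cs.fit_spatial_probit(d, W, quick_mcmc)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.rho_draws, b.rho_draws)

    def test_recovers_positive_rho(self):
        d, W, truth = simple_design(n=400, rho=0.5, seed=0)
        fit = cs.fit_spatial_probit(d, W, cs.McmcConfig(seed=0))
        assert fit.rho_draws.mean() == pytest.approx(0.5, abs=0.2)
        assert 0.05 < fit.acceptance_rate < 0.95
        assert fit.latent_sign_ok

    def test_dimension_mismatch_rejected(self, quick_mcmc):
        d, W, _ = simple_design(n=80, seed=5)
        W2 = cs.WeightsSpec("knn", 5).build(
            np.random.default_rng(1).random((40, 2)))
        with pytest.raises(ValueError):
            cs.fit_spatial_probit(d, W2, quick_mcmc)


class TestSummarize:
    def test_constant_draws_degenerate(self):
        fit = make_fit(np.full((200, 1), 1.5), ["c"])
        s = cs.summarize(fit)
        assert s.loc["c", "sd"] == 0.0
        assert s.loc["c", "mcse"] == 0.0
        assert s.loc["c", "bci_lower"] == s.loc["c", "bci_upper"] == 1.5

    def test_iid_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        fit = make_fit(rng.standard_normal(10_000), ["z"])
        s = cs.summarize(fit)
        assert abs(s.loc["z", "mean"]) < 0.05
        assert s.loc["z", "sd"] == pytest.approx(1.0, abs=0.05)
        assert s.loc["z", "bci_lower"] == pytest.approx(-1.96, abs=0.05)
        assert s.loc["z", "bci_upper"] == pytest.approx(1.96, abs=0.05)

    def test_bci_equals_empirical_quantiles(self):
        rng = np.random.default_rng(1)
        draws = rng.gamma(2.0, size=500)
        fit = make_fit(draws, ["g"])
        s = cs.summarize(fit, level=0.95)
        assert s.loc["g", "bci_lower"] == pytest.approx(
            np.quantile(draws, 0.025), rel=1e-12)
        assert s.loc["g", "bci_upper"] == pytest.approx(
            np.quantile(draws, 0.975), rel=1e-12)

    def test_significance_flag(self):
        rng = np.random.default_rng(2)
        fit = make_fit(np.column_stack([rng.normal(5, 0.1, 300),
                                        rng.normal(0, 1, 300)]), ["a", "b"])
        s = cs.summarize(fit)
        assert s.loc["a", "significant"]
        assert not s.loc["b", "significant"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            cs.summarize(make_fit(np.zeros((50, 1))))


class TestDIC:
    def test_perfect_fit_deviance_near_zero(self):
        y = np.array([0, 0, 1, 1])
        eta = np.array([-20.0, -20.0, 20.0, 20.0])
        dev, _ = _deviance(y, eta)
        assert dev == pytest.approx(0.0, abs=1e-6)

    def test_balanced_intercept_only_dhat(self):
        rng = np.random.default_rng(4)
        n = 400
        y = np.repeat([0, 1], n // 2)
        d = DesignMatrix(y, np.ones((n, 1)), ["intercept"])
        fit = cs.fit_probit(d, cs.McmcConfig(n_draws=2000, burn_in=400, seed=5))
        dic = cs.compute_dic(fit, d)
        assert dic.dhat == pytest.approx(-2 * n * np.log(0.5), rel=0.005)
        assert dic.dic == pytest.approx(dic.dbar + dic.pd)

    def test_spatial_dic_requires_weights(self, quick_mcmc):
        d, W, _ = simple_design(n=100, rho=0.3, seed=6)
        fit = cs.fit_spatial_probit(d, W, quick_mcmc)
        with pytest.raises(ValueError):
            cs.compute_dic(fit, d)


class TestMarginalEffects:
    def test_reported_mode_matches_published_arithmetic(self):
        # posterior-mean coefficient -0.106 is quoted as a 10.6% decrease
        assert reported_effect_pct(-0.106) == pytest.approx(-10.6)
        d, _, _ = simple_design(n=100, seed=7)
        fit = make_fit(np.column_stack([np.full(200, 0.2),
                                        np.full(200, -0.106)]),
                       ["intercept", "x1"])
        eff = marginal_effects(fit, d)
        assert eff.loc["x1", "reported_pct"] == pytest.approx(-10.6)

    def test_zero_coefficient_zero_effect(self):
        d, _, _ = simple_design(n=100, seed=7)
        fit = make_fit(np.column_stack([np.full(200, 0.3),
                                        np.zeros(200)]), ["intercept", "x1"])
        eff = marginal_effects(fit, d)
        assert eff.loc["x1", "reported_pct"] == 0.0
        assert eff.loc["x1", "ape"] == 0.0

    def test_spatial_multiplier_reduces_to_identity_at_rho_zero(self):
        d, W, _ = simple_design(n=120, rho=0.0, seed=8)
        beta_draws = np.column_stack([np.full(150, 0.4), np.full(150, -0.6)])
        plain = marginal_effects(make_fit(beta_draws, ["intercept", "x1"]), d)
        spatial = marginal_effects(
            make_fit(beta_draws, ["intercept", "x1"], rho=np.zeros(150)),
            d, W)
        assert spatial.loc["x1", "ape"] == pytest.approx(
            plain.loc["x1", "ape"], rel=1e-9)

    def test_spatial_without_weights_rejected(self):
        d, _, _ = simple_design(n=50, seed=9)
        fit = make_fit(np.zeros((150, 2)), ["intercept", "x1"],
                       rho=np.zeros(150))
        with pytest.raises(ValueError):
            marginal_effects(fit, d)


class TestStepwisePrune:
    def test_noise_removed_signal_kept(self):
        cfg = cs.SyntheticConfig(
            hotspots=[], background_count=500, bounding_box=(0, 0, 1000, 1000),
            covariate_schema=[cs.Continuous("signal", 0.0, 1.0),
                              cs.Continuous("noise", 0.0, 1.0)],
            beta=[0.3, -1.2, 0.0], rho=0.0, seed=10)
        table, _ = cs.generate_crash_table(cfg)
        d = cs.build_design(cs.binarize_severity(table), ["signal", "noise"])
        fit, log, final = cs.stepwise_prune(
            d, None, cs.McmcConfig(n_draws=2500, burn_in=500, seed=11))
        assert [e["removed"] for e in log] == ["noise"]
        assert final.names == ["intercept", "signal"]
        # bookkeeping: removals = initial predictors - retained predictors
        assert len(log) == (len(d.names) - len(final.names))

    def test_all_significant_no_removals(self):
        d, _, _ = simple_design(n=500, seed=12, beta=(1.0, -1.5))
        fit, log, final = cs.stepwise_prune(
            d, None, cs.McmcConfig(n_draws=2000, burn_in=400, seed=13))
        assert log == []
        assert final.names == d.names


class TestReports:
    def test_fit_report_text_contains_table(self, quick_mcmc):
        d, _, _ = simple_design(n=150, seed=14)
        fit = cs.fit_probit(d, quick_mcmc)
        dic = cs.compute_dic(fit, d)
        text = fit_report_text(fit, dic)
        assert "intercept" in text and "DIC" in text

    def test_trace_file(self, quick_mcmc, tmp_path):
        d, W, _ = simple_design(n=100, rho=0.3, seed=15)
        fit = cs.fit_spatial_probit(d, W, quick_mcmc)
        path = tmp_path / "trace.csv"
        write_trace(fit, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["intercept", "x1", "rho"]
        assert len(df) == fit.n_retained
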