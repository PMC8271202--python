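"""Model scoring engine: standardization, subset fits, marginal likelihoods,
and exhaustive / shotgun-stochastic model search."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp

from mrbma import (
    ConfigurationError,
    HarmonizedDataset,
    PriorConfig,
    VariantKey,
    fit_subset,
    log_marginal,
    score_models,
    standardize,
)
from mrbma.bma_core import DegenerateModelError


def _dataset(beta_x, beta_y, se_y):
    n = beta_x.shape[0]
    variants = [VariantKey(f"rs{i}", "1", 1000 + i, "A", "G") for i in range(n)]
    return HarmonizedDataset(variants=variants,
                             factors=[f"F{j}" for j in range(beta_x.shape[1])],
                             beta_x=beta_x, beta_y=beta_y, se_y=se_y)


class TestStandardize:
    def test_unit_se_is_identity(self, rng):
        beta_x = rng.normal(size=(10, 2))
        beta_y = rng.normal(size=10)
        X, y = standardize(_dataset(beta_x, beta_y, np.ones(10)))
        np.testing.assert_array_equal(X, beta_x)
        np.testing.assert_array_equal(y, beta_y)

    def test_doubling_se_halves_row(self, rng):
        beta_x = rng.normal(size=(10, 2))
        beta_y = rng.normal(size=10)
        se = np.ones(10)
        X1, y1 = standardize(_dataset(beta_x, beta_y, se))
        se2 = se.copy()
        se2[3] *= 2
        X2, y2 = standardize(_dataset(beta_x, beta_y, se2))
        np.testing.assert_allclose(X2[3], X1[3] / 2)
        np.testing.assert_allclose(y2[3], y1[3] / 2)

    def test_ols_on_standardized_equals_wls_on_raw(self, rng):
        """Inverse-variance weighting: WLS(1/se^2) on raw data == OLS on standardized."""
        import statsmodels.api as sm

        beta_x = rng.normal(size=(20, 3))
        beta_y = beta_x @ [0.4, 0.0, -0.2] + rng.normal(size=20) * 0.1
        se = rng.uniform(0.5, 2.0, size=20)
        ds = _dataset(beta_x, beta_y, se)
        X, y = standardize(ds)
        wls = sm.WLS(beta_y, beta_x, weights=1.0 / se**2).fit()
        theta, _ = fit_subset(X, y, (0, 1, 2))
        np.testing.assert_allclose(theta, wls.params, rtol=1e-10)


class TestFitSubset:
    def test_exact_fit_recovers_planted_slope(self):
        x = np.linspace(-2, 2, 12)
        X = x[:, None]
        y = 0.464 * x
        theta, se = fit_subset(X, y, (0,))
        assert theta[0] == pytest.approx(0.464, abs=1e-12)
        np.testing.assert_allclose(y - X @ theta, 0.0, atol=1e-12)

    def test_duplicated_column_is_degenerate(self, rng):
        col = rng.normal(size=15)
        X = np.column_stack([col, col])
        with pytest.raises(DegenerateModelError):
            fit_subset(X, rng.normal(size=15), (0, 1))

    def test_matches_normal_equations_oracle(self, rng):
        """Random 15x2 instance agrees with an independent OLS solver."""
        import statsmodels.api as sm

        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        theta, se = fit_subset(X, y, (0, 1))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(theta, ols.params, rtol=1e-10)
        # fixed-effect convention: SEs from unscaled inverse Gram
        np.testing.assert_allclose(se, np.sqrt(np.diag(np.linalg.inv(X.T @ X))), rtol=1e-10)


class TestLogMarginal:
    def test_vanishing_prior_sd_approaches_empty_model(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        empty = log_marginal(X, y, (), PriorConfig(effect_sd=0.5))
        small = log_marginal(X, y, (0, 2), PriorConfig(effect_sd=1e-8))
        assert small == pytest.approx(empty, abs=1e-6)

    def test_agrees_with_adaptive_quadrature_k1(self, rng):
        """n=8, one factor: closed form vs numerical likelihood x prior integration."""
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        sd = 0.5
        got = log_marginal(X, y, (1,), PriorConfig(effect_sd=sd))
        x1 = X[:, 1]

        def loglik(th):
            return -0.5 * (8 * np.log(2 * np.pi) + np.sum((y - th * x1) ** 2))

        peak = loglik(np.dot(y, x1) / np.dot(x1, x1))
        val, err = integrate.quad(lambda th: np.exp(loglik(th) - peak) * stats.norm.pdf(th, 0, sd),
                                  -20, 20, epsabs=1e-14, epsrel=1e-12)
        oracle = np.log(val) + peak
        assert abs(got - oracle) / abs(oracle) < 1e-6

    def test_agrees_with_monte_carlo_k2(self, rng):
        """n=8, two factors: closed form within 3 standard errors of a 1e6-draw MC estimate."""
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        sd = 0.5
        got = log_marginal(X, y, (0, 1), PriorConfig(effect_sd=sd))
        draws = rng.normal(scale=sd, size=(1_000_000, 2))
        resid = y[None, :] - draws @ X.T
        loglik = -0.5 * (8 * np.log(2 * np.pi) + np.sum(resid**2, axis=1))
        log_mean = logsumexp(loglik) - np.log(len(loglik))
        w = np.exp(loglik - loglik.max())
        rel_se = np.std(w) / (np.mean(w) * np.sqrt(len(w)))  # se of the mean, relative scale
        assert abs(np.exp(got - log_mean) - 1.0) < 3 * rel_se

    def test_empty_subset_is_standard_normal_density(self, rng):
        y = rng.normal(size=10)
        got = log_marginal(rng.normal(size=(10, 1)), y, (), PriorConfig())
        assert got == pytest.approx(np.sum(stats.norm.logpdf(y)), rel=1e-12)


class TestScoreModels:
    def test_single_factor_forced_normalization(self, rng):
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        res = score_models(X, y, PriorConfig())
        assert len(res.models) == 1
        assert res.models[0].posterior_prob == pytest.approx(1.0)
        assert res.mip[0] == pytest.approx(1.0)

    def test_posteriors_normalize_and_mip_dominates_models(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 1] * 0.3 + rng.normal(size=40)
        res = score_models(X, y, PriorConfig(max_model_size=3))
        assert sum(m.posterior_prob for m in res.models) == pytest.approx(1.0, abs=1e-10)
        for j in range(6):
            containing = [m.posterior_prob for m in res.models if j in m.subset]
            assert res.mip[j] == pytest.approx(sum(containing), abs=1e-10)
            assert res.mip[j] >= max(containing) - 1e-12
            assert 0.0 <= res.mip[j] <= 1.0 + 1e-12

    def test_mace_is_posterior_weighted_effect_sum(self, rng):
        X = rng.normal(size=(30, 4))
        y = X[:, 0] * 0.4 + rng.normal(size=30)
        res = score_models(X, y, PriorConfig(max_model_size=2))
        for j in range(4):
            expected = sum(m.posterior_prob * m.theta_hat[m.subset.index(j)]
                           for m in res.models if j in m.subset)
            assert res.mace[j] == pytest.approx(expected, abs=1e-12)

    def test_factor_relabeling_permutes_summaries(self, rng):
        X = rng.normal(size=(30, 5))
        y = X[:, 2] * 0.5 + rng.normal(size=30)
        perm = np.array([3, 0, 4, 1, 2])
        res = score_models(X, y, PriorConfig(max_model_size=2))
        res_p = score_models(X[:, perm], y, PriorConfig(max_model_size=2))
        np.testing.assert_allclose(res_p.mip, res.mip[perm], atol=1e-12)
        np.testing.assert_allclose(res_p.mace, res.mace[perm], atol=1e-12)

    def test_scale_coherence_with_rescaled_prior(self, rng):
        """Rescaling one exposure column by c and its prior sd by 1/c leaves
        posteriors invariant and divides that factor's effects by c."""
        X = rng.normal(size=(30, 3))
        y = X[:, 0] * 0.4 + rng.normal(size=30)
        c = 2.5
        sd = np.array([0.5, 0.5, 0.5])
        res = score_models(X, y, PriorConfig(effect_sd=sd, max_model_size=2))
        X2 = X.copy()
        X2[:, 1] *= c
        sd2 = sd.copy()
        sd2[1] /= c
        res2 = score_models(X2, y, PriorConfig(effect_sd=sd2, max_model_size=2))
        for m1, m2 in zip(sorted(res.models, key=lambda m: m.subset),
                          sorted(res2.models, key=lambda m: m.subset)):
            assert m1.subset == m2.subset
            assert m2.posterior_prob == pytest.approx(m1.posterior_prob, rel=1e-9)
        np.testing.assert_allclose(res2.mace[1], res.mace[1] / c, rtol=1e-9)
        np.testing.assert_allclose(res2.mace[[0, 2]], res.mace[[0, 2]], rtol=1e-9)

    def test_stochastic_with_ample_budget_matches_exhaustive(self, rng):
        X = rng.normal(size=(40, 5))
        y = X[:, 1] * 0.3 + rng.normal(size=40)
        prior = PriorConfig(max_model_size=5)
        ex = score_models(X, y, prior)
        st = score_models(X, y, prior, mode="stochastic", budget=5000, seed=3)
        assert st.models_visited == ex.models_visited  # all 2^5 - 1 models found
        np.testing.assert_allclose(st.mip, ex.mip, atol=1e-12)
        assert st.models[0].subset == ex.models[0].subset

    def test_stochastic_rerun_is_bit_identical(self, rng):
        X = rng.normal(size=(40, 8))
        y = X[:, 0] * 0.3 + rng.normal(size=40)
        prior = PriorConfig(max_model_size=3)
        a = score_models(X, y, prior, mode="stochastic", budget=200, seed=9)
        b = score_models(X, y, prior, mode="stochastic", budget=200, seed=9)
        assert [m.subset for m in a.models] == [m.subset for m in b.models]
        np.testing.assert_array_equal(a.mip, b.mip)

    def test_insufficient_budget_is_configuration_error(self, rng):
        X = rng.normal(size=(20, 8))
        with pytest.raises(ConfigurationError, match="budget"):
            score_models(X, rng.normal(size=20), PriorConfig(), mode="stochastic",
                         budget=4, seed=0)

    def test_degenerate_models_get_zero_posterior(self, rng):
        col = rng.normal(size=25)
        X = np.column_stack([col, col, rng.normal(size=25)])
        y = col * 0.4 + rng.normal(size=25)
        res = score_models(X, y, PriorConfig(max_model_size=2))
        bad = [m for m in res.models if m.subset == (0, 1)]
        assert bad[0].degenerate and bad[0].posterior_prob == 0.0
        assert sum(m.posterior_prob for m in res.models) == pytest.approx(1.0, abs=1e-10)
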