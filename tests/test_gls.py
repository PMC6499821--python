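"""The ML-GLS engine: likelihood, fitting, tests, predictions, residuals."""

import numpy as np
import pytest
from scipy import stats

from langdiv.gls import (
    CorrelationParams,
    GLSConfig,
    build_correlation,
    fit_gls,
    fit_gls_fixed,
    fit_ols,
    lr_test,
    negloglik,
    predicted_r2,
    standardized_residuals,
)
from langdiv.similarity import euclidean_matrix, gaussian_decay

from _oracles import ols_closed_form
from conftest import gls_instance, small_config


def random_problem(rng, n=30, p=3):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n)
    P = np.eye(n)
    pts = rng.uniform(0, 1000, size=(n, 2))
    d = euclidean_matrix(pts[:, 0], pts[:, 1])
    return y, X, P, d


class TestBuildCorrelation:
    def test_alpha_zero_gives_identity(self, rng):
        _, _, P, d = random_problem(rng)
        C = build_correlation(CorrelationParams(0.0, 0.5, 500.0), P, d)
        assert np.array_equal(C, np.eye(len(C)))

    def test_alpha_beta_one_gives_P(self, rng):
        n = 10
        A = rng.uniform(0, 1, size=(n, n))
        P = 0.5 * (A + A.T)
        np.fill_diagonal(P, 1.0)
        d = euclidean_matrix(*rng.uniform(0, 100, size=(2, n)))
        C = build_correlation(CorrelationParams(1.0, 1.0, 100.0), P, d)
        assert np.allclose(C, P, atol=1e-15)

    def test_unit_diagonal_for_any_valid_params(self, rng):
        _, _, P, d = random_problem(rng, n=15)
        for a, b, g in rng.uniform([0, 0, 10], [1, 1, 5000], size=(25, 3)):
            C = build_correlation(CorrelationParams(a, b, g), P, d)
            assert np.all(np.diag(C) == 1.0)
            assert np.allclose(C, C.T)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_correlation(
                CorrelationParams(0.5, 0.5, 100.0), np.eye(3), np.zeros((4, 4))
            )

    def test_param_bounds_enforced(self):
        with pytest.raises(ValueError):
            CorrelationParams(-0.1, 0.5, 100.0)
        with pytest.raises(ValueError):
            CorrelationParams(0.5, 1.2, 100.0)
        with pytest.raises(ValueError):
            CorrelationParams(0.5, 0.5, 0.0)


class TestNegLogLik:
    def test_alpha_zero_equals_closed_form_ols_likelihood(self, rng):
        y, X, P, d = random_problem(rng)
        nll = negloglik(CorrelationParams(0.0, 0.3, 500.0), y, X, P, d)
        _, _, ll_ols = ols_closed_form(y, X)
        assert nll == pytest.approx(-ll_ols, rel=1e-12)

    def test_matches_multivariate_normal_logpdf_at_profiled_estimates(self, rng):
        # independent oracle: evaluate the exact Gaussian density at the
        # profiled (b, sigma2) computed from explicit inverses
        y, X, P, d = random_problem(rng, n=20)
        params = CorrelationParams(0.6, 0.4, 400.0)
        C = build_correlation(params, P, d)
        Ci = np.linalg.inv(C)
        b = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        r = y - X @ b
        sigma2 = float(r @ Ci @ r) / len(y)
        ll = stats.multivariate_normal(mean=X @ b, cov=sigma2 * C).logpdf(y)
        assert negloglik(params, y, X, P, d) == pytest.approx(-ll, rel=1e-10)

    def test_beta_irrelevant_when_P_identity_and_kernel_vanishes(self, rng):
        y, X, P, d = random_problem(rng)
        d = d + 1e7  # off-diagonal distances huge -> kernel ~ 0
        np.fill_diagonal(d, 0.0)
        vals = [
            negloglik(CorrelationParams(0.5, b, 10.0), y, X, P, d)
            for b in (0.0, 0.5, 1.0)
        ]
        assert np.ptp(vals) < 1e-9

    def test_underdetermined_problem_rejected(self, rng):
        y, X, P, d = random_problem(rng, n=3, p=3)
        with pytest.raises(ValueError, match="rank"):
            negloglik(CorrelationParams(0.1, 0.5, 100.0), y, X, P, d)


class TestOLS:
    def test_matches_textbook_closed_form_and_statsmodels(self, rng):
        import statsmodels.api as sm

        y, X, _, _ = random_problem(rng, n=40)
        fit = fit_ols(y, X)
        b, sigma2, ll = ols_closed_form(y, X)
        assert np.allclose(fit.coef, b, atol=1e-12)
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-12)
        assert fit.loglik == pytest.approx(ll, rel=1e-12)
        res = sm.OLS(y, X).fit()
        assert np.allclose(fit.coef, res.params, atol=1e-10)
        assert fit.loglik == pytest.approx(res.llf, rel=1e-10)
        # in-sample R^2 is the OLS predicted R^2
        assert fit.predicted_r2 == pytest.approx(res.rsquared, rel=1e-10)

    def test_rank_deficiency_raises(self, rng):
        y, X, _, _ = random_problem(rng)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(y, X)


class TestFitGLS:
    def test_noiseless_response_recovered_exactly(self, rng):
        y, X, P, d = random_problem(rng, n=25)
        b_true = np.array([1.0, -2.0, 0.5])
        fit = fit_gls(X @ b_true, X, P, d, config=GLSConfig(n_starts=2))
        assert np.allclose(fit.coef, b_true, atol=1e-8)
        assert fit.sigma2 < 1e-16

    def test_alpha_pinned_at_zero_collapses_to_ols(self, rng):
        y, X, P, d = random_problem(rng)
        pinned = fit_gls_fixed(CorrelationParams(0.0, 0.5, 300.0), y, X, P, d)
        b, sigma2, ll = ols_closed_form(y, X)
        assert np.allclose(pinned.coef, b, atol=1e-6)
        assert pinned.loglik == pytest.approx(ll, abs=1e-8)

    def test_gls_likelihood_dominates_ols(self):
        y, X, names, P, d, _ = gls_instance(seed=3, n_cells=24)
        gls = fit_gls(y, X, P, d, config=GLSConfig(n_starts=3))
        ols = fit_ols(y, X)
        assert gls.loglik >= ols.loglik - 1e-6

    def test_scale_equivariance(self):
        y, X, names, P, d, _ = gls_instance(seed=5, n_cells=25)
        f1 = fit_gls(y, X, P, d)
        f2 = fit_gls(3.0 * y, X, P, d)
        assert np.allclose(f2.coef, 3.0 * f1.coef, rtol=1e-5)
        assert f2.sigma2 == pytest.approx(9.0 * f1.sigma2, rel=1e-5)
        assert np.allclose(f2.t, f1.t, rtol=1e-5)
        assert np.allclose(f2.p, f1.p, atol=1e-6)
        assert f2.params.alpha == pytest.approx(f1.params.alpha, abs=1e-5)
        assert f2.predicted_r2 == pytest.approx(f1.predicted_r2, abs=1e-6)

    def test_alpha_rmse_shrinks_with_sample_size(self):
        errs = {5: [], 11: []}
        for side in errs:
            for seed in range(8):
                cfg = small_config(
                    100 + seed, n_rows=side, n_cols=side, cell_km=400.0,
                    n_families=10,
                )
                y, X, names, P, d, _ = gls_instance(seed, config=cfg)
                fit = fit_gls(y, X, P, d, config=GLSConfig(n_starts=3))
                errs[side].append(fit.params.alpha - 0.7)
        rmse = {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in errs.items()}
        assert rmse[11] < rmse[5]


class TestLRTest:
    def test_identical_models_give_zero_and_p_one(self, rng):
        y, X, _, _ = random_problem(rng)
        fit = fit_ols(y, X)
        res = lr_test(fit, fit, df=1)
        assert res.lr == 0.0
        assert res.p == 1.0

    def test_negative_lr_beyond_tolerance_raises(self, rng):
        y, X, _, _ = random_problem(rng)
        full = fit_ols(y, X)
        reduced = fit_ols(y, X[:, :2])
        bad_full = fit_ols(y, X[:, :1])  # "full" that fits worse
        with pytest.raises(ValueError, match="negative LR"):
            lr_test(bad_full, reduced, df=1)

    def test_default_df_counts_dropped_columns(self, rng):
        y, X, _, _ = random_problem(rng, n=40, p=4)
        full = fit_ols(y, X)
        reduced = fit_ols(y, X[:, :2])
        assert lr_test(full, reduced).df == 2


class TestPredictedR2:
    def test_perfect_fit_gives_one(self, rng):
        y, X, P, d = random_problem(rng, n=20)
        y = X @ np.array([1.0, 2.0, -1.0])
        fit = fit_ols(y, X)
        assert fit.predicted_r2 == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_response_near_zero(self, rng):
        # alpha = 0, intercept-plus-junk predictors, large n
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        fit = fit_ols(y, X)
        assert abs(fit.predicted_r2) < 0.05

    def test_conditional_prediction_beats_ols_under_strong_correlation(self):
        y, X, names, P, d, cfg = gls_instance(
            seed=11, config=small_config(11, n_rows=8, n_cols=8, alpha=0.85)
        )
        gls = fit_gls(y, X, P, d, config=GLSConfig(n_starts=3))
        ols = fit_ols(y, X)
        assert gls.predicted_r2 > ols.predicted_r2

    def test_standalone_function_matches_fit_attribute(self):
        y, X, names, P, d, _ = gls_instance(seed=13, n_cells=25)
        fit = fit_gls(y, X, P, d, config=GLSConfig(n_starts=2))
        assert predicted_r2(fit, y, X, P, d) == pytest.approx(
            fit.predicted_r2, rel=1e-12
        )


class TestResiduals:
    def test_zero_residuals_give_no_flags(self, rng):
        _, X, P, d = random_problem(rng, n=20)
        y = X @ np.array([1.0, 0.5, -0.5])
        fit = fit_ols(y, X)
        report = standardized_residuals(fit, y, X)
        assert not report.flags.any()

    def test_standard_normal_residuals_flag_about_five_percent(self, rng):
        n = 2000
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        fit = fit_ols(y, X)
        rate = standardized_residuals(fit, y, X).flags.mean()
        assert 0.03 < rate < 0.07

    def test_whitened_residuals_pass_normality_under_correct_model(self):
        pvals = []
        for seed in range(12):
            y, X, names, P, d, cfg = gls_instance(seed=40 + seed, n_cells=25)
            fit = fit_gls(y, X, P, d, config=GLSConfig(n_starts=3))
            pvals.append(standardized_residuals(fit, y, X, P, d).shapiro_p)
        # correctly specified model: very small p-values should be rare
        assert np.mean(np.array(pvals) < 0.01) <= 2 / 12
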