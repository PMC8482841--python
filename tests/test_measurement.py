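import numpy as np
import pytest
from scipy.stats import multivariate_normal

from riskscape import GeneratorConfig, TrueParameters, generate_cohort
from riskscape import measurement as M
from riskscape.measurement import (MeasurementSpec, estimate_factor_scores,
                                   fiml_loglik, fiml_saturated,
                                   fit_measurement, invariance_ladder)

from conftest import toy_mvn_data


def brute_force_fiml(Y, mu, sigma):
    """Independent oracle: per-case density via explicit submatrices."""
    total = 0.0
    for row in np.asarray(Y, float):
        o = ~np.isnan(row)
        if not o.any():
            continue
        total += multivariate_normal.logpdf(row[o], mu[o],
                                            sigma[np.ix_(o, o)])
    return total


class TestFimlLoglik:
    def test_matches_brute_force_on_random_missing_data(self):
        Y, mu, sigma = toy_mvn_data(n=20, seed=1)
        assert fiml_loglik(Y, mu, sigma) == pytest.approx(
            brute_force_fiml(Y, mu, sigma), abs=1e-8)

    def test_complete_data_reduces_to_full_density(self):
        Y, mu, sigma = toy_mvn_data(n=10, seed=2, missing=0.0)
        expected = multivariate_normal.logpdf(Y, mu, sigma).sum()
        assert fiml_loglik(Y, mu, sigma) == pytest.approx(expected, abs=1e-8)

    def test_single_observed_variable_is_univariate_density(self):
        Y = np.full((1, 12), np.nan)
        Y[0, 3] = 1.7
        mu = np.linspace(0, 1, 12)
        sigma = np.diag(np.linspace(1, 2, 12))
        from scipy.stats import norm
        expected = norm.logpdf(1.7, mu[3], np.sqrt(sigma[3, 3]))
        assert fiml_loglik(Y, mu, sigma) == pytest.approx(expected, abs=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, cohort600):
        Y = cohort600.ef_matrix()[:150]
        pmap = M._ParamMap(MeasurementSpec(1, "metric"))
        pat = M._PatternData(Y)
        rng = np.random.default_rng(0)
        x = M._start_values(pmap, Y) + 0.05 * rng.standard_normal(pmap.n_params)
        _, grad = M._neg_loglik_and_grad(x, pmap, pat)
        h = 1e-6
        for i in rng.choice(pmap.n_params, size=12, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num = (M._neg_loglik_and_grad(xp, pmap, pat)[0]
                   - M._neg_loglik_and_grad(xm, pmap, pat)[0]) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestSaturatedModel:
    def test_em_matches_moments_on_complete_data(self):
        Y, _, _ = toy_mvn_data(n=200, seed=3, missing=0.0)
        mu, sigma, ll = fiml_saturated(Y)
        assert np.allclose(mu, Y.mean(axis=0), atol=1e-8)
        assert np.allclose(sigma, np.cov(Y.T, bias=True), atol=1e-6)

    def test_em_increases_loglik_over_start(self):
        Y, _, _ = toy_mvn_data(n=120, seed=4, missing=0.3)
        mu, sigma, ll = fiml_saturated(Y)
        diag_ll = fiml_loglik(Y, np.nanmean(Y, axis=0),
                              np.diag(np.nanvar(Y, axis=0)))
        assert ll > diag_ll


class TestFitMeasurement:
    def test_recovers_generating_parameters(self, cohort600_latent):
        cohort, _ = cohort600_latent
        truth = TrueParameters()
        big = generate_cohort(
            GeneratorConfig(n_participants=2000, seed=31,
                            retention=(1.0, 1.0),
                            wave3_opportunity_retention=1.0), truth)
        fit = fit_measurement(big.ef_matrix(), MeasurementSpec(1, "metric"))
        assert fit.converged
        # shared loadings within ~3 MC standard errors of truth
        assert np.allclose(fit.loadings[0], truth.loadings, atol=0.08)
        assert fit.indices.rmsea <= 0.05
        assert fit.indices.cfi >= 0.95
        assert fit.indices.srmr <= 0.08

    def test_chi2_zero_when_sample_moments_equal_implied(self):
        """Colour complete data so its sample moments exactly match a
        one-factor structure; the LRT against saturated must vanish."""
        rng = np.random.default_rng(5)
        lam = np.tile([1.0, 0.9, 0.8, 0.7], 3)
        Lambda = np.zeros((12, 3))
        for w in range(3):
            Lambda[w * 4:(w + 1) * 4, w] = lam[w * 4:(w + 1) * 4]
        psi = 0.4 * np.eye(3) + 0.2
        theta = 0.3 * np.eye(12)
        sigma = Lambda @ psi @ Lambda.T + theta
        mu = np.zeros(12)
        Z = rng.standard_normal((300, 12))
        Z = (Z - Z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(Z.T, bias=True)).T)
        Y = Z @ np.linalg.cholesky(sigma).T + mu
        fit = fit_measurement(Y, MeasurementSpec(1, "configural"))
        assert fit.indices.chi2 == pytest.approx(0.0, abs=1e-3)

    def test_two_factor_data_prefers_two_factor_model(self):
        rng = np.random.default_rng(6)
        n = 900
        # per wave: inhibition and shifting factors correlated 0.3
        facs = rng.multivariate_normal(
            np.zeros(6), np.kron(np.eye(3), [[1.0, 0.3], [0.3, 1.0]]), size=n)
        Y = np.empty((n, 12))
        for w in range(3):
            f_inh, f_shf = facs[:, 2 * w], facs[:, 2 * w + 1]
            Y[:, 4 * w + 0] = f_inh + 0.5 * rng.standard_normal(n)
            Y[:, 4 * w + 1] = 0.9 * f_inh + 0.5 * rng.standard_normal(n)
            Y[:, 4 * w + 2] = f_shf + 0.5 * rng.standard_normal(n)
            Y[:, 4 * w + 3] = 0.9 * f_shf + 0.5 * rng.standard_normal(n)
        sat = fiml_saturated(Y)
        one = fit_measurement(Y, MeasurementSpec(1, "configural"), saturated=sat)
        two = fit_measurement(Y, MeasurementSpec(2, "configural"), saturated=sat)
        assert two.indices.aic < one.indices.aic

    def test_order_invariance(self, cohort600):
        Y = cohort600.ef_matrix()
        perm = np.random.default_rng(7).permutation(len(Y))
        a = fit_measurement(Y, MeasurementSpec(1, "metric"),
                            compute_indices=False)
        b = fit_measurement(Y[perm], MeasurementSpec(1, "metric"),
                            compute_indices=False)
        assert a.logL == pytest.approx(b.logL, abs=1e-5)

    def test_aic_bic_identities(self, cohort600):
        fit = fit_measurement(cohort600.ef_matrix(), MeasurementSpec(1, "scalar"))
        idx = fit.indices
        assert idx.aic == pytest.approx(-2 * idx.logL + 2 * idx.n_free_params,
                                        abs=1e-9)
        assert idx.bic == pytest.approx(
            -2 * idx.logL + idx.n_free_params * np.log(fit.n_obs), abs=1e-9)


class TestInvarianceLadder:
    def test_nested_loglik_ordering_and_nonnegative_deltas(self, cohort600):
        report = invariance_ladder(cohort600.ef_matrix(), seed=0)
        by_level = {s.level: s.fit for s in report.steps}
        assert by_level["configural"].logL >= by_level["metric"].logL - 1e-6
        assert by_level["metric"].logL >= by_level["scalar"].logL - 1e-6
        for s in report.steps:
            if s.delta_chi2 is not None:
                assert s.delta_chi2 >= -1e-8
                assert s.delta_df > 0

    def test_invariant_data_reaches_scalar_or_better(self, cohort600):
        report = invariance_ladder(cohort600.ef_matrix(), seed=0)
        assert report.accepted_level in ("scalar", "partial_scalar", "residual")

    def test_planted_intercept_shift_detected_and_freed(self):
        truth = TrueParameters()
        shifted = list(map(list, truth.indicator_intercepts))
        # indicator SD ~ sqrt(lam^2*psi + theta) ~ 0.75; shift 0.8 SD
        shifted[2][1] += 0.6
        truth2 = TrueParameters(indicator_intercepts=tuple(
            tuple(r) for r in shifted))
        cohort = generate_cohort(
            GeneratorConfig(n_participants=800, seed=17), truth2)
        report = invariance_ladder(cohort.ef_matrix(), seed=0)
        scalar_step = [s for s in report.steps if s.level == "scalar"][0]
        assert scalar_step.p < 0.05
        assert (1, 2) in report.freed_intercepts


class TestFactorScores:
    def test_regression_scores_match_closed_form(self, small_complete_cohort):
        Y = small_complete_cohort.ef_matrix()
        fit = fit_measurement(Y, MeasurementSpec(1, "metric"),
                              compute_indices=False)
        scores = estimate_factor_scores(fit, Y, method="regression")
        mu, sigma, Lambda, psi, alpha = fit._pmap.implied_moments(fit._x)
        oracle = alpha + (Y - mu) @ np.linalg.inv(sigma) @ Lambda @ psi
        assert np.allclose(scores, oracle, atol=1e-8)

    def test_bartlett_noiseless_limit_recovers_latent(self):
        truth = TrueParameters(residual_variances=((1e-3,) * 4,) * 3,
                               residual_cross_corr=0.0)
        cohort, lat = generate_cohort(
            GeneratorConfig(n_participants=150, seed=23, retention=(1.0, 1.0),
                            wave3_opportunity_retention=1.0), truth,
            return_latent=True)
        fit = fit_measurement(cohort.ef_matrix(), MeasurementSpec(1, "metric"),
                              compute_indices=False)
        scores = estimate_factor_scores(fit, cohort.ef_matrix(),
                                        method="bartlett")
        for w in range(3):
            r = np.corrcoef(scores[:, w], lat["eta"][:, w])[0, 1]
            assert r > 0.999

    def test_score_determinacy_bound(self, cohort600_latent):
        cohort, lat = cohort600_latent
        Y = cohort.ef_matrix()
        fit = fit_measurement(Y, MeasurementSpec(1, "metric"),
                              compute_indices=False)
        scores = estimate_factor_scores(fit, Y, method="regression")
        mu, sigma, Lambda, psi, _ = fit._pmap.implied_moments(fit._x)
        m = psi @ Lambda.T @ np.linalg.inv(sigma) @ Lambda @ psi
        ok = ~np.isnan(scores[:, 0])
        rho = np.sqrt(m[0, 0] / psi[0, 0])  # theoretical determinacy, wave 1
        r = np.corrcoef(scores[ok, 0], lat["eta"][ok, 0])[0, 1]
        assert r > rho - 0.05

    def test_unobserved_wave_has_no_score(self, cohort600):
        Y = cohort600.ef_matrix()
        fit = fit_measurement(Y, MeasurementSpec(1, "metric"),
                              compute_indices=False)
        for method in ("bartlett", "regression"):
            scores = estimate_factor_scores(fit, Y, method=method)
            wave3_missing = np.isnan(Y[:, 8:]).all(axis=1)
            assert np.isnan(scores[wave3_missing, 2]).all()
            assert np.isfinite(scores[~wave3_missing, 2]).all()


def test_underidentified_sample_rejected():
    Y = np.random.default_rng(0).standard_normal((30, 12))
    with pytest.raises(ValueError, match="cannot identify"):
        fit_measurement(Y, MeasurementSpec(1, "configural"))
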