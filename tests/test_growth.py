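import numpy as np
import pytest
from scipy.stats import multivariate_normal

from riskscape.growth import (GrowthParams, fit_conditional_growth,
                              fit_growth, fit_stratified, growth_loglik,
                              information_criteria, model_building_ladder)


def simulate_lgm(n=300, seed=0, beta_risk=(-0.161, -0.007),
                 beta_sex=(0.275, 0.015), means=(0.0, -0.02),
                 G=((0.35, -0.005), (-0.005, 0.0016)), resid=0.1,
                 retention=(0.81, 0.56)):
    """Direct latent-growth data (no measurement layer)."""
    rng = np.random.default_rng(seed)
    risk = rng.integers(0, 12, n).astype(float)
    risk -= risk.mean()
    sex = (rng.random(n) < 0.66).astype(float)
    age1 = rng.uniform(53, 85, n)
    t = np.column_stack([age1, age1 + 4.4, age1 + 8.9]) - 75.0
    re = rng.standard_normal((n, 2)) @ np.linalg.cholesky(np.asarray(G)).T
    I = means[0] + beta_risk[0] * risk + beta_sex[0] * sex + re[:, 0]
    S = means[1] + beta_risk[1] * risk + beta_sex[1] * sex + re[:, 1]
    y = I[:, None] + S[:, None] * t + rng.standard_normal((n, 3)) * np.sqrt(resid)
    if retention is not None:
        w2 = rng.random(n) < retention[0]
        w3 = w2 & (rng.random(n) < retention[1])
        y[~w2, 1] = np.nan
        y[~w3, 2] = np.nan
    return y, t, risk, sex


class TestGrowthLoglik:
    def test_matches_brute_force_mvn_with_missing_waves(self):
        y, t, risk, sex = simulate_lgm(n=15, seed=1)
        G = np.array([[0.3, -0.004], [-0.004, 0.002]])
        resid = np.array([0.12, 0.1, 0.09])
        beta = np.array([0.05, -0.1, 0.2, -0.015, -0.006, 0.012])
        params = GrowthParams(beta=beta, G=G, resid=resid,
                              stage="random_slope", predictors=("risk", "sex"))
        U = np.column_stack([risk, sex])
        got = growth_loglik(params, y, t, U)
        total = 0.0
        for i in range(15):
            o = ~np.isnan(y[i])
            Z = np.column_stack([np.ones(o.sum()), t[i, o]])
            V = Z @ G @ Z.T + np.diag(resid[o])
            X = np.column_stack([np.ones(o.sum()), np.full(o.sum(), risk[i]),
                                 np.full(o.sum(), sex[i]),
                                 t[i, o], risk[i] * t[i, o], sex[i] * t[i, o]])
            total += multivariate_normal.logpdf(y[i, o], X @ beta, V)
        assert got == pytest.approx(total, abs=1e-8)

    def test_compound_symmetry_reduction(self):
        """Zero slope variance/covariance with a common residual is an
        exchangeable (compound-symmetry) covariance; compare against a
        direct construction of that matrix."""
        y, t, _, _ = simulate_lgm(n=12, seed=2, retention=None)
        v0, ve = 0.3, 0.1
        params = GrowthParams(beta=np.array([0.1, -0.02]),
                              G=np.array([[v0, 0.0], [0.0, 0.0]]),
                              resid=np.full(3, ve), stage="fixed_slope")
        got = growth_loglik(params, y, t)
        V = np.full((3, 3), v0) + ve * np.eye(3)
        total = 0.0
        for i in range(12):
            mean = 0.1 - 0.02 * t[i]
            total += multivariate_normal.logpdf(y[i], mean, V)
        assert got == pytest.approx(total, abs=1e-8)

    def test_degenerate_variances_raise(self):
        t = np.tile(np.array([-2.0, 0.0, 2.0]), (5, 1))
        y = 0.5 - 0.01 * t  # exactly on the mean line
        params = GrowthParams(beta=np.array([0.5, -0.01]),
                              G=np.zeros((2, 2)), resid=np.zeros(3),
                              stage="fixed_slope")
        with pytest.raises(np.linalg.LinAlgError, match="diverges"):
            growth_loglik(params, y, t)


class TestFitGrowth:
    def test_matches_statsmodels_mixedlm_on_complete_data(self):
        """Independent cross-check: same random-slope model fitted by
        statsmodels MixedLM (ML, common residual) on complete data."""
        import pandas as pd
        import statsmodels.formula.api as smf

        y, t, risk, sex = simulate_lgm(n=250, seed=3, retention=None)
        fit = fit_growth(y, t, stage="random_slope",
                         predictors={"risk": risk, "sex": sex},
                         per_wave_resid=False)
        long = pd.DataFrame({
            "y": y.ravel(), "t": t.ravel(),
            "risk": np.repeat(risk, 3), "sex": np.repeat(sex, 3),
            "pid": np.repeat(np.arange(250), 3)})
        sm_fit = smf.mixedlm("y ~ risk + sex + t + risk:t + sex:t", long,
                             groups="pid", re_formula="~t").fit(reml=False)
        ours = dict(zip(fit.labels, fit.beta))
        assert ours["intercept"] == pytest.approx(sm_fit.params["Intercept"], abs=2e-3)
        assert ours["risk_on_intercept"] == pytest.approx(sm_fit.params["risk"], abs=2e-3)
        assert ours["risk_on_slope"] == pytest.approx(sm_fit.params["risk:t"], abs=2e-4)
        assert ours["sex_on_slope"] == pytest.approx(sm_fit.params["sex:t"], abs=2e-4)
        assert fit.logL == pytest.approx(sm_fit.llf, abs=0.05)

    def test_permuted_risk_has_null_effect(self):
        y, t, risk, sex = simulate_lgm(n=400, seed=4)
        rng = np.random.default_rng(5)
        cond = fit_conditional_growth(y, t, rng.permutation(risk), sex,
                                      risk_name="risk")
        b, se, p = cond.risk_on_slope
        assert abs(b / se) < 4.0

    def test_constant_sex_dropped_with_reduced_k(self):
        y, t, risk, _ = simulate_lgm(n=120, seed=6)
        with pytest.warns(UserWarning, match="constant"):
            cond = fit_conditional_growth(y, t, risk, np.ones(120),
                                          risk_name="risk")
        assert cond.fit.k == 10  # 12 minus the two sex coefficients
        assert "sex_on_slope" not in cond.fit.labels
        assert np.isnan(cond.sex_on_slope[0])

    def test_collinear_predictors_raise(self):
        y, t, risk, _ = simulate_lgm(n=80, seed=7)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_growth(y, t, stage="random_slope",
                       predictors={"risk": risk, "double": 2.0 * risk})

    def test_single_wave_data_not_identified_for_slope(self):
        y, t, _, _ = simulate_lgm(n=50, seed=8, retention=None)
        y[:, 1:] = np.nan
        with pytest.raises(ValueError, match="not identified"):
            fit_growth(y, t, stage="random_slope")

    def test_age_shift_with_matching_centering_is_invariant(self):
        y, t, risk, sex = simulate_lgm(n=150, seed=9)
        a = fit_conditional_growth(y, t, risk, sex, risk_name="risk")
        b = fit_conditional_growth(y, (t + 80.0) - 80.0, risk, sex,
                                   risk_name="risk")
        assert np.allclose(a.fit.beta, b.fit.beta, atol=1e-6)

    def test_estimator_bias_shrinks_with_n(self):
        reps = 40
        bias = {}
        for n in (150, 600):
            est = [fit_conditional_growth(
                *simulate_lgm(n=n, seed=10_000 + n + r)
            ).risk_on_slope[0] for r in range(reps)]
            bias[n] = np.mean(est) - (-0.007)
        sd_small = 0.004 / np.sqrt(reps)  # generous per-rep sd bound
        assert abs(bias[600]) <= abs(bias[150]) + 3 * sd_small


class TestLadder:
    def test_loglik_monotone_and_random_slope_detected(self):
        y, t, risk, sex = simulate_lgm(n=600, seed=11)
        stages = model_building_ladder(y, t)
        names = [s.stage for s in stages]
        assert names == ["null", "random_intercept", "fixed_slope",
                         "random_slope", "fixed_quadratic"]
        lls = [s.fit.logL for s in stages]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))
        for s in stages[1:]:
            assert s.delta_chi2 >= 0
        random_slope = stages[3]
        assert random_slope.p < 0.05
        assert random_slope.boundary_caveat

    def test_flat_data_keeps_null_acceptable(self):
        rng = np.random.default_rng(12)
        n = 200
        t = np.column_stack([rng.uniform(-20, 10, n)] * 3) + [0, 4.4, 8.9]
        y = 0.3 + rng.standard_normal((n, 3)) * 0.4  # no growth, no spread
        stages = model_building_ladder(y, t)
        ri = stages[1]
        # boundary test: variance addition should not look significant
        assert ri.p > 0.01


class TestStratified:
    def test_single_stratum_reduces_to_conditional(self):
        y, t, risk, sex = simulate_lgm(n=200, seed=13)
        table = fit_stratified(y, t, risk, sex, np.repeat("all", 200),
                               risk_name="risk")
        cond = fit_conditional_growth(y, t, risk, sex, risk_name="risk")
        assert table.logL == pytest.approx(cond.fit.logL, abs=1e-6)
        assert table.k == cond.fit.k
        got = table.strata["all"].risk_on_slope[0]
        assert got == pytest.approx(cond.risk_on_slope[0], abs=1e-8)

    def test_identical_strata_close_to_pooled_fit(self):
        y, t, risk, sex = simulate_lgm(n=400, seed=14)
        strata = np.where(np.arange(400) % 2 == 0, "a", "b")
        table = fit_stratified(y, t, risk, sex, strata, risk_name="risk")
        pooled = fit_conditional_growth(y, t, risk, sex, risk_name="risk")
        # free (two-group) model cannot fit worse than the pooled one,
        # and under the null the improvement is within LRT acceptance
        delta = 2.0 * (table.logL - pooled.fit.logL)
        from scipy.stats import chi2
        assert delta >= -1e-6
        assert delta < chi2.ppf(0.999, table.k - pooled.fit.k)

    def test_planted_stratum_effect_recovered(self):
        ya, ta, ra, sa = simulate_lgm(n=300, seed=15,
                                      beta_risk=(-0.15, -0.010))
        yb, tb, rb, sb = simulate_lgm(n=300, seed=16, beta_risk=(0.0, 0.0))
        y = np.vstack([ya, yb])
        t = np.vstack([ta, tb])
        risk = np.concatenate([ra, rb])
        sex = np.concatenate([sa, sb])
        strata = np.array(["hit"] * 300 + ["null"] * 300)
        table = fit_stratified(y, t, risk, sex, strata, risk_name="risk")
        hit = table.strata["hit"].risk_on_slope
        null = table.strata["null"].risk_on_slope
        assert hit[0] < -0.005 and hit[2] < 0.05
        assert abs(null[0]) < 0.004

    def test_low_n_stratum_flagged(self):
        y, t, risk, sex = simulate_lgm(n=60, seed=17, retention=None)
        strata = np.array(["big"] * 50 + ["tiny"] * 10)
        table = fit_stratified(y, t, risk, sex, strata, risk_name="risk")
        assert any(f.startswith("low_n") for f in table.strata["tiny"].fit.flags)


class TestInformationCriteria:
    def test_printed_row_identities(self):
        m2ll, aic, bic = information_criteria(-700.892, 12, 524)
        assert m2ll == pytest.approx(1401.784, abs=5e-4)
        assert aic == pytest.approx(1425.784, abs=5e-4)
        assert bic == pytest.approx(1476.922, abs=5e-4)

    def test_ln1_is_zero(self):
        # BIC's k*ln(n) penalty vanishes at n = 1
        m2ll, aic, bic = information_criteria(0.0, 1, 1)
        assert (m2ll, aic, bic) == (0.0, 2.0, 0.0)

    def test_guards(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 0, 10)
        with pytest.raises(ValueError):
            information_criteria(0.0, 2, 0)
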