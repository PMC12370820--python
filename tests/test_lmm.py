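"""Random-intercept LMM: likelihood, CIs, LRT, selection, regional maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from iceegnorm import (
    RandomInterceptRegressor,
    SimulationParams,
    fit_lmm,
    fit_regional,
    icc,
    lrt,
    marginal_r2,
    mirror_table,
    profile_ci,
    select_model,
    simulate_cohort,
    wald_ci,
)


def sim_rows(seed, n_hospitals=5, subjects=100, b_age=4e-4, b_sex=0.0,
             sigma_u=0.02, sigma_e=0.05, band="alpha"):
    slopes = dict(SimulationParams().band_age_slopes)
    sexes = dict(SimulationParams().band_sex_offsets)
    slopes[band] = b_age
    sexes[band] = b_sex
    p = SimulationParams(band_age_slopes=slopes, band_sex_offsets=sexes,
                         hospital_sd=sigma_u, residual_sd=sigma_e,
                         n_hospitals=n_hospitals,
                         subjects_per_hospital=subjects, seed=seed)
    table, truth = simulate_cohort(p)
    return table.band_rows(band), truth


# ---------------------------------------------------------------------------
# independent likelihood oracles (explicit covariance matrices)


def oracle_loglik_ml(X, y, codes, beta, s2u, s2e):
    n = len(y)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    V = s2e * np.eye(n) + s2u * (Z @ Z.T)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi) + logdet
                   + r @ linalg.solve(V, r, assume_a="pos"))


def oracle_loglik_reml(X, y, codes, s2u, s2e):
    n, p = X.shape
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    V = s2e * np.eye(n) + s2u * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetX = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX
                   + r @ Vi @ r)


@pytest.fixture(scope="module")
def small_fixture():
    rng = np.random.default_rng(42)
    codes = np.repeat(np.arange(4), [12, 10, 10, 8])
    age = rng.uniform(5, 65, 40)
    u = rng.normal(0, 0.5, 4)
    y = 1.0 + 0.05 * age + u[codes] + rng.normal(0, 1.0, 40)
    X = np.column_stack([np.ones(40), age])
    return X, y, codes


class TestLikelihoodOracle:
    def test_ml_optimum_beats_dense_grid(self, small_fixture):
        X, y, codes = small_fixture
        est = RandomInterceptRegressor(method="ml").fit(X[:, 1:], y,
                                                        groups=codes)
        betas0 = np.linspace(est.intercept_ - 1.5, est.intercept_ + 1.5, 7)
        betas1 = np.linspace(est.coef_[0] - 0.03, est.coef_[0] + 0.03, 7)
        s2us = np.linspace(1e-6, 1.5, 10)
        s2es = np.linspace(0.4, 2.5, 10)
        best = -np.inf
        arg = None
        for b0 in betas0:
            for b1 in betas1:
                for su in s2us:
                    for se in s2es:
                        ll = oracle_loglik_ml(X, y, codes,
                                              np.array([b0, b1]), su, se)
                        if ll > best:
                            best, arg = ll, (b0, b1, su, se)
        assert est.loglik_ >= best - 1e-9
        # the grid argmax must sit within one grid step of our estimates
        assert abs(arg[0] - est.intercept_) <= np.diff(betas0)[0] + 1e-12
        assert abs(arg[1] - est.coef_[0]) <= np.diff(betas1)[0] + 1e-12
        assert abs(arg[2] - est.sigma2_group_) <= np.diff(s2us)[0] + 1e-12
        assert abs(arg[3] - est.sigma2_resid_) <= np.diff(s2es)[0] + 1e-12

    def test_reml_optimum_beats_dense_grid(self, small_fixture):
        X, y, codes = small_fixture
        est = RandomInterceptRegressor(method="reml").fit(X[:, 1:], y,
                                                          groups=codes)
        best = -np.inf
        arg = None
        s2us = np.linspace(1e-6, 1.5, 25)
        s2es = np.linspace(0.4, 2.5, 25)
        for su in s2us:
            for se in s2es:
                ll = oracle_loglik_reml(X, y, codes, su, se)
                if ll > best:
                    best, arg = ll, (su, se)
        assert est.loglik_ >= best - 1e-9
        assert abs(arg[0] - est.sigma2_group_) <= np.diff(s2us)[0] + 1e-12
        assert abs(arg[1] - est.sigma2_resid_) <= np.diff(s2es)[0] + 1e-12

    def test_matches_statsmodels_mixedlm(self):
        rows, _ = sim_rows(seed=3)
        fit = fit_lmm(rows, ("age",), method="reml")
        import statsmodels.formula.api as smf

        sm = smf.mixedlm("rbp ~ age", rows,
                         groups=rows["hospital"]).fit(reml=True)
        assert fit.coefficients["age"] == pytest.approx(sm.params["age"],
                                                        rel=1e-4)
        assert fit.sigma2_residual == pytest.approx(sm.scale, rel=1e-3)
        assert fit.sigma2_hospital == pytest.approx(
            float(sm.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-5)

    def test_reduces_to_ols_with_one_row_per_group(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 30)
        y = 2.0 + 0.7 * x + rng.normal(0, 1, 30)
        est = RandomInterceptRegressor(method="ml").fit(
            x, y, groups=np.arange(30))
        ols = np.linalg.lstsq(np.column_stack([np.ones(30), x]), y,
                              rcond=None)[0]
        assert est.intercept_ == pytest.approx(ols[0], rel=1e-6)
        assert est.coef_[0] == pytest.approx(ols[1], rel=1e-6)

    def test_permutation_invariance(self, small_fixture):
        X, y, codes = small_fixture
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        a = RandomInterceptRegressor().fit(X[:, 1:], y, groups=codes)
        b = RandomInterceptRegressor().fit(X[perm, 1:], y[perm],
                                           groups=codes[perm])
        assert a.loglik_ == pytest.approx(b.loglik_, abs=1e-7)
        assert a.coef_[0] == pytest.approx(b.coef_[0], rel=1e-7)


class TestFitBehaviour:
    def test_boundary_truth_flags_singular(self):
        # sigma_u = 0 in truth: the boundary estimate lambda-hat = 0 occurs
        # with asymptotic probability 1/2 (half point-mass of the boundary
        # MLE), so the singular flag fires in about half the replicates and
        # the estimated hospital variance is near zero throughout
        flags, ratios = [], []
        for rep in range(200):
            rows, _ = sim_rows(seed=3000 + rep, n_hospitals=5, subjects=10,
                               sigma_u=0.0)
            f = fit_lmm(rows, ("age",))
            flags.append(f.singular)
            ratios.append(f.sigma2_hospital / f.sigma2_residual)
        assert 0.40 <= np.mean(flags)
        assert np.median(ratios) < 1e-3
        assert np.quantile(ratios, 0.9) < 0.15

    def test_parameter_recovery_within_3_se(self):
        rows, _ = sim_rows(seed=21, n_hospitals=5, subjects=100, b_age=4e-4)
        fit = fit_lmm(rows, ("age",))
        assert abs(fit.coefficients["age"] - 4e-4) <= 3 * fit.se["age"]

    def test_aic_bic_consistent_with_loglik(self):
        rows, _ = sim_rows(seed=2)
        fit = fit_lmm(rows, ("age", "sex"), method="ml")
        k = len(fit.coefficients) + 2
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik_ml)
        assert fit.bic == pytest.approx(k * np.log(fit.n) - 2 * fit.loglik_ml)

    def test_single_hospital_warns_and_flags(self):
        rows, _ = sim_rows(seed=4, n_hospitals=1, subjects=40)
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_lmm(rows, ("age",))
        assert fit.singular

    def test_rank_deficient_design_rejected(self):
        rows, _ = sim_rows(seed=4, n_hospitals=3, subjects=10)
        rows = rows.copy()
        rows["age"] = 30.0  # constant age column collides with intercept
        with pytest.raises(np.linalg.LinAlgError):
            fit_lmm(rows, ("age",))

    def test_blups_shrink_towards_zero(self):
        rows, truth = sim_rows(seed=8, n_hospitals=10, subjects=50,
                               sigma_u=0.02)
        fit = fit_lmm(rows, ("age",))
        u_true = truth["hospital_effects"]["alpha"]
        # BLUPs correlate with the realised hospital intercepts
        common = fit.hospital_effects.index
        r = np.corrcoef(fit.hospital_effects[common], u_true[common])[0, 1]
        assert r > 0.8


class TestVarianceDecomposition:
    def test_icc_is_the_variance_ratio(self):
        rows, _ = sim_rows(seed=2)
        fit = fit_lmm(rows, ("age",))
        assert icc(fit) == pytest.approx(
            fit.sigma2_hospital / (fit.sigma2_hospital + fit.sigma2_residual))
        fit.sigma2_hospital = fit.sigma2_residual
        assert icc(fit) == pytest.approx(0.5)
        fit.sigma2_hospital = 0.0
        assert icc(fit) == 0.0

    def test_icc_recovery_at_one_quarter(self):
        # sigma_u^2 = 1, sigma_e^2 = 3 on a 20 x 50 design -> ICC 0.25
        vals = []
        for rep in range(15):
            rows, _ = sim_rows(seed=3100 + rep, n_hospitals=20, subjects=50,
                               sigma_u=1.0, sigma_e=np.sqrt(3.0), b_age=0.0)
            vals.append(icc(fit_lmm(rows, ())))
        # Monte-Carlo SE of the mean ICC over 15 replicates is ~0.013
        assert np.mean(vals) == pytest.approx(0.25, abs=0.04)

    def test_marginal_r2_null_is_zero(self):
        rows, _ = sim_rows(seed=2)
        assert marginal_r2(fit_lmm(rows, ())) == 0.0

    def test_marginal_r2_plugin_truth(self):
        # var(b_age * age) = 1 with age ~ U(5,65); sigma_u^2=1, sigma_e^2=2
        b = 1.0 / np.sqrt(3600.0 / 12.0)
        rows, _ = sim_rows(seed=13, n_hospitals=20, subjects=50,
                           b_age=b, sigma_u=1.0, sigma_e=np.sqrt(2.0))
        fit = fit_lmm(rows, ("age",))
        assert marginal_r2(fit) == pytest.approx(0.25, abs=0.05)
        assert 0.0 <= marginal_r2(fit) <= 1.0


class TestIntervals:
    def test_profile_interval_contains_estimate(self):
        rows, _ = sim_rows(seed=7)
        fit = fit_lmm(rows, ("age",))
        lo, hi = profile_ci(fit, "age")
        assert lo < fit.coefficients["age"] < hi

    def test_profile_close_to_wald_on_large_balanced_data(self):
        rows, _ = sim_rows(seed=17, n_hospitals=15, subjects=100)
        fit = fit_lmm(rows, ("age",))
        plo, phi = profile_ci(fit, "age")
        wlo, whi = wald_ci(fit, "age")
        assert (phi - plo) == pytest.approx(whi - wlo, rel=0.10)

    def test_unknown_parameter_rejected(self):
        rows, _ = sim_rows(seed=7)
        fit = fit_lmm(rows, ("age",))
        with pytest.raises(KeyError):
            profile_ci(fit, "sex")


class TestLRT:
    def test_identically_zero_covariate_gives_null_test(self):
        rows, _ = sim_rows(seed=5, n_hospitals=4, subjects=30)
        rows = rows.copy()
        rows["sex"] = "female"  # sex dummy identically zero
        f0 = fit_lmm(rows, (), method="ml")
        with pytest.warns(UserWarning, match="zero covariate"):
            f1 = fit_lmm(rows, ("sex",), method="ml")
        stat, p = lrt(f0, f1)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_strong_age_effect_detected(self):
        rows, _ = sim_rows(seed=6, b_age=2e-3)
        stat, p = lrt(fit_lmm(rows, (), method="ml"),
                      fit_lmm(rows, ("age",), method="ml"))
        assert p < 1e-3

    def test_reml_fits_rejected(self):
        rows, _ = sim_rows(seed=5, n_hospitals=4, subjects=20)
        with pytest.raises(ValueError, match="ML"):
            lrt(fit_lmm(rows, ()), fit_lmm(rows, ("age",)))

    def test_non_nested_pair_rejected(self):
        rows, _ = sim_rows(seed=5, n_hospitals=4, subjects=20)
        with pytest.raises(ValueError, match="nested"):
            lrt(fit_lmm(rows, ("age",), method="ml"),
                fit_lmm(rows, ("sex",), method="ml"))


class TestSelectModel:
    def test_planted_age_effect_selects_age_model(self):
        hits = 0
        for rep in range(10):
            rows, _ = sim_rows(seed=500 + rep, n_hospitals=10, subjects=50,
                               b_age=6e-4)
            hits += select_model(rows).chosen_name == "age"
        assert hits >= 6

    def test_no_effects_selects_null_model(self):
        hits = 0
        for rep in range(10):
            rows, _ = sim_rows(seed=700 + rep, n_hospitals=10, subjects=50,
                               b_age=0.0)
            hits += select_model(rows).chosen_name == "null"
        assert hits >= 6

    def test_split_metrics_tie_break_to_simpler(self):
        # at this seed AIC prefers the full model while BIC and the CI/LRT
        # indicators prefer age: the simpler age model must win
        rows, _ = sim_rows(seed=3)
        sel = select_model(rows)
        assert sel.summary.loc[sel.summary["model"] == "full",
                               "aic"].iloc[0] < \
            sel.summary.loc[sel.summary["model"] == "age", "aic"].iloc[0]
        assert sel.chosen_name == "age"
        assert any("tie-break" in line for line in sel.trace)

    def test_interaction_candidate_off_by_default(self):
        rows, _ = sim_rows(seed=3, n_hospitals=4, subjects=25)
        sel = select_model(rows)
        assert set(sel.fits_ml) == {"null", "age", "sex", "full"}
        sel2 = select_model(rows, include_interaction=True)
        assert "interaction" in sel2.fits_ml


@pytest.fixture(scope="module")
def regional_table():
    probs = {f"roi{i:02d}": p for i, p in enumerate([0.9, 0.6, 0.3, 0.05])}
    p = SimulationParams(roi_probs=probs, n_hospitals=8,
                         subjects_per_hospital=25, seed=77)
    table, _ = simulate_cohort(p)
    return table


class TestRegionalMaps:
    def test_rows_ordered_by_sample_size(self, regional_table):
        m = fit_regional(regional_table, "alpha")
        assert list(m["n"]) == sorted(m["n"], reverse=True)

    def test_sparse_roi_marked_unfitted(self, regional_table):
        m = fit_regional(regional_table, "alpha", min_rows=50)
        sparse = m[~m["fitted"]]
        assert len(sparse) >= 1
        assert (sparse["reason"].str.contains("fewer than")).all()
        assert sparse["b_age"].isna().all()

    def test_ci_flag_matches_stored_endpoints(self, regional_table):
        m = fit_regional(regional_table, "delta")
        fitted = m[m["fitted"]]
        expected = (fitted["ci_lo"] <= 0) & (0 <= fitted["ci_hi"])
        assert (fitted["ci_contains_zero"].astype(bool) ==
                expected).all()

    def test_single_hospital_roi_flagged_singular(self):
        p = SimulationParams(n_hospitals=1, subjects_per_hospital=30, seed=9)
        table, _ = simulate_cohort(p)
        m = fit_regional(table, "alpha")
        assert m.iloc[0]["singular"]

    def test_unmirrored_table_rejected(self, rng):
        from iceegnorm.synthdata import standard_region_names
        from conftest import make_metadata, make_roi_vectors

        from iceegnorm import build_normative_table

        subjects = [f"s{i}" for i in range(12)]
        vecs = make_roi_vectors(subjects, ["Left-insula"], rng)
        table = build_normative_table(vecs, make_metadata(subjects, rng),
                                      regions=standard_region_names())
        with pytest.raises(ValueError, match="mirrored"):
            fit_regional(table, "alpha")
        m = fit_regional(mirror_table(table), "alpha", min_rows=5)
        assert (m.loc[m["roi"] == "insula", "n"] == 12).all()
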