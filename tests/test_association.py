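"""Gamma log-link regression: oracle equivalence, inference calibration,
stratified basic models, pattern tables and descriptives."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import moveability as mv
from moveability.association import (ModelSpec, build_design,
                                     basic_models_table, descriptive_table,
                                     fit_basic_models, fit_gamma_log,
                                     gamma_loglik, run_pattern_analysis)


def direct_ml_oracle(X, y, start_beta, start_lognu):
    """Independent full-likelihood maximization (gradient-based, tight)."""
    from scipy.special import digamma

    def nll(p):
        mu = np.exp(X @ p[:-1])
        return -gamma_loglik(y, mu, math.exp(p[-1]))

    def grad(p):
        beta, nu = p[:-1], math.exp(p[-1])
        mu = np.exp(X @ beta)
        g_beta = -nu * (X.T @ (y / mu - 1.0))
        g_lognu = -nu * float(np.sum(
            math.log(nu) + 1.0 - digamma(nu) + np.log(y / mu) - y / mu))
        return np.concatenate([g_beta, [g_lognu]])

    p0 = np.concatenate([start_beta, [start_lognu]])
    res = optimize.minimize(nll, p0, jac=grad, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 10_000})
    return res.x[:-1], math.exp(res.x[-1])


def _cohort(n=400, seed=0, **beta_overrides):
    cfg = mv.CohortConfig(n_children=n, seed=seed)
    cfg.true_beta.update(beta_overrides)
    df, _ = mv.generate_cohort(cfg)
    return df


class TestFitGammaLog:
    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(shape=8.0, scale=60.0 / 8.0, size=2000)
        df = pd.DataFrame({"mvpa_min_per_day": y, "age_group": "school",
                           "sex": "girl"})
        spec = ModelSpec(covariates=[], stratum=("school", "all"))
        fit = fit_gamma_log(spec, df)
        se = fit.terms.loc["intercept", "se"]
        assert abs(math.log(60.0) - fit.terms.loc["intercept", "beta"]) < 3 * se
        assert fit.shape == pytest.approx(8.0, rel=0.15)

    def test_matches_direct_likelihood_oracle(self):
        df = _cohort(seed=3)
        spec = ModelSpec(stratum=("school", "all"))
        fit = fit_gamma_log(spec, df)
        X, y, _ = build_design(df, spec)
        beta0 = fit.terms.beta.to_numpy() + 0.03  # start slightly off
        ob, onu = direct_ml_oracle(X, y, beta0, math.log(fit.shape) + 0.1)
        assert np.abs(ob - fit.terms.beta.to_numpy()).max() < 1e-6
        assert onu == pytest.approx(fit.shape, abs=1e-4)
        # AIC conventions differ by exactly the shape parameter
        assert fit.aic - fit.aic_excl_shape == pytest.approx(2.0)

    def test_season_effect_ci_coverage(self):
        # planted multiplicative season effect 1.17 in a school-age design
        covered = 0
        n_seeds = 50
        for seed in range(n_seeds):
            df = _cohort(n=400, seed=seed)
            fit = fit_gamma_log(ModelSpec(stratum=("school", "all")), df)
            lo, hi = fit.conf_int("season_spring_summer")
            covered += lo <= 1.17 <= hi
        assert covered >= 0.9 * n_seeds

    def test_null_safety_effect_type_one_error(self):
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            df = _cohort(n=400, seed=10_000 + seed, safety=0.0)
            fit = fit_gamma_log(ModelSpec(stratum=("school", "all")), df)
            rejections += fit.p_value("safety_concerns") < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.08

    def test_planted_safety_effect_power_in_preschool_girls(self):
        # exp(β) = 0.75 planted; pre-school-girl stratum scaled to ~5× the
        # study's 43 girls
        detected = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = mv.CohortConfig(n_children=860, frac_school_age=0.5,
                                  frac_girls=0.5, seed=20_000 + seed)
            cfg.true_beta["safety"] = math.log(0.75)
            df, _ = mv.generate_cohort(cfg)
            fit = fit_gamma_log(ModelSpec(stratum=("pre_school", "girl")), df)
            detected += (fit.p_value("safety_concerns") < 0.05
                         and fit.exp_beta("safety_concerns") < 1.0)
        assert detected >= 0.8 * n_seeds

    def test_nonpositive_outcome_dropped_with_warning(self):
        df = _cohort(n=100, seed=5)
        df.loc[df.index[:3], "mvpa_min_per_day"] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_gamma_log(ModelSpec(stratum=("school", "all")), df)
        assert fit.n == (df.age_group == "school").sum() - \
            (df.mvpa_min_per_day[df.age_group == "school"] <= 0).sum()


class TestBasicModels:
    def test_strata_partition_cohort(self):
        df = _cohort(seed=7)
        fits = fit_basic_models(df)
        n_all = fits[("school", "all")].n + fits[("pre_school", "all")].n
        assert n_all == len(df)
        assert fits[("school", "boy")].n + fits[("school", "girl")].n == \
            fits[("school", "all")].n

    def test_pooled_coefficient_between_stratum_coefficients(self):
        # no sex interaction in the generator → the pooled school-age
        # coefficient should usually sit between the sex-stratum ones
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df = _cohort(n=600, seed=30_000 + seed)
            fits = fit_basic_models(
                df, strata=[("school", "all"), ("school", "boy"),
                            ("school", "girl")])
            b_all = fits[("school", "all")].terms.loc["season_spring_summer",
                                                      "beta"]
            b_boy = fits[("school", "boy")].terms.loc["season_spring_summer",
                                                      "beta"]
            b_girl = fits[("school", "girl")].terms.loc["season_spring_summer",
                                                        "beta"]
            hits += min(b_boy, b_girl) - 1e-12 <= b_all <= \
                max(b_boy, b_girl) + 1e-12
        assert hits >= 0.7 * n_seeds

    def test_report_table_shape(self):
        df = _cohort(seed=2)
        tbl = basic_models_table(fit_basic_models(df))
        assert set(tbl.columns) >= {"age_group", "sex", "term", "exp_beta",
                                    "p", "aic", "n"}
        # 6 strata × 8 terms (intercept + 7 covariates)
        assert len(tbl) == 6 * 8

    def test_null_covariate_aic_penalty(self):
        # dropping a truly null covariate moves AIC by ≈ the parameter
        # penalty: mean ΔAIC(with − without) in [−0.5, 2.5]
        deltas = []
        for seed in range(100):
            df = _cohort(n=300, seed=40_000 + seed, bmi_z=0.0)
            with_cov = fit_gamma_log(ModelSpec(stratum=("school", "all")), df)
            covs = [c for c in with_cov.terms.index
                    if c not in ("intercept", "bmi_z")]
            without = fit_gamma_log(
                ModelSpec(covariates=covs, stratum=("school", "all")), df)
            deltas.append(with_cov.aic - without.aic)
        assert -0.5 <= float(np.mean(deltas)) <= 2.5


class TestPatternAnalysis:
    def _fake_exposures(self, cohort, measures, distances, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in measures:
            for d in distances:
                vals = rng.normal(5, 1.5, size=len(cohort))
                for cid, v in zip(cohort.child_id, vals):
                    rows.append({"child_id": cid, "kind": "open_space",
                                 "measure": m, "distance_m": d, "value": v})
        return pd.DataFrame(rows)

    def test_grid_completeness(self):
        df = _cohort(n=200, seed=1)
        measures = list(mv.ExposureConfig().measures)
        distances = [500.0, 750.0, 1000.0, 1250.0, 1500.0, 2000.0]
        exp = self._fake_exposures(df, measures, distances)
        pat = run_pattern_analysis(df, exp, strata=[("school", "all")])
        # full grid over requested measures × distances for one layer and
        # one stratum
        assert len(pat) == 7 * 6
        assert not pat.exp_beta.isna().any()
        assert pat.converged.all()

    def test_null_exposure_no_aic_improvement(self):
        deltas = []
        for seed in range(50):
            df = _cohort(n=300, seed=50_000 + seed)
            exp = self._fake_exposures(df, ["simple"], [500.0],
                                       seed=seed)  # independent of MVPA
            basic = fit_gamma_log(ModelSpec(stratum=("school", "all")), df)
            pat = run_pattern_analysis(df, exp, strata=[("school", "all")])
            deltas.append(float(pat.aic.iloc[0]) - basic.aic)
        assert -2.0 <= float(np.mean(deltas)) <= 2.0

    def test_nonconverged_cell_recorded_not_dropped(self):
        df = _cohort(n=200, seed=4)
        exp = self._fake_exposures(df, ["simple"], [500.0])
        exp["value"] = np.nan  # breaks the fit for that cell
        pat = run_pattern_analysis(df, exp, strata=[("school", "all")])
        assert len(pat) == 1
        assert not pat.converged.iloc[0]
        assert np.isnan(pat.exp_beta.iloc[0])


class TestDescriptiveTable:
    def test_identical_records_degenerate_summary(self):
        df = pd.DataFrame({
            "child_id": [f"c{i}" for i in range(8)],
            "age_years": 7.0, "sex": "girl", "age_group": "school",
            "bmi_z": 0.5, "isced": "medium", "safety_concerns": 0,
            "season": "autumn_winter", "valid_weartime_h": 11.0,
            "mvpa_min_per_day": 60.0})
        tbl = descriptive_table(df)
        sub = tbl[(tbl.age_group == "school") & (tbl.sex == "girl")]
        assert (sub[sub.variable == "mvpa_min_per_day"].sd == 0).all()
        medium = sub[(sub.variable == "isced") & (sub.level == "medium")]
        assert medium.pct.iloc[0] == 100.0

    def test_percentages_sum_to_hundred(self):
        df = _cohort(n=300, seed=9)
        tbl = descriptive_table(df)
        for (grp, sex, var), g in tbl[tbl.variable == "isced"].groupby(
                ["age_group", "sex", "variable"]):
            if g.n.sum():
                assert g.pct.sum() == pytest.approx(100.0)

    def test_matches_hand_counted_fixture(self):
        # 20 records with known composition: 12 school (8 girls), 8 pre-school
        rows = []
        for i in range(20):
            school = i < 12
            rows.append({
                "child_id": f"c{i}",
                "age_group": "school" if school else "pre_school",
                "sex": "girl" if (i < 8 or i >= 16) else "boy",
                "age_years": 7.0 if school else 4.0,
                "bmi_z": 1.0 if i % 2 else -1.0,
                "isced": ["low", "medium", "high", "medium"][i % 4],
                "safety_concerns": int(i % 5 == 0),
                "season": "spring_summer" if i % 10 == 0 else "autumn_winter",
                "valid_weartime_h": 10.0,
                "mvpa_min_per_day": 50.0 + i})
        tbl = descriptive_table(pd.DataFrame(rows))
        school_all = tbl[(tbl.age_group == "school") & (tbl.sex == "all")]
        # hand counts: 12 school rows, isced pattern l,m,h,m repeating
        med = school_all[(school_all.variable == "isced")
                         & (school_all.level == "medium")]
        assert med.n.iloc[0] == 6 and med.pct.iloc[0] == pytest.approx(50.0)
        mv_row = school_all[school_all.variable == "mvpa_min_per_day"]
        assert mv_row["mean"].iloc[0] == pytest.approx(np.mean(
            [50.0 + i for i in range(12)]))
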