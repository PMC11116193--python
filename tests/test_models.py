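"""Design construction, closed-form OLS, and the profiled-REML mixed model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import _oracles
from ibisflight import models, synthetic
from ibisflight.models import (DISTANCE_PRESET, GLIDING_PRESET, build_design,
                               fit_lmm_random_intercept, fit_ols,
                               log10_transform, reml_criterion_at)


def _factorial_table(n_per=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for shape in ("cube", "drop"):
        for angle in ("+2", "+6"):
            for _ in range(n_per):
                rows.append({"logger_shape": shape, "wind_angle": angle,
                             "gliding_proportion": rng.uniform(0, 1),
                             "bird": "310"})
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_two_by_two_with_interaction_has_four_columns(self):
        tab = _factorial_table()
        X, y, names = build_design(tab, "gliding_proportion",
                                   {"logger_shape": "cube", "wind_angle": "+2"},
                                   [("logger_shape", "wind_angle")])
        assert names == ["Intercept", "logger_shape[drop]", "wind_angle[+6]",
                         "logger_shape[drop]:wind_angle[+6]"]
        assert X.shape == (20, 4)

    def test_balanced_interaction_column_sums_to_quarter(self):
        tab = _factorial_table(n_per=8)
        X, _, names = build_design(tab, "gliding_proportion",
                                   {"logger_shape": "cube", "wind_angle": "+2"},
                                   [("logger_shape", "wind_angle")])
        assert X[:, names.index("logger_shape[drop]:wind_angle[+6]")].sum() == 8

    def test_two_level_bird_factor_adds_one_column(self):
        tab = _factorial_table()
        tab.loc[::2, "bird"] = "311"
        X, _, names = build_design(tab, "gliding_proportion",
                                   GLIDING_PRESET["factors"],
                                   GLIDING_PRESET["interactions"])
        assert "bird[311]" in names
        assert X.shape[1] == 5

    def test_unseen_reference_level_rejected(self):
        tab = _factorial_table()
        with pytest.raises(ValueError, match="absent"):
            build_design(tab, "gliding_proportion", {"logger_shape": "pyramid"})


class TestFitOLS:
    def test_exact_linear_response_gives_r2_one(self):
        tab = _factorial_table()
        X, _, names = build_design(tab, "gliding_proportion",
                                   {"logger_shape": "cube", "wind_angle": "+2"},
                                   [("logger_shape", "wind_angle")])
        beta = np.array([0.3, 0.1, 0.25, 0.05])
        fit = fit_ols(X, X @ beta, names)
        assert np.allclose(fit.estimates, beta, atol=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        y = rng.normal(size=20)
        fit = fit_ols(X, y)
        beta_ref, se_ref = _oracles.ols_normal_equations(X, y)
        assert np.allclose(fit.estimates, beta_ref, atol=1e-10)
        assert np.allclose(fit.se, se_ref, atol=1e-10)

    def test_matches_statsmodels(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        fit = fit_ols(X, y)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.estimates, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared)
        assert fit.fstat[0] == pytest.approx(ref.fvalue)

    def test_campaign_scale_recovery_within_3_se(self):
        tab = synthetic.simulate_gliding_experiment(seed=101)
        X, y, names = build_design(tab, **{k: GLIDING_PRESET[k] for k in
                                           ("response", "factors")},
                                   interactions=GLIDING_PRESET["interactions"])
        fit = fit_ols(X, y, names)
        eff = synthetic.study.GLIDING_EFFECTS
        truth = {"Intercept": eff["intercept"],
                 "logger_shape[drop]": eff["drop"],
                 "wind_angle[+6]": eff["wind6"],
                 "bird[311]": eff["bird311"],
                 "logger_shape[drop]:wind_angle[+6]": eff["drop_wind6"]}
        for term, est, se in zip(fit.terms, fit.estimates, fit.se):
            assert abs(est - truth[term]) < 3 * se

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            fit_ols(X, np.zeros(10))


class TestFitLMM:
    def _simulate(self, rng, nb=20, per=15, bird_sd=0.4, resid_sd=0.7):
        groups = np.repeat(np.arange(nb), per)
        x1 = rng.normal(size=len(groups))
        x2 = rng.integers(0, 2, len(groups)).astype(float)
        y = (2.0 + 0.5 * x1 - 0.3 * x2 + rng.normal(0, bird_sd, nb)[groups]
             + rng.normal(0, resid_sd, len(groups)))
        return np.column_stack([np.ones(len(y)), x1, x2]), y, groups

    def test_matches_statsmodels_mixedlm(self, rng):
        X, y, groups = self._simulate(rng)
        fit = fit_lmm_random_intercept(X, y, groups)
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert np.allclose(fit.estimates, ref.fe_params, atol=1e-6)
        assert fit.group_var == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                              abs=1e-4)
        assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-4)
        assert np.allclose(fit.se, ref.bse_fe, atol=1e-3)

    def test_balanced_oneway_matches_closed_form(self, rng):
        a, n = 8, 12
        mu, bird_sd, resid_sd = 3.0, 0.6, 0.5
        y_groups = [mu + rng.normal(0, bird_sd)
                    + rng.normal(0, resid_sd, n) for _ in range(a)]
        y = np.concatenate(y_groups)
        groups = np.repeat(np.arange(a), n)
        X = np.ones((len(y), 1))
        fit = fit_lmm_random_intercept(X, y, groups)
        mu_ref, sig_e_ref, sig_b_ref = _oracles.oneway_balanced_reml(y_groups)
        assert fit.estimates[0] == pytest.approx(mu_ref, abs=1e-6)
        assert fit.sigma2 == pytest.approx(sig_e_ref, abs=1e-6)
        assert fit.group_var == pytest.approx(sig_b_ref, abs=1e-6)

    def test_zero_variance_limit_degenerates_to_ols(self, rng):
        # residuals centered within each group: the data carry strictly
        # less between-group spread than any positive variance implies,
        # so REML lands on the boundary and the fit collapses to OLS
        nb, per = 20, 15
        groups = np.repeat(np.arange(nb), per)
        x1 = rng.normal(size=len(groups))
        resid = rng.normal(0, 0.7, len(groups))
        for g in range(nb):
            resid[groups == g] -= resid[groups == g].mean()
        y = 2.0 + 0.5 * x1 + resid
        X = np.column_stack([np.ones(len(y)), x1])
        fit = fit_lmm_random_intercept(X, y, groups)
        ols = fit_ols(X, y)
        assert fit.group_var <= 1e-6
        assert np.allclose(fit.estimates, ols.estimates, atol=1e-6)

    def test_reml_optimum_beats_random_candidates(self, rng):
        X, y, groups = self._simulate(rng)
        fit = fit_lmm_random_intercept(X, y, groups)
        for lam in rng.uniform(0.0, 10.0, 50):
            assert fit.reml <= reml_criterion_at(X, y, groups, lam) + 1e-8

    def test_field_study_scale_recovery(self):
        daily = synthetic.simulate_distance_study(seed=7)
        table, n_excl = log10_transform(daily)
        assert n_excl == 0
        X, y, names = build_design(table, DISTANCE_PRESET["response"],
                                   DISTANCE_PRESET["factors"],
                                   DISTANCE_PRESET["interactions"])
        fit = fit_lmm_random_intercept(X, y, table["bird"].to_numpy(), names)
        truth = synthetic.study.DISTANCE_MODEL_TRUTH
        expect = {"Intercept": truth["intercept"],
                  "attachment[leg_loop]": truth["attachment_leg_loop"],
                  "activity[migration]": truth["activity_migration"],
                  "attachment[leg_loop]:activity[migration]": truth["interaction"]}
        for term, est, se in zip(fit.terms, fit.estimates, fit.se):
            assert abs(est - expect[term]) < 3 * se
        assert fit.n_obs == 1060

    def test_interval_coverage_near_nominal(self):
        """95 % intervals for the attachment effect cover truth 90-99 % of runs."""
        truth = synthetic.study.DISTANCE_MODEL_TRUTH["attachment_leg_loop"]
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            daily = synthetic.simulate_distance_study(seed=10_000 + rep)
            table, _ = log10_transform(daily)
            X, y, names = build_design(table, DISTANCE_PRESET["response"],
                                       DISTANCE_PRESET["factors"],
                                       DISTANCE_PRESET["interactions"])
            fit = fit_lmm_random_intercept(X, y, table["bird"].to_numpy(), names)
            i = names.index("attachment[leg_loop]")
            lo, hi = fit.conf_int(0.95)[i]
            hits += int(lo <= truth <= hi)
        assert 0.90 <= hits / n_rep <= 0.99


class TestLog10Transform:
    def test_values_and_columns(self):
        daily = pd.DataFrame({
            "bird": ["a", "a", "b"], "attachment": ["leg_loop"] * 3,
            "day_type": ["migration", "migration", "stopover"],
            "path_km": [100.0, 50.0, 12.0]})
        table, n_excl = log10_transform(daily)
        assert n_excl == 0
        assert table["log10_km"].iloc[0] == pytest.approx(2.0)
        assert table["log10_km"].iloc[1] == pytest.approx(1.69897, abs=1e-5)
        assert list(table.columns) == ["log10_km", "attachment", "activity", "bird"]

    def test_zero_distance_days_excluded_and_counted(self):
        daily = pd.DataFrame({
            "bird": ["a", "a"], "attachment": ["leg_loop"] * 2,
            "day_type": ["stopover", "migration"],
            "path_km": [0.0, 80.0]})
        table, n_excl = log10_transform(daily)
        assert n_excl == 1
        assert len(table) == 1
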