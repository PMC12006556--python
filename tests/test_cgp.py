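"""Corrected-group-prognosis standardisation: curves, QALYs, cost products."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import trialcea as tc
from trialcea import cgp as cgp_mod
from trialcea import regression_engine as reg
from conftest import random_patients


def _toy_survival_fit(beta_arm=0.5, intercept=4.5, sigma=1.0, extra=None) -> reg.ModelFit:
    names = [f"mu_:{c}" for c in reg.COVARIATE_COLS] + ["mu_:Intercept", "sigma_:Intercept"]
    vals = {n: 0.0 for n in names}
    vals["mu_:arm"] = beta_arm
    vals["mu_:Intercept"] = intercept
    vals["sigma_:Intercept"] = np.log(sigma)
    if extra:
        vals.update(extra)
    params = pd.Series(vals)
    return reg.ModelFit(
        family="lognormal_aft",
        params=params,
        vcov=pd.DataFrame(np.zeros((len(params),) * 2), index=params.index, columns=params.index),
        n_obs=10,
        loglik=0.0,
        aic=0.0,
        bic=0.0,
        age_center=62.7,
        extras={"location_prefix": "mu_:", "log_scale_param": "sigma_:Intercept"},
    )


def _one_patient(arm="swab"):
    pats = pd.DataFrame(
        {
            "patient_id": ["p0"],
            "arm": [arm],
            "age": [62.7],
            "sex": ["male"],
            "n_ulcers": [1],
            "ulcer_area": [2.0],
            "ulcer_duration": [1.0],
        }
    )
    X, _ = reg.make_covariates(pats, age_center=62.7)
    return X


class TestSurvivalCurve:
    def test_median_time_has_half_survival(self):
        fit = _toy_survival_fit(beta_arm=0.0, intercept=np.log(40.0), sigma=0.8)
        X = _one_patient()
        X["sex_male"] = 0.0
        curve = cgp_mod.predict_survival_curve(fit, X.iloc[0], arm=0, grid=np.array([0.0, 40.0]))
        assert curve.surv[0] == 1.0
        assert curve.surv[1] == pytest.approx(0.5, abs=1e-12)

    def test_sigma_zero_limit_is_step_function(self):
        grid = np.array([0.0, 10.0, 39.9, 40.1, 100.0])
        s = cgp_mod.lognormal_survival(np.array([np.log(40.0)]), 0.0, grid)[0]
        assert list(s) == [1.0, 1.0, 1.0, 0.0, 0.0]

    def test_curve_matches_quadrature_of_fitted_density(self):
        """1 - S(t) equals the integrated lognormal density to 1e-6."""
        mu, sigma = np.log(60.0), 0.7
        for t in (5.0, 30.0, 90.0):
            s = cgp_mod.lognormal_survival(np.array([mu]), sigma, np.array([t]))[0, 0]
            cdf, _ = integrate.quad(
                lambda x: stats.lognorm.pdf(x, s=sigma, scale=np.exp(mu)), 0, t
            )
            assert 1.0 - s == pytest.approx(cdf, abs=1e-6)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            cgp_mod.SurvivalCurve("p", 0, [0.0, 1.0, 2.0], [1.0, 0.4, 0.6])
        with pytest.raises(ValueError, match="S\\(0\\)"):
            cgp_mod.SurvivalCurve("p", 0, [0.0, 1.0], [0.9, 0.5])


class TestExpectedQaly:
    @staticmethod
    def flat_curve(value=1.0, horizon=104.0):
        t = np.array([0.0, horizon])
        return cgp_mod.SurvivalCurve("p", 0, t, np.array([1.0, value]))

    def test_full_health_full_survival_one_year_is_one_qaly(self):
        q = cgp_mod.expected_qaly(
            self.flat_curve(), np.array([0.0, 52.0]), np.array([1.0, 1.0]), 52.0
        )
        assert q == pytest.approx(1.0, abs=1e-12)

    def test_half_utility_half_year(self):
        q = cgp_mod.expected_qaly(
            self.flat_curve(), np.array([0.0, 26.0]), np.array([0.5, 0.5]), 26.0
        )
        assert q == pytest.approx(0.25, abs=1e-12)

    def test_piecewise_fixture_matches_dense_quadrature(self):
        """Non-trivial S times interpolated u vs a 10x denser trapezoid."""
        visit_weeks = np.array([0.0, 26.0, 52.0])
        utilities = np.array([0.8, 0.6, 0.3])
        mu, sigma = np.log(70.0), 0.9
        grid = np.arange(0.0, 52.001, 0.5)
        curve = cgp_mod.SurvivalCurve(
            "p", 0, grid, cgp_mod.lognormal_survival(np.array([mu]), sigma, grid)[0]
        )
        q = cgp_mod.expected_qaly(curve, visit_weeks, utilities, 52.0)
        dense = np.arange(0.0, 52.0001, 0.01)
        s = cgp_mod.lognormal_survival(np.array([mu]), sigma, dense)[0]
        u = np.interp(dense, visit_weeks, utilities)
        oracle = np.trapezoid(s * u, dense) / 52.0
        assert q == pytest.approx(oracle, abs=1e-4)

    def test_discounting_scales_second_year_only(self):
        vw = np.array([0.0, 52.0, 104.0])
        u = np.array([1.0, 1.0, 1.0])
        q0 = cgp_mod.expected_qaly(self.flat_curve(), vw, u, 104.0, discount_rate=None)
        q1 = cgp_mod.expected_qaly(self.flat_curve(), vw, u, 104.0, discount_rate=0.035)
        assert q0 == pytest.approx(2.0, abs=1e-9)
        assert q1 == pytest.approx(1.0 + 1.0 / 1.035, abs=1e-9)

    def test_horizon_beyond_visits_is_an_error(self):
        with pytest.raises(ValueError, match="extrapolation"):
            cgp_mod.expected_qaly(
                self.flat_curve(), np.array([0.0, 52.0]), np.array([1.0, 1.0]), 104.0
            )


def _hand_fits(arm_surv=0.5, arm_util=-0.1, arm_ord=0.3, arm_logit=0.4,
               arm_other=100.0, visit_weeks=(0, 4, 12, 26, 39, 52, 104)):
    """Small analytic model set with known coefficients for CGP fixtures."""
    vw = list(visit_weeks)
    surv = _toy_survival_fit(beta_arm=arm_surv, intercept=6.0, sigma=1.0)

    def lmm(outcome, intercept, arm_coef, weeks):
        cols = ["const"] + reg.COVARIATE_COLS
        for w in weeks[1:]:
            cols += [f"week_{w}", f"arm_x_week_{w}"]
        vals = pd.Series(0.0, index=cols)
        vals["const"] = intercept
        vals["arm"] = arm_coef
        return reg.ModelFit(
            family="linear_mixed",
            params=vals,
            vcov=pd.DataFrame(np.zeros((len(vals),) * 2), index=vals.index, columns=vals.index),
            n_obs=10, loglik=0.0, aic=0.0, bic=0.0, age_center=62.7,
            extras={"outcome": outcome, "visit_weeks": weeks, "re_var": 0.0, "resid_var": 1.0},
        )

    util = lmm("utility", 0.6, arm_util, vw)
    other = lmm("other_cost", 500.0, arm_other, vw[1:])
    ord_names = reg.COVARIATE_COLS + ["th0", "th1", "th2"]
    ord_vals = pd.Series(0.0, index=ord_names)
    ord_vals["arm"] = arm_ord
    ord_vals["th0"], ord_vals["th1"], ord_vals["th2"] = 1.0, np.log(1.0), np.log(1.0)
    ordinal = reg.ModelFit(
        family="ordinal_logit",
        params=ord_vals,
        vcov=pd.DataFrame(np.zeros((len(ord_vals),) * 2), index=ord_vals.index, columns=ord_vals.index),
        n_obs=10, loglik=0.0, aic=0.0, bic=0.0, age_center=62.7,
        extras={"categories": list(reg.HOSP_CATEGORIES), "n_covariates": len(reg.COVARIATE_COLS)},
    )
    lg_names = ["const"] + reg.COVARIATE_COLS
    lg_vals = pd.Series(0.0, index=lg_names)
    lg_vals["const"], lg_vals["arm"] = -0.5, arm_logit
    logit = reg.ModelFit(
        family="logit",
        params=lg_vals,
        vcov=pd.DataFrame(np.zeros((len(lg_vals),) * 2), index=lg_vals.index, columns=lg_vals.index),
        n_obs=10, loglik=0.0, aic=0.0, bic=0.0, age_center=62.7,
        extras={"outcome": "prescribed"},
    )
    return tc.FittedModels(
        survival=surv, utility=util, hospitalisation=ordinal,
        antibiotics=logit, other_cost=other,
    )


ASSUME = tc.CostAssumptions(
    hosp_category_costs={"other": 2000.0, "minor_amp_or_revasc": 7000.0, "major_amp": 12878.0},
    expected_course_cost=100.0,
)


class TestExpectedEventCosts:
    def test_zero_probabilities_give_zero_event_costs(self):
        fits = _hand_fits(arm_ord=0.0, arm_logit=0.0, arm_other=0.0)
        # push category to 'none' and prescription probability to ~0
        fits.hospitalisation.params["th0"] = 40.0
        fits.antibiotics.params["const"] = -40.0
        X = _one_patient()
        out = tc.expected_event_costs(
            fits, X, [0, 4, 12, 26, 39, 52, 104], 52, ASSUME
        )
        assert out["hospitalisation"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert out["antibiotics"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_single_period_hand_arithmetic(self):
        """P(major amp) = 0.1 at 12,878 pounds with alive-weight 1 -> 1,287.80."""
        fits = _hand_fits(arm_surv=0.0, arm_ord=0.0)
        # survival ~ 1 over the window
        fits.survival.params["mu_:Intercept"] = 20.0
        # cuts (logit(0.9), +1e-9, +2e-9): P(none)=0.9, P(major)=0.1, rest ~ 0
        p = fits.hospitalisation.params
        p["th0"] = stats.logistic.ppf(0.9)
        p["th1"] = np.log(1e-9)
        p["th2"] = np.log(1e-9)
        fits.antibiotics.params["const"] = -40.0
        X = _one_patient()
        out = tc.expected_event_costs(fits, X, [0, 4], 4, ASSUME)
        assert out["hospitalisation"].iloc[0] == pytest.approx(1287.8, rel=1e-3)

    def test_misaligned_horizon_rejected(self):
        fits = _hand_fits()
        with pytest.raises(ValueError, match="boundary"):
            tc.expected_event_costs(fits, _one_patient(), [0, 4, 12], 10, ASSUME)

    def test_intercept_only_logit_reproduces_observed_mean(self):
        """With an intercept-only prescription model the expected antibiotic
        cost collapses to p-hat x course cost x n periods."""
        fits = _hand_fits(arm_surv=0.0, arm_logit=0.0)
        fits.survival.params["mu_:Intercept"] = 20.0
        phat = 0.37
        fits.antibiotics.params["const"] = stats.logistic.ppf(phat)
        fits.hospitalisation.params["th0"] = 40.0
        X = _one_patient()
        out = tc.expected_event_costs(fits, X, [0, 4, 12, 26], 26, ASSUME)
        assert out["antibiotics"].iloc[0] == pytest.approx(
            phat * ASSUME.expected_course_cost * 3, rel=1e-9
        )


class TestCgpAverage:
    def test_population_of_one_equals_patient_prediction(self):
        fits = _hand_fits()
        pats = pd.DataFrame(
            {
                "patient_id": ["p0"],
                "arm": ["tissue"],
                "age": [62.7],
                "sex": ["female"],
                "n_ulcers": [1],
                "ulcer_area": [2.0],
                "ulcer_duration": [1.0],
            }
        )
        out = tc.cgp_average(fits, pats, arm=1, horizon=52, assumptions=ASSUME)
        ev = cgp_mod.CgpEvaluator(fits, pats, ASSUME)
        single = ev.outcome(1, 52)
        assert out.qaly == pytest.approx(single.qaly)
        assert out.total_cost == pytest.approx(single.total_cost)

    def test_linear_submodel_cgp_equals_marginal_prediction_at_means(self, fitted_models, analysis_inputs):
        """For the linear utility model, averaging patient-level predictions
        equals predicting at the covariate means (collapsibility, 1e-8)."""
        fits = fitted_models
        pats = analysis_inputs.patients
        X, _ = reg.make_covariates(pats, age_center=fits.utility.age_center)
        X1 = X.copy()
        X1["arm"] = 1.0
        n = len(X1)
        pred = reg.predict_lmm(
            fits.utility, X1, np.full(n, 52), include_random_effect=False
        )
        Xbar = X1.mean().to_frame().T
        Xbar.index = ["mean"]
        at_mean = reg.predict_lmm(
            fits.utility, Xbar, np.array([52]), include_random_effect=False
        )
        assert pred.mean() == pytest.approx(at_mean[0], abs=1e-8)

    def test_counterfactual_symmetry(self):
        """Relabelling arms (and negating every arm coefficient) leaves the
        absolute incremental QALY and cost unchanged."""
        pats = random_patients(40, np.random.default_rng(21))
        fits = _hand_fits(arm_surv=0.4, arm_util=-0.08, arm_ord=0.25,
                          arm_logit=0.3, arm_other=120.0)
        flipped = _hand_fits(arm_surv=-0.4, arm_util=0.08, arm_ord=-0.25,
                             arm_logit=-0.3, arm_other=-120.0)
        # absorb the arm main effects into the intercepts / thresholds
        flipped.survival.params["mu_:Intercept"] += 0.4
        flipped.utility.params["const"] += -0.08
        flipped.other_cost.params["const"] += 120.0
        flipped.antibiotics.params["const"] += 0.3
        flipped.hospitalisation.params["th0"] -= 0.25
        t1, s1 = tc.cgp_contrast(fits, pats, 52, ASSUME)
        t2, s2 = tc.cgp_contrast(flipped, pats, 52, ASSUME)
        assert abs(t1.qaly - s1.qaly) == pytest.approx(abs(t2.qaly - s2.qaly), abs=1e-9)
        assert abs(t1.total_cost - s1.total_cost) == pytest.approx(
            abs(t2.total_cost - s2.total_cost), abs=1e-6
        )

    def test_qaly_bounds_and_dead_population(self):
        fits = _hand_fits()
        pats = random_patients(10, np.random.default_rng(22))
        out = tc.cgp_average(fits, pats, arm=0, horizon=104, assumptions=ASSUME)
        assert 0.0 <= out.qaly <= 104 / 52
        dead = _hand_fits()
        dead.survival.params["mu_:Intercept"] = -30.0
        dead.survival.params["mu_:arm"] = 0.0
        out0 = tc.cgp_average(dead, pats, arm=0, horizon=104, assumptions=ASSUME)
        # instant death: the QALY vanishes up to the trapezoid's first
        # half-step (S(0)=1 by convention, grid step 0.1 weeks)
        assert out0.qaly <= 0.1 / 52 / 2 + 1e-12

    def test_total_cost_non_decreasing_in_horizon(self, fitted_models, analysis_inputs):
        costs = [
            tc.cgp_average(
                fitted_models, analysis_inputs.patients, 1, h, analysis_inputs.assumptions
            ).total_cost
            for h in (26, 52, 104)
        ]
        assert costs[0] <= costs[1] <= costs[2]

    def test_component_totals_add_up(self, fitted_models, analysis_inputs):
        out = tc.cgp_average(
            fitted_models, analysis_inputs.patients, 0, 52, analysis_inputs.assumptions
        )
        assert out.total_cost == pytest.approx(
            out.cost_antibiotics + out.cost_hospitalisation + out.cost_other, abs=1e-9
        )
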