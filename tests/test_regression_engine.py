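"""Unit checks of the five regression models against closed forms and oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from trialcea import regression_engine as reg
from conftest import random_patients


@pytest.fixture(scope="module")
def patients500():
    return random_patients(500, np.random.default_rng(11))


class TestSurvival:
    def test_intercept_only_uncensored_matches_sample_moments(self, patients500):
        """Lognormal MLE with no covariates is the mean/SD of log times."""
        rng = np.random.default_rng(3)
        t = np.exp(4.0 + 0.7 * rng.standard_normal(500))
        fit = reg.fit_survival(
            patients500,
            pd.Series(t),
            pd.Series(np.ones(500)),
            covariates=[],
        )
        logt = np.log(t)
        assert fit.params["mu_:Intercept"] == pytest.approx(logt.mean(), abs=1e-4)
        sigma_hat = np.exp(fit.params["sigma_:Intercept"])
        assert sigma_hat == pytest.approx(logt.std(ddof=0), rel=1e-3)

    def test_no_deaths_is_an_error(self, patients500):
        with pytest.raises(ValueError, match="no deaths"):
            reg.fit_survival(
                patients500, pd.Series(np.ones(500)), pd.Series(np.zeros(500))
            )

    def test_non_positive_times_rejected(self, patients500):
        t = np.ones(500)
        t[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            reg.fit_survival(patients500, pd.Series(t), pd.Series(np.ones(500)))

    def test_family_selection_recovers_lognormal(self):
        """AIC selection picks the true lognormal family in nearly every
        replicate at n=500 with modest censoring."""
        wins = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            patients = random_patients(500, rng)
            X, _ = reg.make_covariates(patients)
            mu = 4.0 + 0.3 * X["arm"].to_numpy() - 0.02 * X["mean_adjusted_age"].to_numpy()
            t = np.exp(mu + 0.9 * rng.standard_normal(500))
            time = np.minimum(t, 300.0)
            event = (t <= 300.0).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam, table = reg.select_survival_family(
                    patients, pd.Series(time), pd.Series(event)
                )
            wins += fam == "lognormal"
            if r == 0:
                assert set(table.index) == {
                    "exponential", "weibull", "lognormal", "loglogistic",
                }
                assert (table["aic"] > 0).all()
        assert wins >= reps - 1

    def test_json_round_trip_preserves_predictions(self, patients500):
        rng = np.random.default_rng(5)
        t = np.exp(4.5 + 0.8 * rng.standard_normal(500))
        fit = reg.fit_survival(
            patients500, pd.Series(np.minimum(t, 104)), pd.Series((t <= 104).astype(int))
        )
        back = reg.ModelFit.from_json(fit.to_json())
        X, _ = reg.make_covariates(patients500, age_center=fit.age_center)
        mu1, s1 = reg.survival_location_scale(fit, X)
        mu2, s2 = reg.survival_location_scale(back, X)
        assert np.allclose(mu1, mu2) and s1 == pytest.approx(s2)


class TestInformationCriteria:
    def test_aic_bic_hand_calculation_five_observations(self):
        # -2l + 2k and -2l + k log n on a 5-point fixture
        ll, k, n = -7.25, 3, 5
        aic, bic = reg.information_criteria(ll, k, n)
        assert aic == pytest.approx(2 * 7.25 + 6)
        assert bic == pytest.approx(2 * 7.25 + 3 * np.log(5))


class TestLinearMixed:
    def test_zero_random_effect_data_matches_ols(self):
        """With no between-patient heterogeneity the LMM collapses to OLS."""
        rng = np.random.default_rng(6)
        n = 120
        patients = random_patients(n, rng)
        vw = [0, 4, 12]
        long = pd.DataFrame(
            {
                "patient_id": np.repeat(patients["patient_id"], len(vw)),
                "time": np.tile(vw, n),
            }
        )
        X, _ = reg.make_covariates(patients)
        Xl = X.loc[long["patient_id"]]
        long["utility"] = (
            0.5
            + 0.1 * Xl["arm"].to_numpy() * (long["time"] == 12).to_numpy()
            + rng.normal(0, 0.15, len(long))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reg.fit_lmm(long, patients, "utility", "time", vw)
        exog = reg.longitudinal_design(Xl, long["time"].to_numpy(), vw)
        ols = sm.OLS(long["utility"].to_numpy(), exog.to_numpy()).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-4)
        assert fit.extras["re_var"] == pytest.approx(0.0, abs=1e-3)

    def test_all_missing_outcome_rejected(self):
        patients = random_patients(10, np.random.default_rng(0))
        long = pd.DataFrame(
            {"patient_id": patients["patient_id"], "time": 0, "utility": np.nan}
        )
        with pytest.raises(ValueError, match="missing"):
            reg.fit_lmm(long, patients, "utility", "time", [0, 4])

    def test_single_observation_per_patient_boundary(self):
        """RE and residual variance are not separable; the fit must still
        return finite fixed effects with the RE variance at the boundary."""
        rng = np.random.default_rng(7)
        patients = random_patients(150, rng)
        long = pd.DataFrame(
            {"patient_id": patients["patient_id"], "time": 0}
        )
        X, _ = reg.make_covariates(patients)
        long["utility"] = 0.5 + 0.05 * X["arm"].to_numpy() + rng.normal(0, 0.2, 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reg.fit_lmm(long, patients, "utility", "time", [0])
        assert np.isfinite(fit.params.to_numpy()).all()
        assert fit.extras["re_var"] >= 0.0


class TestOrdinal:
    def test_intercept_like_fit_recovers_frequencies(self):
        """With no covariate signal, predicted probabilities at the covariate
        mean match the observed category frequencies closely."""
        rng = np.random.default_rng(8)
        n = 2000
        patients = random_patients(n, rng)
        freqs = np.array([0.7, 0.2, 0.07, 0.03])
        cats = rng.choice(reg.HOSP_CATEGORIES, n, p=freqs)
        period = pd.DataFrame({"patient_id": patients["patient_id"], "category": cats})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reg.fit_hospitalisation_ordinal(period, patients)
        X, _ = reg.make_covariates(patients, age_center=fit.age_center)
        probs = reg.predict_ordinal_probs(fit, X)
        observed = pd.Series(cats).value_counts(normalize=True)
        for c in reg.HOSP_CATEGORIES:
            assert probs[c].mean() == pytest.approx(observed[c], abs=0.02)

    def test_probabilities_sum_to_one_for_every_patient(self, patients500):
        rng = np.random.default_rng(9)
        cats = rng.choice(reg.HOSP_CATEGORIES, 500, p=[0.6, 0.25, 0.1, 0.05])
        period = pd.DataFrame({"patient_id": patients500["patient_id"], "category": cats})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reg.fit_hospitalisation_ordinal(period, patients500)
        X, _ = reg.make_covariates(patients500, age_center=fit.age_center)
        probs = reg.predict_ordinal_probs(fit, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert (probs.to_numpy() >= 0).all()

    def test_empty_category_merges_upward_with_warning(self, patients500):
        rng = np.random.default_rng(10)
        cats = rng.choice(["none", "other", "major_amp"], 500, p=[0.7, 0.25, 0.05])
        period = pd.DataFrame({"patient_id": patients500["patient_id"], "category": cats})
        with pytest.warns(UserWarning, match="merged"):
            collapsed, present = reg.collapse_empty_categories(pd.Series(cats))
        assert "minor_amp_or_revasc" not in set(collapsed)
        assert present == ["none", "other", "major_amp"]

    def test_thresholds_strictly_increasing(self, patients500):
        rng = np.random.default_rng(12)
        cats = rng.choice(reg.HOSP_CATEGORIES, 500, p=[0.6, 0.25, 0.1, 0.05])
        period = pd.DataFrame({"patient_id": patients500["patient_id"], "category": cats})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reg.fit_hospitalisation_ordinal(period, patients500)
        th = reg.ordinal_thresholds(fit)
        assert np.all(np.diff(th) > 0)
        # any MVN draw in the unconstrained parametrisation stays monotone
        draw = fit.draw_params(np.random.default_rng(0), 20)
        for d in draw:
            assert np.all(np.diff(reg.ordinal_thresholds(fit, d)) > 0)


class TestLogit:
    def test_two_by_two_table_equals_hand_log_odds_ratio(self):
        """Arm coefficient on a pure 2x2 design is the hand-computed log OR."""
        rows = []
        for arm, y, count in [
            ("swab", 0, 60), ("swab", 1, 40), ("tissue", 0, 45), ("tissue", 1, 55),
        ]:
            rows += [{"arm": arm, "prescribed": y}] * count
        df = pd.DataFrame(rows)
        df["patient_id"] = [f"q{i}" for i in range(len(df))]
        patients = pd.DataFrame(
            {
                "patient_id": df["patient_id"],
                "arm": df["arm"],
                "age": 60.0,
                "sex": "male",
                "n_ulcers": 1,
                "ulcer_area": 2.0,
                "ulcer_duration": 1.0,
            }
        )
        period = df[["patient_id", "prescribed"]]
        fit = reg.fit_antibiotic_logit(period, patients, covariates=["arm"])
        hand = np.log((55 / 45) / (40 / 60))
        assert fit.params["arm"] == pytest.approx(hand, abs=1e-6)

    def test_balanced_null_data_gives_near_zero_arm_effect(self, patients500):
        rng = np.random.default_rng(13)
        period = pd.DataFrame(
            {
                "patient_id": patients500["patient_id"],
                "prescribed": rng.integers(0, 2, 500),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reg.fit_antibiotic_logit(period, patients500)
        assert abs(fit.params["arm"]) < 3 * np.sqrt(fit.vcov.loc["arm", "arm"])

    def test_perfect_separation_names_covariate(self):
        patients = random_patients(40, np.random.default_rng(14))
        period = pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "prescribed": (patients["age"] > patients["age"].median()).astype(int),
            }
        )
        patients = patients.copy()
        # make age a perfect separator
        period["prescribed"] = (
            patients["age"] > np.median(patients["age"])
        ).astype(int)
        with pytest.raises(ValueError, match="separation.*age"):
            reg.fit_antibiotic_logit(period, patients)


def test_all_fits_share_design(fitted_models):
    fitted_models.validate()
    cols = fitted_models.survival.covariate_cols
    assert cols == reg.COVARIATE_COLS
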