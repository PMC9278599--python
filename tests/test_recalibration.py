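import dataclasses

import numpy as np
import pandas as pd
import pytest

import riskvalid as rv
from riskvalid.cohort import ValidationError
from riskvalid.engines import WeibullBaseline
from riskvalid.recalibration import fit_weibull_ph


def weibull_cohort(seed=0, n=4000, alpha=-9.5, p=2.0, beta=0.7,
                   age_offset=20.0):
    """Self-generated Weibull PH data on the age timescale with delayed
    entry and administrative censoring at 10 years."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(45, 70, n)
    lp = rng.normal(0, 1, n) * beta
    u0 = age - age_offset
    draw = rng.exponential(size=n)
    t_evt = (u0 ** p + draw / np.exp(alpha + lp)) ** (1 / p) - u0
    time = np.minimum(t_evt, 10.0)
    event = (t_evt <= 10.0).astype(int)
    return pd.DataFrame({"age": age, "time": time, "event": event,
                         "lp": lp / beta})


class TestCalibrationSlope:
    @pytest.mark.parametrize("form", ["weibull", "proportional_hazards"])
    def test_recovers_unit_slope_on_self_generated_data(self, form):
        df = weibull_cohort(seed=1, n=6000)
        comp = rv.fit_calibration_slope(df, 0.7 * df["lp"].to_numpy(), form)
        assert comp.ci[0] < 1.0 < comp.ci[1]
        assert comp.slope == pytest.approx(1.0, abs=0.15)

    def test_scale_equivariance(self):
        df = weibull_cohort(seed=2, n=6000)
        lp = 0.7 * df["lp"].to_numpy()
        full = rv.fit_calibration_slope(df, lp, "proportional_hazards")
        half = rv.fit_calibration_slope(df, lp / 2, "proportional_hazards")
        assert half.slope == pytest.approx(2 * full.slope, rel=1e-6)

    def test_shift_invariance_of_slope(self):
        df = weibull_cohort(seed=3, n=4000)
        lp = 0.7 * df["lp"].to_numpy()
        a = rv.fit_calibration_slope(df, lp, "proportional_hazards")
        b = rv.fit_calibration_slope(df, lp + 5.0, "proportional_hazards")
        assert b.slope == pytest.approx(a.slope, abs=1e-6)

    def test_constant_lp_rejected(self):
        df = weibull_cohort(seed=4, n=200)
        with pytest.raises(ValidationError, match="degenerate"):
            rv.fit_calibration_slope(df, np.zeros(len(df)), "weibull")

    def test_zero_events_rejected(self):
        df = weibull_cohort(seed=5, n=200)
        df["event"] = 0
        with pytest.raises(ValidationError, match="events"):
            rv.fit_calibration_slope(df, df["lp"].to_numpy(), "weibull")


class TestBaselineUpdate:
    def test_weibull_parameters_recovered_within_3_se(self):
        alpha_true, p_true = -9.5, 2.0
        df = weibull_cohort(seed=6, n=20000, alpha=alpha_true, p=p_true)
        lp = 0.7 * df["lp"].to_numpy()
        entry = df["age"].to_numpy()
        params, cov, _ = fit_weibull_ph(entry, entry + df["time"].to_numpy(),
                                        df["event"].to_numpy(), X=None,
                                        offset=lp)
        se = np.sqrt(np.diag(cov)[:2])
        assert abs(params[0] - alpha_true) < 3 * se[0]
        assert abs(params[1] - np.log(p_true)) < 3 * se[1]

    def test_no_events_rejected(self):
        df = weibull_cohort(seed=7, n=200)
        df["event"] = 0
        with pytest.raises((ValidationError, rv.recalibration.FittingError)
                           if hasattr(rv, "recalibration") else ValidationError):
            rv.update_baseline(df, np.zeros(len(df)), form="weibull")

    def test_ph_update_matches_observed_risk_exactly(self, men_cohort):
        cohort, true_model = men_cohort
        model = rv.GloboriskModel()  # the uncalibrated original
        lp = model.linear_predictor(cohort)
        comp = rv.fit_calibration_slope(cohort, lp, "proportional_hazards")
        k = rv.update_baseline(cohort, comp.slope * lp,
                               form="proportional_hazards", model=model)
        dH = model.baseline_cumhaz_increment(cohort)
        pred = 1 - np.exp(-k * dH * np.exp(comp.slope * lp))
        observed = rv.km_risk(cohort["time"], cohort["event"], 10)
        assert pred.mean() == pytest.approx(observed, abs=1e-9)


class TestRecalibratedRisk:
    def test_identity_recalibration_reproduces_original(self, toy_subjects):
        model = rv.GloboriskModel()
        comp = rv.recalibration.SlopeComponent(
            name="overall", slope=1.0, ci=(0.8, 1.2), se=0.1,
            log_likelihood=0.0, n_events=50, baseline=1.0)
        result = rv.RecalibrationResult(model_label=model.label,
                                        components={"overall": comp})
        np.testing.assert_array_equal(
            rv.recalibrated_risk(model, result, toy_subjects),
            model.predict_risk(toy_subjects))

    def test_identity_recalibration_score(self, toy_subjects):
        model = rv.ScoreModel("score_low")
        comps = {}
        for part in model.parts:
            comps[part] = rv.recalibration.SlopeComponent(
                name=part, slope=1.0, ci=(0.8, 1.2), se=0.1,
                log_likelihood=0.0, n_events=50,
                baseline=model.coefs_.baselines[part])
        result = rv.RecalibrationResult(model_label=model.label,
                                        components=comps, form="weibull")
        np.testing.assert_array_equal(
            rv.recalibrated_risk(model, result, toy_subjects),
            model.predict_risk(toy_subjects))

    def test_zero_slope_removes_discrimination(self, toy_subjects):
        model = rv.GloboriskModel()
        comp = rv.recalibration.SlopeComponent(
            name="overall", slope=0.0, ci=(-0.2, 0.2), se=0.1,
            log_likelihood=0.0, n_events=50, baseline=1.0)
        result = rv.RecalibrationResult(model_label=model.label,
                                        components={"overall": comp})
        X = toy_subjects.assign(age=55.0, sex="male")
        risks = rv.recalibrated_risk(model, result, X)
        assert np.ptp(risks) == 0.0  # same age and sex: identical risks

    def test_slope_0p84_matches_hand_formula(self, toy_subjects):
        model = rv.GloboriskModel()
        comp = rv.recalibration.SlopeComponent(
            name="overall", slope=0.84, ci=(0.70, 0.99), se=0.07,
            log_likelihood=0.0, n_events=50, baseline=0.9)
        result = rv.RecalibrationResult(model_label=model.label,
                                        components={"overall": comp})
        lp = model.linear_predictor(toy_subjects)
        dH = model.baseline_cumhaz_increment(toy_subjects)
        expected = 1 - np.exp(-0.9 * dH * np.exp(0.84 * lp))
        np.testing.assert_allclose(
            rv.recalibrated_risk(model, result, toy_subjects), expected,
            atol=1e-10)

    def test_mismatched_model_label_rejected(self, toy_subjects):
        model = rv.GloboriskModel()
        result = rv.RecalibrationResult(model_label="score_low")
        with pytest.raises(ValidationError, match="score_low"):
            rv.recalibrated_risk(model, result, toy_subjects)


class TestSlopeRecalibrator:
    def test_score_two_part_recalibration(self, men_cohort):
        cohort, _ = men_cohort
        model = rv.ScoreModel("score_low")
        recal = rv.SlopeRecalibrator(model).fit(cohort)
        assert set(recal.slope_) == {"chd", "non_chd"}
        risks = recal.predict_risk(cohort)
        assert np.all((risks >= 0) & (risks <= 1))
        # baseline update keeps overall calibration close
        po = rv.po_ratio(cohort["time"], cohort["event"], risks)
        assert po == pytest.approx(1.0, abs=0.1)

    def test_consistency_of_mean_recalibrated_risk(self, men_cohort):
        cohort, _ = men_cohort
        model = rv.GloboriskModel()
        recal = rv.SlopeRecalibrator(model).fit(cohort)
        risks = recal.predict_risk(cohort)
        observed = rv.km_risk(cohort["time"], cohort["event"], 10)
        assert risks.mean() == pytest.approx(observed, abs=0.002)

    def test_sklearn_param_interface(self):
        model = rv.GloboriskModel()
        recal = rv.SlopeRecalibrator(model, horizon=10.0)
        params = recal.get_params()
        assert params["horizon"] == 10.0
        recal.set_params(horizon=5.0)
        assert recal.horizon == 5.0


class TestRefit:
    def test_recovers_simulated_sbp_hazard_ratio(self):
        rng = np.random.default_rng(12)
        n = 8000
        age = rng.uniform(45, 70, n)
        sbp = rng.normal(125, 20, n)
        lp = 0.02 * (sbp - 125)
        draw = rng.exponential(size=n)
        u0 = age - 20
        t_evt = (u0 ** 2 + draw / np.exp(-8.2 + lp)) ** 0.5 - u0
        df = pd.DataFrame({"age": age, "sbp": sbp,
                           "time": np.minimum(t_evt, 10.0),
                           "event": (t_evt <= 10.0).astype(int)})
        res = rv.refit_model(df, ["sbp"], form="proportional_hazards")
        row = res.summary.loc["sbp"]
        hr20 = np.exp(20 * row["coef"])
        se20 = 20 * row["se"]
        assert abs(np.log(hr20) - 0.4) < 3 * se20

    def test_null_effect_wald_calibration(self):
        rejections = 0
        for seed in range(20):
            df = weibull_cohort(seed=300 + seed, n=1500, beta=0.7)
            noise = np.random.default_rng(seed).normal(0, 1, len(df))
            df["x"] = noise  # unrelated covariate
            res = rv.refit_model(df, ["x"], form="proportional_hazards")
            rejections += res.summary.loc["x", "p"] < 0.05
        assert rejections <= 4  # ~5% nominal type-I error

    def test_absent_term_named_in_error(self, men_cohort):
        cohort, _ = men_cohort
        with pytest.raises(ValidationError, match="ldl"):
            rv.refit_model(cohort, ["sbp", "ldl"])

    def test_sex_interactions_supported(self, small_cohort):
        cohort, _ = small_cohort
        res = rv.refit_model(cohort, ["sbp", "smoking", "sex:smoking"])
        assert "sex:smoking" in res.summary.index
        assert (res.summary["hr_ci_low"] <= res.summary["hr"]).all()
        assert (res.summary["hr"] <= res.summary["hr_ci_high"]).all()
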