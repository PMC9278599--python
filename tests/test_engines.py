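import dataclasses

import numpy as np
import pandas as pd
import pytest

import riskvalid as rv
from riskvalid.cohort import SchemaError, ValidationError
from riskvalid.engines import (MG_PER_MMOL, GloboriskCoefficients,
                               ScoreCoefficients, WeibullBaseline, convert_tc)


def one_subject(**kw):
    base = {"id": "x", "sex": "male", "age": 55.0, "sbp": 140.0,
            "tc": 230.0, "smoking": 1, "diabetes": 0}
    base.update(kw)
    return pd.DataFrame([base])


@pytest.fixture(scope="module")
def score():
    return rv.ScoreModel("score_low", diabetes_multiplier=False)


@pytest.fixture(scope="module")
def glob():
    return rv.GloboriskModel()


def zero_score_coefs():
    c = rv.load_score_coefficients("score_low")
    zeroed = {part: {k: 0.0 for k in c.coefficients[part]}
              for part in c.coefficients}
    return dataclasses.replace(c, coefficients=zeroed)


class TestLinearPredictor:
    def test_zero_coefficients_give_zero(self, toy_subjects):
        model = rv.ScoreModel(zero_score_coefs(), diabetes_multiplier=False)
        for part in model.parts:
            assert np.all(model.linear_predictor(toy_subjects, part) == 0.0)

    def test_single_term_product(self):
        c = zero_score_coefs()
        c.coefficients["chd"]["sbp"] = 0.02
        model = rv.ScoreModel(c)
        lp = model.linear_predictor(one_subject(sbp=130.0), "chd")  # centred at 120
        assert lp[0] == pytest.approx(0.2, abs=1e-12)

    def test_globorisk_lp_matches_term_by_term_sum(self, glob, toy_subjects):
        c = glob.coefs_
        expected = []
        for _, s in toy_subjects.iterrows():
            female = float(s.sex == "female")
            dev = s.age - c.age_center
            vals = {"sbp": s.sbp - c.sbp_center, "tc": s.tc - c.tc_center,
                    "smoking": float(s.smoking), "diabetes": float(s.diabetes)}
            total = 0.0
            for term, x in vals.items():
                total += c.coefficients[term] * x
                total += c.age_interactions[term] * dev * x
            total += c.sex_interactions["smoking"] * female * vals["smoking"]
            total += c.sex_interactions["diabetes"] * female * vals["diabetes"]
            expected.append(total)
        np.testing.assert_allclose(glob.linear_predictor(toy_subjects),
                                   expected, atol=1e-12)

    def test_missing_covariate_named_in_error(self, glob):
        with pytest.raises(ValidationError, match="sbp"):
            glob.linear_predictor(one_subject().drop(columns="sbp"))


class TestScoreRisk:
    def test_zero_lp_reduces_to_baseline_ratio(self):
        model = rv.ScoreModel(zero_score_coefs(), diabetes_multiplier=False)
        X = one_subject()
        c = model.coefs_
        expected = 1.0
        for part in model.parts:
            b = c.baselines[part]["male"]
            expected *= b.survival(65.0) / b.survival(55.0)
        assert model.predict_risk(X)[0] == pytest.approx(1 - expected, abs=1e-12)

    def test_risk_increases_with_sbp(self, score):
        lo = score.predict_risk(one_subject(sbp=120.0))[0]
        hi = score.predict_risk(one_subject(sbp=140.0))[0]
        assert hi > lo

    def test_hand_evaluated_two_part_formula(self, score):
        # male, 55 y, SBP 140, TC 230 mg/dL, smoker, step-by-step evaluation
        X = one_subject()
        tc_mmol = 230.0 / MG_PER_MMOL
        risk = 1.0
        for part, (alpha, p) in (("chd", (-22.1, 4.71)),
                                 ("non_chd", (-26.7, 5.64))):
            betas = {"chd": (0.71, 0.018, 0.24),
                     "non_chd": (0.63, 0.022, 0.02)}[part]
            lp = betas[0] * 1 + betas[1] * (140 - 120) + betas[2] * (tc_mmol - 6)
            s0 = lambda a: np.exp(-np.exp(alpha) * (a - 20) ** p)
            risk *= (s0(65.0) / s0(55.0)) ** np.exp(lp)
        assert score.predict_risk(X)[0] == pytest.approx(1 - risk, abs=1e-10)

    def test_combined_risk_at_least_each_part(self, score, toy_subjects):
        combined = score.predict_risk(toy_subjects)
        for part in score.parts:
            part_risk = 1.0 - score.part_survival(toy_subjects, part)
            assert np.all(combined >= part_risk - 1e-15)


class TestDiabetesMultiplier:
    @pytest.mark.parametrize("risk,sex,dm,expected", [
        (0.03, "male", 1, 0.06),
        (0.03, "female", 1, 0.12),
        (0.30, "female", 1, 1.0),   # capped at certainty
        (0.03, "male", 0, 0.03),
    ])
    def test_values(self, risk, sex, dm, expected):
        assert rv.apply_diabetes_multiplier(risk, sex, dm) == pytest.approx(expected)

    def test_invalid_risk_rejected(self):
        with pytest.raises(ValidationError):
            rv.apply_diabetes_multiplier(1.2, "male", 1)


class TestGloboriskRisk:
    def test_zero_lp_reduces_to_baseline(self, glob):
        c = glob.coefs_
        zeroed = dataclasses.replace(
            c,
            coefficients={k: 0.0 for k in c.coefficients},
            age_interactions={k: 0.0 for k in c.age_interactions},
            sex_interactions={k: 0.0 for k in c.sex_interactions})
        model = rv.GloboriskModel(zeroed)
        X = one_subject()
        dH = c.cumulative_hazard("male", 65.0) - c.cumulative_hazard("male", 55.0)
        assert model.predict_risk(X)[0] == pytest.approx(1 - np.exp(-dH), abs=1e-12)

    def test_null_hazard_gives_zero_risk(self, glob):
        c = glob.coefs_
        nul = dataclasses.replace(
            c, baseline_hazard={s: np.zeros_like(c.baseline_hazard[s])
                                for s in ("male", "female")})
        model = rv.GloboriskModel(nul)
        assert model.predict_risk(one_subject(sbp=190.0))[0] == 0.0

    def test_matches_piecewise_hazard_integration_oracle(self, glob):
        X = one_subject(age=57.3)
        c = glob.coefs_
        h = np.asarray(c.baseline_hazard["male"], float)
        a0, a1 = 57.3, 67.3
        start = int(c.baseline_ages[0])
        dH = 0.0  # exact integral of the piecewise-constant hazard
        for year in range(int(np.floor(a0)), int(np.ceil(a1))):
            lo, hi = max(a0, year), min(a1, year + 1)
            if hi > lo:
                dH += h[year - start] * (hi - lo)
        lp = glob.linear_predictor(X)[0]
        assert glob.predict_risk(X)[0] == pytest.approx(
            1 - np.exp(-dH * np.exp(lp)), abs=1e-10)

    def test_baseline_coverage_error(self, glob):
        with pytest.raises(ValidationError, match="covers ages"):
            glob.predict_risk(one_subject(age=90.0))


class TestInvariantsAndConfig:
    def test_risks_within_unit_interval(self, score, glob, toy_subjects):
        for model in (score, glob):
            r = model.predict_risk(toy_subjects)
            assert np.all((r >= 0) & (r <= 1))

    def test_risk_nondecreasing_in_age_at_fixed_lp(self, glob):
        c = glob.coefs_
        zeroed = dataclasses.replace(
            c,
            coefficients={k: 0.0 for k in c.coefficients},
            age_interactions={k: 0.0 for k in c.age_interactions},
            sex_interactions={k: 0.0 for k in c.sex_interactions})
        model = rv.GloboriskModel(zeroed)
        risks = [model.predict_risk(one_subject(age=a))[0]
                 for a in (45.0, 55.0, 65.0, 75.0)]
        assert np.all(np.diff(risks) >= 0)

    def test_unit_conversion_round_trip(self, score, toy_subjects):
        tc = toy_subjects["tc"].to_numpy(float)
        back = convert_tc(convert_tc(tc, "mmol/L") * MG_PER_MMOL, "mg/dL")
        X2 = toy_subjects.assign(tc=back)
        np.testing.assert_allclose(score.predict_risk(toy_subjects),
                                   score.predict_risk(X2), atol=1e-12)

    def test_nonpositive_weibull_shape_rejected(self):
        with pytest.raises(SchemaError):
            WeibullBaseline(alpha=-20.0, p=0.0)

    def test_incomplete_score_config_rejected(self):
        c = rv.load_score_coefficients("score_low")
        bad = {k: v for k, v in c.coefficients.items() if k == "chd"}
        with pytest.raises(SchemaError):
            ScoreCoefficients(coefficients=bad, baselines=c.baselines,
                              tc_units=c.tc_units, sbp_center=c.sbp_center,
                              tc_center=c.tc_center)

    def test_prediction_frame_carries_lp_and_risk(self, score, glob,
                                                  toy_subjects):
        frame = glob.predict_risk_frame(toy_subjects)
        assert list(frame["id"]) == list(toy_subjects["id"])
        np.testing.assert_allclose(frame["ten_year_risk"],
                                   glob.predict_risk(toy_subjects))
        sf = score.predict_risk_frame(toy_subjects)
        assert {"lp_chd", "lp_non_chd", "ten_year_risk"} <= set(sf.columns)

    def test_globorisk_requires_all_age_interactions(self):
        c = rv.load_globorisk_coefficients()
        incomplete = {k: v for k, v in c.age_interactions.items()
                      if k != "sbp"}
        with pytest.raises(SchemaError, match="age interaction"):
            dataclasses.replace(c, age_interactions=incomplete)
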