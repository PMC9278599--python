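"""10-year fatal-CVD risk engines: SCORE (two-part Weibull) and Globorisk
(proportional hazards), both on the age timescale.

Age acts as the time-to-event axis, not as a covariate: a subject's 10-year
risk is the conditional probability of CVD death between baseline age ``a``
and ``a + 10`` given survival to ``a``,

    risk = 1 - [S0(a + 10) / S0(a)] ** exp(lp),

where ``lp`` is the model's linear predictor evaluated at baseline.  SCORE
splits the outcome into coronary (CHD) and non-coronary parts with separate
Weibull baselines per sex and combines them multiplicatively on the survival
scale; Globorisk uses a sex-stratified piecewise-constant baseline hazard by
single year of age with age and sex interactions in the linear predictor.

Coefficient sets are plain YAML configs (see ``riskvalid/data``); nothing is
hard-coded in the engines.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .cohort import SchemaError, ValidationError

#: 1 mmol/L of total cholesterol in mg/dL.
MG_PER_MMOL = 38.67

SCORE_PARTS = ("chd", "non_chd")
SEXES = ("male", "female")


def _require(mapping, keys, context):
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise SchemaError(f"{context}: missing key(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Coefficient containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeibullBaseline:
    """Weibull baseline survival S0(a) = exp(-exp(alpha) * (a - offset)^p)."""

    alpha: float
    p: float
    age_offset: float = 20.0

    def __post_init__(self):
        if self.p <= 0:
            raise SchemaError("Weibull shape p must be positive")

    def cumulative_hazard(self, age):
        a = np.asarray(age, dtype=float)
        if np.any(a < self.age_offset):
            raise ValidationError(
                f"age below Weibull age origin {self.age_offset}")
        return np.exp(self.alpha) * (a - self.age_offset) ** self.p

    def survival(self, age):
        return np.exp(-self.cumulative_hazard(age))


@dataclass(frozen=True)
class ScoreCoefficients:
    """Coefficient set for the two-part SCORE equation.

    ``coefficients[part]`` maps smoking / sbp / tc to betas (shared between
    the sexes, as in the original equations); ``baselines[part][sex]`` is a
    :class:`WeibullBaseline`; ``tc_units`` declares the cholesterol scale
    the betas expect.
    """

    coefficients: dict
    baselines: dict
    tc_units: str
    sbp_center: float
    tc_center: float
    label: str = "score"

    def __post_init__(self):
        if self.tc_units not in ("mg/dL", "mmol/L"):
            raise SchemaError("tc_units must be 'mg/dL' or 'mmol/L'")
        for part in SCORE_PARTS:
            if part not in self.coefficients or part not in self.baselines:
                raise SchemaError(f"SCORE coefficient set lacks part {part!r}")
            _require(self.coefficients[part], ("smoking", "sbp", "tc"),
                     f"SCORE {part} coefficients")
            for sex in SEXES:
                if sex not in self.baselines[part]:
                    raise SchemaError(
                        f"SCORE {part} baseline lacks sex {sex!r}")


@dataclass(frozen=True)
class GloboriskCoefficients:
    """Coefficient set for the fatal-CVD Globorisk equation.

    The baseline cumulative hazard is sex-stratified and piecewise constant
    by single year of age: ``baseline_ages`` are the year starts and
    ``baseline_hazard[sex][k]`` is the hazard on ``[age_k, age_k + 1)``.
    Every main effect carries an age interaction; smoking and diabetes also
    interact with (female) sex.
    """

    coefficients: dict
    age_interactions: dict
    sex_interactions: dict
    baseline_ages: np.ndarray
    baseline_hazard: dict
    age_center: float
    sbp_center: float
    tc_center: float
    tc_units: str = "mg/dL"
    label: str = "globorisk"

    def __post_init__(self):
        _require(self.coefficients, ("sbp", "tc", "smoking", "diabetes"),
                 "Globorisk coefficients")
        missing = [k for k in self.coefficients if k not in self.age_interactions]
        if missing:
            raise SchemaError(
                "Globorisk requires an age interaction for every main effect; "
                f"missing: {', '.join(missing)}")
        _require(self.sex_interactions, ("smoking", "diabetes"),
                 "Globorisk sex interactions")
        ages = np.asarray(self.baseline_ages)
        if len(ages) < 2 or np.any(np.diff(ages) != 1):
            raise SchemaError("baseline hazard table must cover consecutive "
                              "single years of age")
        for sex in SEXES:
            h = np.asarray(self.baseline_hazard[sex], dtype=float)
            if len(h) != len(ages):
                raise SchemaError(f"baseline hazard length mismatch for {sex}")
            if np.any(h < 0):
                raise SchemaError("baseline hazard must be non-negative")

    def cumhaz_grid(self, sex):
        """Age boundaries and baseline cumulative hazard at those boundaries."""
        ages = np.asarray(self.baseline_ages, dtype=float)
        h = np.asarray(self.baseline_hazard[sex], dtype=float)
        bounds = np.append(ages, ages[-1] + 1.0)
        H = np.concatenate([[0.0], np.cumsum(h)])
        return bounds, H

    def cumulative_hazard(self, sex, age):
        """H0_sex at (possibly fractional) ages; piecewise linear between
        single-year boundaries."""
        bounds, H = self.cumhaz_grid(sex)
        a = np.asarray(age, dtype=float)
        if np.any(a < bounds[0]) or np.any(a > bounds[-1]):
            raise ValidationError(
                f"baseline hazard table covers ages [{bounds[0]}, {bounds[-1]}]"
                f" but {float(np.min(a)):.1f}-{float(np.max(a)):.1f} requested")
        return np.interp(a, bounds, H)


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def _read_config(path_or_name):
    name = str(path_or_name)
    if name.endswith((".yaml", ".yml")):
        with open(name) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("riskvalid.data").joinpath(f"{name}.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_score_coefficients(path_or_name="score_low") -> ScoreCoefficients:
    """Load a SCORE coefficient config (packaged name or YAML path)."""
    raw = _read_config(path_or_name)
    _require(raw, ("model", "tc_units", "centering", "parts"), "SCORE config")
    if raw["model"] != "score":
        raise SchemaError(f"not a SCORE config: model={raw['model']!r}")
    coefficients, baselines = {}, {}
    _require(raw["parts"], SCORE_PARTS, "SCORE config parts")
    for part in SCORE_PARTS:
        block = raw["parts"][part]
        _require(block, ("coefficients", "baseline"), f"SCORE part {part}")
        coefficients[part] = dict(block["coefficients"])
        baselines[part] = {
            sex: WeibullBaseline(**block["baseline"][sex]) for sex in SEXES}
    return ScoreCoefficients(
        coefficients=coefficients,
        baselines=baselines,
        tc_units=raw["tc_units"],
        sbp_center=float(raw["centering"]["sbp"]),
        tc_center=float(raw["centering"]["tc"]),
        label=raw.get("label", f"score_{raw.get('variant', 'custom')}"),
    )


def load_globorisk_coefficients(path_or_name="globorisk_fixture") -> GloboriskCoefficients:
    """Load a Globorisk coefficient config (packaged name or YAML path)."""
    raw = _read_config(path_or_name)
    _require(raw, ("model", "centering", "coefficients", "age_interactions",
                   "sex_interactions", "baseline_hazard"), "Globorisk config")
    if raw["model"] != "globorisk":
        raise SchemaError(f"not a Globorisk config: model={raw['model']!r}")
    bh = raw["baseline_hazard"]
    _require(bh, ("age_start", "male", "female"), "Globorisk baseline hazard")
    n = len(bh["male"])
    ages = np.arange(int(bh["age_start"]), int(bh["age_start"]) + n)
    return GloboriskCoefficients(
        coefficients=dict(raw["coefficients"]),
        age_interactions=dict(raw["age_interactions"]),
        sex_interactions=dict(raw["sex_interactions"]),
        baseline_ages=ages,
        baseline_hazard={"male": np.asarray(bh["male"], float),
                         "female": np.asarray(bh["female"], float)},
        age_center=float(raw["centering"]["age"]),
        sbp_center=float(raw["centering"]["sbp"]),
        tc_center=float(raw["centering"]["tc"]),
        tc_units=raw.get("tc_units", "mg/dL"),
        label=raw.get("label", "globorisk"),
    )


# ---------------------------------------------------------------------------
# Covariate access
# ---------------------------------------------------------------------------

def _column(X, name):
    if name not in X.columns:
        raise ValidationError(f"missing covariate: {name}")
    col = X[name]
    if col.isna().any():
        raise ValidationError(f"missing covariate values in: {name}")
    return col


def _sex_indicator(X):
    sex = _column(X, "sex")
    female = sex.astype(str).str.lower().isin(["female", "f", "0", "2"])
    male = sex.astype(str).str.lower().isin(["male", "m", "1"])
    if not (female | male).all():
        raise ValidationError("unrecognised sex codes in cohort")
    return female.to_numpy()


def convert_tc(tc_mgdl, to_units):
    """Convert total cholesterol from the canonical mg/dL to model units."""
    tc = np.asarray(tc_mgdl, dtype=float)
    if to_units == "mg/dL":
        return tc
    if to_units == "mmol/L":
        return tc / MG_PER_MMOL
    raise SchemaError(f"unknown cholesterol units: {to_units!r}")


def apply_diabetes_multiplier(risk, sex, diabetes):
    """Double the predicted risk of diabetic men and quadruple that of
    diabetic women (SCORE risk-chart convention), capping at 1.

    Non-diabetic subjects are returned unchanged.  Accepts scalars or
    aligned arrays.
    """
    r = np.asarray(risk, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValidationError("risk must lie in [0, 1]")
    sex_arr = np.asarray(sex)
    female = np.char.lower(sex_arr.astype(str)) != "male"
    if sex_arr.dtype.kind in "if":
        female = sex_arr == 0
    dm = np.asarray(diabetes, dtype=float) > 0
    mult = np.where(dm, np.where(female, 4.0, 2.0), 1.0)
    out = np.minimum(r * mult, 1.0)
    if np.isscalar(risk):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

class ScoreModel(BaseEstimator):
    """Two-part Weibull SCORE engine.

    Parameters
    ----------
    coefficients : ScoreCoefficients or str
        A loaded coefficient set, or the name/path of a YAML config
        (``"score_low"`` and ``"score_high"`` are packaged).
    diabetes_multiplier : bool
        Apply the x2 (men) / x4 (women) diabetic multiplier to predicted
        risks.  The multiplier never enters the linear predictor.
    horizon : float
        Prediction horizon in years (10 by default).
    """

    parts = SCORE_PARTS

    def __init__(self, coefficients="score_low", diabetes_multiplier=True,
                 horizon=10.0, hazard_scale=1.0):
        self.coefficients = coefficients
        self.diabetes_multiplier = diabetes_multiplier
        self.horizon = horizon
        self.hazard_scale = hazard_scale

    @property
    def coefs_(self) -> ScoreCoefficients:
        if isinstance(self.coefficients, ScoreCoefficients):
            return self.coefficients
        return load_score_coefficients(self.coefficients)

    @property
    def label(self):
        return self.coefs_.label

    def linear_predictor(self, X: pd.DataFrame, part: str) -> np.ndarray:
        """Centred linear predictor of one outcome part."""
        coefs = self.coefs_
        beta = coefs.coefficients[part]
        smoking = _column(X, "smoking").to_numpy(float)
        sbp = _column(X, "sbp").to_numpy(float)
        tc = convert_tc(_column(X, "tc").to_numpy(float), coefs.tc_units)
        return (beta["smoking"] * smoking
                + beta["sbp"] * (sbp - coefs.sbp_center)
                + beta["tc"] * (tc - coefs.tc_center))

    def part_survival(self, X, part, lp=None, baseline=None, horizon=None):
        """Conditional 10-year survival of one part:
        [S0(a + h)/S0(a)] ** exp(lp)."""
        coefs = self.coefs_
        h = self.horizon if horizon is None else horizon
        age = _column(X, "age").to_numpy(float)
        female = _sex_indicator(X)
        if lp is None:
            lp = self.linear_predictor(X, part)
        surv = np.empty(len(X))
        for sex, mask in (("male", ~female), ("female", female)):
            if not mask.any():
                continue
            base = (baseline or coefs.baselines[part])[sex]
            dH = base.cumulative_hazard(age[mask] + h) - \
                base.cumulative_hazard(age[mask])
            surv[mask] = np.exp(-self.hazard_scale * dH * np.exp(lp[mask]))
        return surv

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Combined 10-year fatal-CVD risk, 1 - S_chd * S_non_chd."""
        s_total = np.ones(len(X))
        for part in self.parts:
            s_total *= self.part_survival(X, part)
        risk = 1.0 - s_total
        if self.diabetes_multiplier:
            risk = apply_diabetes_multiplier(
                risk, X["sex"].to_numpy(), _column(X, "diabetes").to_numpy(float))
        return risk

    def predict_risk_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject prediction records: id, model label, the linear
        predictor of each part, and the combined 10-year risk."""
        out = pd.DataFrame({
            "id": X["id"] if "id" in X.columns else np.arange(len(X)),
            "model": self.label,
        })
        for part in self.parts:
            out[f"lp_{part}"] = self.linear_predictor(X, part)
        out["ten_year_risk"] = self.predict_risk(X)
        return out


class GloboriskModel(BaseEstimator):
    """Proportional-hazards Globorisk engine with age/sex interactions.

    ``interactions_at`` controls whether age interactions are evaluated at
    baseline age (default, held fixed over the interval) or at the attained
    age ``a + horizon/2`` midpoint (``"attained"``).
    """

    def __init__(self, coefficients="globorisk_fixture", horizon=10.0,
                 interactions_at="baseline", hazard_scale=1.0):
        self.coefficients = coefficients
        self.horizon = horizon
        self.interactions_at = interactions_at
        self.hazard_scale = hazard_scale

    @property
    def coefs_(self) -> GloboriskCoefficients:
        if isinstance(self.coefficients, GloboriskCoefficients):
            return self.coefficients
        return load_globorisk_coefficients(self.coefficients)

    @property
    def label(self):
        return self.coefs_.label

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        coefs = self.coefs_
        age = _column(X, "age").to_numpy(float)
        if self.interactions_at == "attained":
            age_eval = age + self.horizon / 2.0
        else:
            age_eval = age
        dev = age_eval - coefs.age_center
        female = _sex_indicator(X).astype(float)
        values = {
            "sbp": _column(X, "sbp").to_numpy(float) - coefs.sbp_center,
            "tc": convert_tc(_column(X, "tc").to_numpy(float),
                             coefs.tc_units) - coefs.tc_center,
            "smoking": _column(X, "smoking").to_numpy(float),
            "diabetes": _column(X, "diabetes").to_numpy(float),
        }
        lp = np.zeros(len(X))
        for term, x in values.items():
            lp += coefs.coefficients[term] * x
            lp += coefs.age_interactions[term] * dev * x
        for term, beta in coefs.sex_interactions.items():
            lp += beta * female * values[term]
        return lp

    def baseline_cumhaz_increment(self, X, horizon=None) -> np.ndarray:
        """H0_sex(a + h) - H0_sex(a) per subject, including hazard_scale."""
        coefs = self.coefs_
        h = self.horizon if horizon is None else horizon
        age = _column(X, "age").to_numpy(float)
        female = _sex_indicator(X)
        dH = np.empty(len(X))
        for sex, mask in (("male", ~female), ("female", female)):
            if not mask.any():
                continue
            dH[mask] = coefs.cumulative_hazard(sex, age[mask] + h) - \
                coefs.cumulative_hazard(sex, age[mask])
        return self.hazard_scale * dH

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """10-year risk 1 - exp(-[H0(a+10) - H0(a)] * exp(lp))."""
        lp = self.linear_predictor(X)
        dH = self.baseline_cumhaz_increment(X)
        return 1.0 - np.exp(-dH * np.exp(lp))

    def predict_risk_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject prediction records: id, model label, linear
        predictor and 10-year risk."""
        return pd.DataFrame({
            "id": X["id"] if "id" in X.columns else np.arange(len(X)),
            "model": self.label,
            "lp": self.linear_predictor(X),
            "ten_year_risk": self.predict_risk(X),
        })


def linear_predictor(model, X: pd.DataFrame, part: str | None = None):
    """Module-level wrapper: the linear predictor sum(beta_i * x_i) of a
    model (one per SCORE part, one for Globorisk)."""
    if isinstance(model, ScoreModel):
        if part is None:
            raise ValidationError("SCORE linear predictor requires a part")
        return model.linear_predictor(X, part)
    return model.linear_predictor(X)


def score_10yr_risk(coefs, X, **kwargs) -> np.ndarray:
    """10-year SCORE risk for a cohort table (thin wrapper over ScoreModel)."""
    return ScoreModel(coefficients=coefs, **kwargs).predict_risk(X)


def globorisk_10yr_risk(coefs, X, **kwargs) -> np.ndarray:
    """10-year Globorisk risk for a cohort table (wrapper over GloboriskModel)."""
    return GloboriskModel(coefficients=coefs, **kwargs).predict_risk(X)
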