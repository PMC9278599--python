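"""Model updating on a validation cohort: calibration slope of a frozen
linear predictor, baseline re-estimation, recalibrated predictions, and
full refits for hazard-ratio comparison.

The recalibration is the two-step "weak" update: (1) fit the survival
model with the frozen linear predictor as the *only* covariate — its
coefficient is the calibration slope (1 under perfect transportability);
(2) re-estimate the baseline holding ``slope * lp`` fixed as an offset so
the model-implied mean 10-year risk matches the cohort's observed risk.
Both steps run on the age timescale with delayed entry at baseline age.

For the two-part SCORE model each part is recalibrated against its own
cause-specific outcome (CHD death vs non-CHD CVD death) and the parts are
recombined on the survival scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .cohort import CHD_CODES, ValidationError, classify_cvd_death
from .engines import (GloboriskModel, ScoreModel, WeibullBaseline,
                      apply_diabetes_multiplier)
from .performance import km_risk

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    """Maximum-likelihood fitting failed to converge."""


# ---------------------------------------------------------------------------
# Weibull proportional-hazards likelihood with delayed entry
# ---------------------------------------------------------------------------

def _weibull_ph_negloglik(params, entry, exit_, d, X, offset, age_offset):
    alpha, logp = params[0], params[1]
    beta = params[2:]
    p = np.exp(logp)
    u1 = exit_ - age_offset
    u0 = np.maximum(entry - age_offset, 1e-12)
    lp = offset + (X @ beta if X is not None else 0.0)
    ll = np.sum(d * (alpha + logp + (p - 1.0) * np.log(u1) + lp))
    ll -= np.exp(alpha) * np.sum(np.exp(lp) * (u1 ** p - u0 ** p))
    return -ll


def _numeric_hessian(f, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps * eps)
            H[j, i] = H[i, j]
    return H


def fit_weibull_ph(entry, exit_, events, X=None, offset=None,
                   age_offset=20.0, free_baseline=True,
                   init_baseline=None):
    """Maximum-likelihood Weibull proportional-hazards fit on the age
    timescale with left truncation.

    Hazard: h(a) = exp(alpha) * p * (a - age_offset)^(p-1) * exp(offset + X beta).
    Returns (params, cov, loglik) where params = (alpha, log p, *beta);
    with ``free_baseline=False`` the baseline (alpha, log p) is held at
    ``init_baseline`` and only beta is fitted.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    d = np.asarray(events).astype(float)
    if offset is None:
        offset = np.zeros(len(entry))
    offset = np.asarray(offset, dtype=float)
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(entry):
            X = X.T
    n_beta = 0 if X is None else X.shape[1]
    if d.sum() < 1:
        raise FittingError("no events; cannot fit survival model")

    if init_baseline is None:
        p0 = 5.0
        u1 = exit_ - age_offset
        u0 = np.maximum(entry - age_offset, 1e-12)
        alpha0 = np.log(d.sum() / np.sum(np.exp(offset) * (u1 ** p0 - u0 ** p0)))
        init_baseline = (alpha0, np.log(p0))
    x0 = np.concatenate([init_baseline, np.zeros(n_beta)])

    if free_baseline:
        def nll(x):
            return _weibull_ph_negloglik(x, entry, exit_, d, X, offset,
                                         age_offset)
        free_idx = np.arange(2 + n_beta)
    else:
        fixed = np.asarray(init_baseline, dtype=float)

        def nll(b):
            return _weibull_ph_negloglik(np.concatenate([fixed, b]),
                                         entry, exit_, d, X, offset,
                                         age_offset)
        x0 = np.zeros(n_beta)
        free_idx = np.arange(n_beta)

    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-10,
                                          "maxiter": 5000})
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            raise FittingError(
                f"Weibull PH fit did not converge: {res.message}; "
                f"last point {res.x}")
    H = _numeric_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    if free_baseline:
        params = res.x
    else:
        params = np.concatenate([init_baseline, res.x])
        cov_full = np.zeros((2 + n_beta, 2 + n_beta))
        cov_full[2:, 2:] = cov
        cov = cov_full
    return params, cov, -res.fun


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class SlopeComponent:
    """Calibration slope (one model component) plus its baseline update."""

    name: str
    slope: float
    ci: tuple[float, float]
    se: float
    log_likelihood: float
    n_events: int
    baseline: object = None          # WeibullBaseline or hazard-scale float

    def __post_init__(self):
        if not (self.ci[0] <= self.slope <= self.ci[1]):
            raise ValidationError("slope CI must contain the point estimate")


@dataclass
class RecalibrationResult:
    """Slopes with 95% CIs and updated baseline parameters for a model."""

    model_label: str
    components: dict = field(default_factory=dict)
    form: str = "proportional_hazards"

    @property
    def slopes(self):
        return {k: v.slope for k, v in self.components.items()}


@dataclass
class RefitResult:
    """Hazard ratios of a full refit, for comparison with the original
    coefficients."""

    form: str
    summary: pd.DataFrame        # index: term; HR, ci_low, ci_high, coef, se, p
    log_likelihood: float


# ---------------------------------------------------------------------------
# Calibration slope
# ---------------------------------------------------------------------------

def _check_lp_events(lp, events):
    lp = np.asarray(lp, dtype=float)
    if np.ptp(lp) == 0:
        raise ValidationError("constant linear predictor: degenerate design")
    n_events = int(np.asarray(events).astype(int).sum())
    if n_events == 0:
        raise ValidationError("no events in cohort")
    if n_events < 10:
        warnings.warn(f"only {n_events} events; slope estimate is unstable",
                      stacklevel=3)
    return lp, n_events


def fit_calibration_slope(cohort: pd.DataFrame, lp, form: str,
                          event_col: str = "event", name: str = "overall",
                          age_offset: float = 20.0,
                          alpha: float = 0.05) -> SlopeComponent:
    """Fit the stated survival form with the frozen linear predictor as the
    sole covariate; the fitted coefficient is the calibration slope.

    ``cohort`` needs ``age``, ``time`` and the event column; the fit uses
    attained age as the time axis with entry at baseline age.
    """
    lp, n_events = _check_lp_events(lp, cohort[event_col])
    entry = cohort["age"].to_numpy(float)
    exit_ = entry + cohort["time"].to_numpy(float)
    d = cohort[event_col].to_numpy(int)
    z = stats.norm.ppf(1 - alpha / 2)

    if form == "weibull":
        params, cov, ll = fit_weibull_ph(entry, exit_, d, X=lp[:, None],
                                         age_offset=age_offset)
        slope = params[2]
        se = float(np.sqrt(max(cov[2, 2], 0.0)))
        baseline = WeibullBaseline(alpha=float(params[0]),
                                   p=float(np.exp(params[1])),
                                   age_offset=age_offset)
        return SlopeComponent(name=name, slope=float(slope),
                              ci=(slope - z * se, slope + z * se), se=se,
                              log_likelihood=ll, n_events=n_events,
                              baseline=baseline)
    if form == "proportional_hazards":
        from lifelines import CoxPHFitter
        df = pd.DataFrame({"entry": entry, "T": exit_, "E": d, "lp": lp})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E", entry_col="entry")
        slope = float(cph.params_["lp"])
        se = float(cph.standard_errors_["lp"])
        return SlopeComponent(name=name, slope=slope,
                              ci=(slope - z * se, slope + z * se), se=se,
                              log_likelihood=float(cph.log_likelihood_),
                              n_events=n_events)
    raise ValidationError(f"unknown form: {form!r}")


# ---------------------------------------------------------------------------
# Baseline update
# ---------------------------------------------------------------------------

def update_baseline(cohort: pd.DataFrame, scaled_lp, form: str,
                    event_col: str = "event", age_offset: float = 20.0,
                    model: GloboriskModel | None = None,
                    horizon: float = 10.0):
    """Re-estimate the baseline holding ``slope * lp`` fixed as an offset.

    Weibull form: refits (alpha, p) by maximum likelihood.  Proportional
    hazards: rescales the model's baseline cumulative hazard by the single
    factor that equates mean predicted 10-year risk with the cohort's
    KM-observed risk.  Returns a :class:`WeibullBaseline` or the scale
    factor respectively.
    """
    scaled_lp = np.asarray(scaled_lp, dtype=float)
    d = cohort[event_col].to_numpy(int)
    if d.sum() == 0:
        raise ValidationError("no events; cannot update baseline")
    if form == "weibull":
        entry = cohort["age"].to_numpy(float)
        exit_ = entry + cohort["time"].to_numpy(float)
        params, _, _ = fit_weibull_ph(entry, exit_, d, X=None,
                                      offset=scaled_lp,
                                      age_offset=age_offset)
        return WeibullBaseline(alpha=float(params[0]),
                               p=float(np.exp(params[1])),
                               age_offset=age_offset)
    if form == "proportional_hazards":
        if model is None:
            raise ValidationError("proportional-hazards update needs the engine")
        observed = km_risk(cohort["time"], d, horizon)
        dH = model.baseline_cumhaz_increment(cohort, horizon=horizon)
        rel = np.exp(scaled_lp)

        def gap(log_k):
            pred = 1.0 - np.exp(-np.exp(log_k) * dH * rel)
            return float(np.mean(pred) - observed)

        log_k = optimize.brentq(gap, -15.0, 15.0, xtol=1e-12)
        return float(np.exp(log_k))
    raise ValidationError(f"unknown form: {form!r}")


# ---------------------------------------------------------------------------
# SCORE cause-specific outcome split
# ---------------------------------------------------------------------------

def split_score_events(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add cause-specific event columns for the two SCORE parts.

    CHD deaths are events with an ICD-10 code in I20-I25 or I46.1; every
    other CVD death counts against the non-CHD part.  Events lacking a
    code raise, since the split is then undecidable.
    """
    df = cohort.copy()
    ev = df["event"].to_numpy(int)
    codes = df["icd_code"]
    if (pd.isna(codes) & (ev == 1)).any():
        raise ValidationError(
            "events without an ICD-10 code; cannot split SCORE outcome parts")
    is_chd = np.zeros(len(df), dtype=bool)
    has_event = ev == 1
    is_chd[has_event] = [classify_cvd_death(c, CHD_CODES)
                         for c in codes[has_event]]
    df["event_chd"] = (has_event & is_chd).astype(int)
    df["event_non_chd"] = (has_event & ~is_chd).astype(int)
    return df


# ---------------------------------------------------------------------------
# Recalibrated predictions
# ---------------------------------------------------------------------------

def recalibrated_risk(model, result: RecalibrationResult,
                      X: pd.DataFrame) -> np.ndarray:
    """Evaluate the engine's risk formula with slope-scaled linear
    predictor(s) and the updated baseline(s)."""
    if result.model_label != model.label:
        raise ValidationError(
            f"recalibration result is for {result.model_label!r}, "
            f"engine is {model.label!r}")
    if isinstance(model, ScoreModel):
        s_total = np.ones(len(X))
        for part in model.parts:
            comp = result.components[part]
            lp = comp.slope * model.linear_predictor(X, part)
            baseline = comp.baseline or model.coefs_.baselines[part]
            if isinstance(baseline, WeibullBaseline):
                baseline = {"male": baseline, "female": baseline}
            s_total *= model.part_survival(X, part, lp=lp, baseline=baseline)
        risk = 1.0 - s_total
        if model.diabetes_multiplier:
            risk = apply_diabetes_multiplier(
                risk, X["sex"].to_numpy(), X["diabetes"].to_numpy(float))
        return risk
    if isinstance(model, GloboriskModel):
        comp = result.components["overall"]
        lp = comp.slope * model.linear_predictor(X)
        k = 1.0 if comp.baseline is None else float(comp.baseline)
        dH = model.baseline_cumhaz_increment(X)
        return 1.0 - np.exp(-k * dH * np.exp(lp))
    raise ValidationError(f"unknown engine type: {type(model).__name__}")


class SlopeRecalibrator(BaseEstimator):
    """Two-step recalibrator of a frozen risk engine.

    ``fit`` estimates the calibration slope(s) of the engine's linear
    predictor(s) on a validation cohort and updates the baseline;
    ``predict_risk`` returns recalibrated 10-year risks.  SCORE engines
    are recalibrated per part on cause-specific outcomes (requires
    ``icd_code`` for events); Globorisk uses a Cox fit plus a baseline
    hazard rescale.

    Fitted attributes: ``result_`` (:class:`RecalibrationResult`),
    ``slope_`` (dict of slopes per component).
    """

    def __init__(self, model=None, horizon=10.0):
        self.model = model
        self.horizon = horizon

    def fit(self, X: pd.DataFrame, y=None):
        model = self.model
        if model is None:
            raise ValidationError("a risk engine must be supplied")
        if isinstance(model, ScoreModel):
            df = split_score_events(X)
            components = {}
            for part in model.parts:
                lp = model.linear_predictor(df, part)
                age_off = model.coefs_.baselines[part]["male"].age_offset
                comp = fit_calibration_slope(
                    df, lp, form="weibull", event_col=f"event_{part}",
                    name=part, age_offset=age_off)
                # per-sex baseline update against the part's own outcome
                base = {}
                for sex in ("male", "female"):
                    mask = (df["sex"] == sex).to_numpy()
                    if mask.sum() and df.loc[mask, f"event_{part}"].sum() > 0:
                        base[sex] = update_baseline(
                            df.loc[mask], comp.slope * lp[mask],
                            form="weibull", event_col=f"event_{part}",
                            age_offset=age_off)
                    else:
                        base[sex] = model.coefs_.baselines[part][sex]
                comp.baseline = base
                components[part] = comp
            self.result_ = RecalibrationResult(
                model_label=model.label, components=components,
                form="weibull")
        elif isinstance(model, GloboriskModel):
            lp = model.linear_predictor(X)
            comp = fit_calibration_slope(X, lp, form="proportional_hazards",
                                         name="overall")
            comp.baseline = update_baseline(
                X, comp.slope * lp, form="proportional_hazards",
                model=model, horizon=self.horizon)
            self.result_ = RecalibrationResult(
                model_label=model.label, components={"overall": comp},
                form="proportional_hazards")
        else:
            raise ValidationError(f"unknown engine type: {type(model).__name__}")
        self.slope_ = self.result_.slopes
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise ValidationError("recalibrator is not fitted")
        return recalibrated_risk(self.model, self.result_, X)


# ---------------------------------------------------------------------------
# Full refit (hazard-ratio comparison)
# ---------------------------------------------------------------------------

def _build_design(cohort: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    from .engines import _sex_indicator
    cols = {}
    for term in terms:
        parts = term.split(":")
        x = np.ones(len(cohort))
        for p in parts:
            if p == "sex":
                x = x * _sex_indicator(cohort).astype(float)
            elif p in cohort.columns:
                vals = pd.to_numeric(cohort[p], errors="coerce")
                if vals.isna().any():
                    raise ValidationError(f"term {p!r} has missing values")
                x = x * vals.to_numpy(float)
            else:
                raise ValidationError(f"term {p!r} absent from data")
        if np.ptp(x) == 0:
            raise ValidationError(f"term {term!r} is constant in the data")
        cols[term] = x
    return pd.DataFrame(cols, index=cohort.index)


def refit_model(cohort: pd.DataFrame, terms: list[str],
                form: str = "proportional_hazards",
                event_col: str = "event", age_offset: float = 20.0,
                alpha: float = 0.05) -> RefitResult:
    """Full maximum-likelihood refit of a model's term list on the cohort,
    on the age timescale, reporting hazard ratios with 95% CIs.

    Interaction terms are written ``"a:b"`` (e.g. ``"sex:smoking"``).
    """
    d = cohort[event_col].to_numpy(int)
    n_events = d.sum()
    if n_events < 10 * len(terms):
        warnings.warn(
            f"{n_events} events for {len(terms)} terms; fewer than 10 events "
            "per term", stacklevel=2)
    design = _build_design(cohort, terms)
    entry = cohort["age"].to_numpy(float)
    exit_ = entry + cohort["time"].to_numpy(float)
    z = stats.norm.ppf(1 - alpha / 2)

    if form == "weibull":
        params, cov, ll = fit_weibull_ph(entry, exit_, d,
                                         X=design.to_numpy(),
                                         age_offset=age_offset)
        coefs = params[2:]
        ses = np.sqrt(np.clip(np.diag(cov)[2:], 0.0, None))
    elif form == "proportional_hazards":
        from lifelines import CoxPHFitter
        df = design.copy()
        df.columns = [c.replace(":", "_x_") for c in df.columns]
        df["T"], df["E"], df["entry"] = exit_, d, entry
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="T", event_col="E", entry_col="entry")
        except Exception as exc:  # lifelines raises ConvergenceError
            raise FittingError(f"Cox refit failed: {exc}") from exc
        coefs = cph.params_.to_numpy()
        ses = cph.standard_errors_.to_numpy()
        ll = float(cph.log_likelihood_)
    else:
        raise ValidationError(f"unknown form: {form!r}")

    summary = pd.DataFrame({
        "coef": coefs,
        "se": ses,
        "hr": np.exp(coefs),
        "hr_ci_low": np.exp(coefs - z * ses),
        "hr_ci_high": np.exp(coefs + z * ses),
        "p": 2 * stats.norm.sf(np.abs(coefs) / np.where(ses > 0, ses, np.inf)),
    }, index=list(terms))
    return RefitResult(form=form, summary=summary, log_likelihood=ll)
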