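"""Cohort data model, delimited-text I/O, exposure/outcome derivation and imputation.

A cohort is held as a pandas DataFrame with one row per subject and the
canonical columns below.  Mandatory columns must be present after schema
mapping; optional columns are added as NA when absent.  Follow-up is in
years from the baseline examination, ``event`` flags fatal cardiovascular
disease, and ``icd_code`` (when available) carries the ICD-10 cause of
death used to resolve outcome definitions.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "id", "sex", "age", "sbp", "tc", "smoking", "time", "event",
]
OPTIONAL_COLUMNS = [
    "cohort", "diabetes", "fpg", "rpg", "glucose_med", "bmi",
    "hypertension", "cvd_history", "icd_code",
]
ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

SEX_CODES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "0": "female", "2": "female",
}

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")


class SchemaError(ValueError):
    """A mandatory column is missing or a config is malformed."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


# ---------------------------------------------------------------------------
# Outcome definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeDefinition:
    """A fatal-CVD outcome as a set of ICD-10 include ranges and exclusions.

    ``include`` entries are either single codes ("I46.1"), categories
    ("I21"), or ranges ("I20-I25") read at the 3-character category level.
    ``exclude`` entries at category level (e.g. "I62") remove the whole
    category; entries at sub-code level (e.g. "I67.1") remove only that
    sub-code.
    """

    name: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def contains(self, code: str) -> bool:
        return classify_cvd_death(code, self)


#: Harmonised outcome used for both models: ischaemic heart disease
#: (I20-I25), sudden cardiac death (I46.1) and stroke (I60-I69).
GLOBORISK_OUTCOME = OutcomeDefinition(
    name="globorisk",
    include=("I20-I25", "I46.1", "I60-I69"),
)

#: The SCORE project's own fatal-CVD definition.
SCORE_OUTCOME = OutcomeDefinition(
    name="score",
    include=("I10-I15", "I20-I25", "R96.0", "R96.1", "I44-I73"),
    exclude=("I45.6", "I51.4", "I52", "I60", "I62",
             "I67.1", "I67.5", "I67.7"),
)

#: Coronary subset used for the CHD part of the two-part SCORE model;
#: everything else inside an outcome definition counts as non-CHD CVD.
CHD_CODES = OutcomeDefinition(name="chd", include=("I20-I25", "I46.1"))


def _category(code: str) -> str:
    return code[:3]


def _in_range(category: str, lo: str, hi: str) -> bool:
    if category[0] != lo[0] or category[0] != hi[0]:
        return False
    return int(lo[1:3]) <= int(category[1:3]) <= int(hi[1:3])


def classify_cvd_death(icd_code: str, definition: OutcomeDefinition) -> bool:
    """True iff ``icd_code`` falls inside the definition's include ranges
    and is not excluded.

    Range membership is decided on the 3-character category (``I21.4`` is
    a member of ``I20-I25``).  Malformed codes raise ``ValidationError``.
    """
    code = str(icd_code).strip().upper()
    if not _ICD10_RE.match(code):
        raise ValidationError(f"malformed ICD-10 code: {icd_code!r}")
    cat = _category(code)
    included = False
    for entry in definition.include:
        if "-" in entry:
            lo, hi = entry.split("-")
            if _in_range(cat, lo.strip(), hi.strip()):
                included = True
        elif "." in entry:
            if code == entry:
                included = True
        elif cat == entry:
            included = True
    if not included:
        return False
    for entry in definition.exclude:
        if "." in entry:
            if code == entry:
                return False
        elif cat == entry:
            return False
    return True


def load_outcome_definitions(path) -> dict[str, OutcomeDefinition]:
    """Read outcome definitions from a YAML config (name -> include/exclude)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, block in raw.items():
        out[name] = OutcomeDefinition(
            name=name,
            include=tuple(block.get("include", ())),
            exclude=tuple(block.get("exclude", ())),
        )
    return out


# ---------------------------------------------------------------------------
# Exposure / follow-up derivation
# ---------------------------------------------------------------------------

def define_diabetes(fpg=None, rpg=None, glucose_med=None):
    """Diabetes: fasting glucose >= 126 mg/dL, random glucose >= 200 mg/dL,
    or use of glucose-lowering medication.

    All three inputs absent is a missing-data condition (imputation
    candidate), not a silent negative.
    """
    fpg_missing = fpg is None or (isinstance(fpg, float) and np.isnan(fpg))
    rpg_missing = rpg is None or (isinstance(rpg, float) and np.isnan(rpg))
    med_missing = glucose_med is None or (
        isinstance(glucose_med, float) and np.isnan(glucose_med))
    if fpg_missing and rpg_missing and med_missing:
        raise ValidationError(
            "diabetes status indeterminable: fpg, rpg and glucose_med all missing")
    if not fpg_missing and fpg <= 0:
        raise ValidationError("fpg must be positive")
    if not rpg_missing and rpg <= 0:
        raise ValidationError("rpg must be positive")
    return bool(
        (not fpg_missing and fpg >= 126)
        or (not rpg_missing and rpg >= 200)
        or (not med_missing and bool(glucose_med))
    )


def truncate_follow_up(time, event, horizon: float = 10.0):
    """Truncate follow-up at ``horizon`` years (default 10).

    Subjects followed beyond the horizon are administratively censored at
    it; events at exactly the horizon are retained as events (closed
    interval, matching the Kaplan-Meier evaluation time).  Accepts scalars
    or arrays.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if np.any(t <= 0):
        raise ValidationError("follow-up times must be positive")
    over = t > horizon
    t_out = np.where(over, horizon, t)
    e_out = np.where(over, 0, e).astype(int)
    if np.isscalar(time) or t.ndim == 0:
        return float(t_out), int(e_out)
    return t_out, e_out


# ---------------------------------------------------------------------------
# Reading cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A validated cohort table plus the row-level rejection report."""

    data: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.data)


def _detect_delimiter(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_schema(path) -> dict:
    """Field-name -> column-name mapping from a plain-text config.

    Accepts YAML mappings or simple ``field = column`` / ``field: column``
    lines.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = yaml.safe_load(text)
        if isinstance(parsed, dict):
            return {str(k): str(v) for k, v in parsed.items()}
    except yaml.YAMLError:
        pass
    mapping = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.replace("=", ":").partition(":")
        mapping[key.strip()] = value.strip()
    return mapping


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a mapped cohort table into valid records and a rejection report.

    Returns ``(valid, rejected)`` where ``rejected`` carries the original
    row number and the reason.
    """
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
        reasons[mask & (reasons == "")] = reason

    numeric = {}
    for col in ("age", "sbp", "tc", "time", "fpg", "rpg", "bmi"):
        if col in df.columns:
            numeric[col] = pd.to_numeric(df[col], errors="coerce")
    bad_num = pd.Series(False, index=df.index)
    for col in ("age", "sbp", "tc", "time"):
        bad_num |= df[col].notna() & numeric[col].isna()
    flag(bad_num, "unparseable numeric value")
    for col in ("age", "sbp", "tc", "time"):
        flag(df[col].isna(), f"missing {col}")
    flag(numeric["time"] <= 0, "non-positive follow-up time")
    for col in ("sbp", "tc", "fpg", "rpg"):
        if col in numeric:
            flag(numeric[col] <= 0, f"non-positive {col}")
    sex_norm = df["sex"].astype(str).str.strip().str.lower().map(SEX_CODES)
    flag(df["sex"].notna() & sex_norm.isna(), "unrecognised sex code")
    flag(df["sex"].isna(), "missing sex")
    event_num = pd.to_numeric(df["event"], errors="coerce")
    flag(~event_num.isin([0, 1]), "event must be 0 or 1")

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["row"] = np.asarray(df.index[bad]) + 2  # 1-based + header line
    rejected["reason"] = reasons[bad]

    valid = df.loc[~bad].copy()
    for col, series in numeric.items():
        valid[col] = series[~bad]
    valid["sex"] = sex_norm[~bad]
    valid["event"] = event_num[~bad].astype(int)
    for col in ("smoking", "diabetes", "glucose_med", "hypertension",
                "cvd_history"):
        if col in valid.columns:
            valid[col] = pd.to_numeric(valid[col], errors="coerce")
    return valid, rejected


def read_cohort(path, schema: dict | None = None,
                eligibility: bool = False,
                age_range: tuple[float, float] = (40.0, 80.0)) -> Cohort:
    """Read a delimited cohort file into a validated :class:`Cohort`.

    Parameters
    ----------
    path : str
        Comma- or tab-delimited text file with a header row.  Missing
        values may be coded as empty strings or ``NA``.
    schema : dict, optional
        Mapping from canonical field names to the file's column names.
    eligibility : bool
        When true, apply the analysis eligibility filter: baseline age
        within ``age_range`` (40-80 by default) and no CVD history.
        Exclusion counts are logged and stored on the result.
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str,
                     na_values=["", "NA", "na", "NaN"], keep_default_na=True,
                     skipinitialspace=True)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ALL_COLUMNS]

    valid, rejected = validate_records(df)
    if len(rejected):
        logger.warning("rejected %d row(s): %s", len(rejected),
                       rejected[["row", "reason"]].to_dict("records"))

    n_excluded = 0
    if eligibility:
        lo, hi = age_range
        ok = (valid["age"] >= lo) & (valid["age"] <= hi)
        ok &= ~(valid["cvd_history"].fillna(0).astype(float) > 0)
        n_excluded = int((~ok).sum())
        logger.info("eligibility filter excluded %d subject(s)", n_excluded)
        valid = valid.loc[ok]

    return Cohort(data=valid.reset_index(drop=True), rejected=rejected,
                  n_excluded=n_excluded)


def write_cohort(df: pd.DataFrame, path, sep=",") -> None:
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

_BINARY_FIELDS = {"smoking", "diabetes", "glucose_med", "hypertension",
                  "cvd_history", "event"}


def _design(df, predictors):
    X = np.column_stack([np.ones(len(df))] +
                        [pd.to_numeric(df[p]).to_numpy(float) for p in predictors])
    return X


def impute_single(table: pd.DataFrame, target: str,
                  predictors: list[str]) -> pd.DataFrame:
    """Single regression imputation of one variable.

    Continuous targets use ordinary least squares on the observed rows;
    binary targets use logistic regression with a 0.5 cut.  Observed
    values are left untouched.
    """
    df = table.copy()
    y = pd.to_numeric(df[target], errors="coerce")
    missing = y.isna()
    if not missing.any():
        return df
    observed = ~missing
    if not observed.any():
        raise ValidationError(
            f"{target} entirely missing; use impute_tc_donor with an external donor table")
    for p in predictors:
        if pd.to_numeric(df[p], errors="coerce").isna().any():
            raise ValidationError(f"predictor {p} has missing values")

    X_obs = _design(df.loc[observed], predictors)
    X_mis = _design(df.loc[missing], predictors)
    if np.linalg.matrix_rank(X_obs) < X_obs.shape[1]:
        raise ValidationError("rank-deficient design matrix for imputation")

    if target in _BINARY_FIELDS:
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(penalty=None, max_iter=1000)
        lr.fit(X_obs[:, 1:], y[observed].astype(int))
        pred = (lr.predict_proba(X_mis[:, 1:])[:, 1] >= 0.5).astype(float)
    else:
        beta, *_ = np.linalg.lstsq(X_obs, y[observed].to_numpy(float),
                                   rcond=None)
        pred = X_mis @ beta
    df.loc[missing, target] = pred
    logger.info("imputed %d value(s) of %s", int(missing.sum()), target)
    return df


def impute_tc_donor(table: pd.DataFrame, donor_table: pd.DataFrame,
                    predictors: list[str], target: str = "tc",
                    m: int = 5, seed: int = 0,
                    burn_in: int = 10) -> pd.DataFrame:
    """Donor-based chained-equation imputation of a variable that is
    entirely missing in the recipient table.

    The donor table (an external survey carrying the target) is appended
    to the recipient rows; ``m`` stochastic regression imputations are
    drawn by chained equations (target imputed last, ``burn_in`` cycles)
    and the draws are averaged into a single completed value per missing
    cell.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    shared = [p for p in predictors if p in donor_table.columns]
    if not shared:
        raise ValidationError("no shared predictors between donor and recipient")
    if target not in donor_table.columns:
        raise ValidationError(f"donor table lacks target {target}")

    rng = np.random.default_rng(seed)
    df = table.copy()
    n_rec = len(df)
    pooled = pd.concat(
        [df[shared + [target]], donor_table[shared + [target]]],
        ignore_index=True)
    y = pd.to_numeric(pooled[target], errors="coerce").to_numpy(float)
    miss = np.isnan(y)
    if not miss.any():
        return df
    X = _design(pooled, shared)
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    XtX = Xo.T @ Xo
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    dof = max(len(yo) - Xo.shape[1], 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(XtX)

    draws = np.zeros((m, int(miss.sum())))
    for j in range(m):
        y_work = y.copy()
        for _ in range(burn_in):
            # Bayesian linear regression draw: sigma^2 then beta | sigma^2
            if s2 > 0:
                sigma2 = s2 * dof / rng.chisquare(dof)
                beta = rng.multivariate_normal(beta_hat, sigma2 * XtX_inv,
                                               method="svd")
                noise = rng.normal(0.0, np.sqrt(sigma2), int(miss.sum()))
            else:
                sigma2 = 0.0
                beta = beta_hat
                noise = np.zeros(int(miss.sum()))
            y_work[miss] = X[miss] @ beta + noise
        draws[j] = y_work[miss]

    completed = draws.mean(axis=0)
    y[miss] = completed
    out_vals = y[:n_rec]
    df[target] = out_vals
    logger.info("donor-imputed %d value(s) of %s (m=%d)",
                int(miss[:n_rec].sum()), target, m)
    return df
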