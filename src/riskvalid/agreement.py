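"""Between-model agreement of predicted risks.

Continuous scale: intra-class correlation from the two-way ANOVA
decomposition over n subjects x 2 models — absolute agreement, single
measures by default (ICC(2,1) in the Shrout-Fleiss numbering), which
penalizes systematic shifts between the two risk scales; the consistency
variant ICC(3,1) is available by flag.  Dichotomized scale: Cohen's kappa
at a risk threshold (5% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import ValidationError


@dataclass
class AgreementResult:
    estimate: float
    ci: tuple[float, float]
    n: int
    method: str
    threshold: float | None = None
    notes: tuple = ()


def _anova_two_way(a, b):
    """Mean squares of the subjects x raters two-way layout with k = 2."""
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc(risks_a, risks_b, variant: str = "absolute_agreement",
        alpha: float = 0.05) -> AgreementResult:
    """Intra-class correlation of two paired risk vectors with an
    F-distribution-based 95% CI (McGraw-Wong single-measures forms)."""
    a = np.asarray(risks_a, dtype=float)
    b = np.asarray(risks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors of equal length required")
    if len(a) < 3:
        raise ValidationError("ICC needs at least 3 paired observations")
    n, k, msr, msc, mse = _anova_two_way(a, b)
    if msr <= 0:
        raise ValidationError("zero between-subject variance; ICC undefined")

    if variant == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est = (msr - mse) / denom
        # Satterthwaite df for the ICC(A,1) confidence bounds
        aa = k * est / (n * (1 - est)) if est < 1 else 0.0
        bb = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else 1.0
        if est >= 1:
            ci = (1.0, 1.0)
        else:
            v = (aa * msc + bb * mse) ** 2 / (
                (aa * msc) ** 2 / (k - 1)
                + (bb * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
            ci = (float(lower), float(upper))
    elif variant == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse <= 0:
            ci = (1.0, 1.0)
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))
    else:
        raise ValidationError(f"unknown ICC variant: {variant!r}")
    return AgreementResult(estimate=float(est), ci=ci, n=n,
                           method=f"icc_{variant}")


def kappa(risks_a, risks_b, pt: float = 0.05,
          alpha: float = 0.05) -> AgreementResult:
    """Cohen's kappa of the two risk vectors dichotomized at ``pt``
    (high risk iff risk >= pt), with an asymptotic-SE 95% CI.

    If both margins are entirely one category the chance agreement is 1
    and kappa is undefined (returned as NaN with a note).
    """
    from statsmodels.stats.inter_rater import cohens_kappa

    a = np.asarray(risks_a, dtype=float) >= pt
    b = np.asarray(risks_b, dtype=float) >= pt
    if a.shape != b.shape:
        raise ValidationError("paired vectors of equal length required")
    n = len(a)
    table = np.array([
        [np.sum(a & b), np.sum(a & ~b)],
        [np.sum(~a & b), np.sum(~a & ~b)],
    ], dtype=float)
    margins_a = table.sum(axis=1) / n
    margins_b = table.sum(axis=0) / n
    p_e = float(margins_a @ margins_b)
    if p_e >= 1.0 - 1e-15:
        return AgreementResult(estimate=np.nan, ci=(np.nan, np.nan), n=n,
                               method="cohen_kappa", threshold=pt,
                               notes=("kappa undefined: chance agreement 1",))
    res = cohens_kappa(table, return_results=True)
    return AgreementResult(estimate=float(res.kappa),
                           ci=(float(res.kappa_low), float(res.kappa_upp)),
                           n=n, method="cohen_kappa", threshold=pt)
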