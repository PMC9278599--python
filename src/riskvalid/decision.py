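"""Decision-curve analysis: net benefit, standardized net benefit (net
benefit fraction), bootstrap confidence bands, and between-model
comparison.

At a risk threshold ``pt`` with harm-to-benefit weight ``w = pt/(1-pt)``,

    NB  = (TP - w * FP) / N
    NBF = NB / pi = sensitivity - (1 - specificity) * w * (1 - pi) / pi

where ``pi`` is the cohort's 10-year incidence.  The treat-all policy has
NBF = 1 - w (1 - pi) / pi (crossing zero at pt = pi); treat-none is
identically zero.  A model's NBF can legitimately be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ValidationError
from .classification import ThresholdMetrics, km_classification_counts
from .performance import km_risk

DEFAULT_GRID = tuple(np.round(np.arange(0.005, 0.2001, 0.005), 4))


def net_benefit(metrics: ThresholdMetrics) -> float:
    """NB = (TP - w * FP) / N with w the odds of the threshold."""
    if not 0 < metrics.threshold < 1:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    return (metrics.tp - metrics.w * metrics.fp) / metrics.n


def nbf(nb: float, incidence: float) -> float:
    """Net benefit fraction (standardized net benefit): NB / incidence."""
    if incidence <= 0:
        raise ValidationError("incidence must be positive for the NBF")
    return nb / incidence


def nbf_from_metrics(metrics: ThresholdMetrics) -> float:
    return nbf(net_benefit(metrics), metrics.incidence)


def nbf_from_rates(sensitivity, specificity, pt, incidence) -> float:
    """NBF from summary rates: sens - (1 - spec) * [pt/(1-pt)] * (1-pi)/pi.

    Algebraically identical to ``nbf(net_benefit(...))`` on the expected
    counts; useful when only printed sensitivity/specificity are available.
    """
    if incidence <= 0:
        raise ValidationError("incidence must be positive for the NBF")
    if not 0 < pt < 1:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    w = pt / (1.0 - pt)
    return sensitivity - (1.0 - specificity) * w * (1.0 - incidence) / incidence


def treat_all_nbf(pt, incidence) -> float:
    """NBF of the treat-everyone policy, 1 - w (1 - pi)/pi; zero at pt = pi."""
    return nbf_from_rates(1.0, 0.0, pt, incidence)


@dataclass
class DecisionCurve:
    """NBF across a threshold grid with bootstrap bands and references."""

    model_label: str
    table: pd.DataFrame      # threshold, nbf, ci_low, ci_high, treat_all
    n_bootstrap: int
    seed: int

    @property
    def thresholds(self):
        return self.table["threshold"].to_numpy()


def _nbf_at(times, events, risks, pt, horizon):
    m = km_classification_counts(times, events, risks, pt, horizon)
    if m.incidence <= 0:
        return np.nan
    return nbf_from_metrics(m)


def decision_curve(times, events, risks, grid=DEFAULT_GRID,
                   n_bootstrap: int = 500, seed: int = 0,
                   horizon: float = 10.0,
                   model_label: str = "model") -> DecisionCurve:
    """Decision curve: per-threshold NBF with percentile bootstrap CIs
    from subject-level resamples, plus treat-all/treat-none references."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValidationError("threshold grid must lie strictly inside (0, 1)")
    if n_bootstrap < 2:
        raise ValidationError("n_bootstrap must be >= 2")
    if n_bootstrap < 200:
        warnings.warn("bootstrap CIs are unreliable below B = 200",
                      stacklevel=2)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    r = np.asarray(risks, dtype=float)
    n = len(t)

    point = np.array([_nbf_at(t, e, r, pt, horizon) for pt in grid])
    pi_overall = km_risk(t, e, horizon)
    treat_all = np.array([treat_all_nbf(pt, pi_overall) for pt in grid])

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, len(grid)))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        tb, eb, rb = t[idx], e[idx], r[idx]
        boots[b] = [_nbf_at(tb, eb, rb, pt, horizon) for pt in grid]
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)

    table = pd.DataFrame({
        "threshold": grid,
        "nbf": point,
        "ci_low": lo,
        "ci_high": hi,
        "treat_all": treat_all,
        "treat_none": np.zeros(len(grid)),
    })
    return DecisionCurve(model_label=model_label, table=table,
                         n_bootstrap=n_bootstrap, seed=seed)


def compare_models(times, events, risks_a, risks_b, pt,
                   n_bootstrap: int = 500, seed: int = 0,
                   horizon: float = 10.0,
                   ids_a=None, ids_b=None):
    """Paired bootstrap of the NBF difference (A - B) at one threshold.

    Both risk vectors must score the same subjects (asserted via ids when
    given); the same resample is applied to both models.  Returns
    ``(difference, (ci_low, ci_high))``.
    """
    ra = np.asarray(risks_a, dtype=float)
    rb = np.asarray(risks_b, dtype=float)
    if len(ra) != len(rb):
        raise ValidationError("risk vectors must score the same subjects")
    if ids_a is not None or ids_b is not None:
        if ids_a is None or ids_b is None or \
                not np.array_equal(np.asarray(ids_a), np.asarray(ids_b)):
            raise ValidationError("subject ids of the two models differ")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    n = len(t)

    diff = _nbf_at(t, e, ra, pt, horizon) - _nbf_at(t, e, rb, pt, horizon)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots[b] = (_nbf_at(t[idx], e[idx], ra[idx], pt, horizon)
                    - _nbf_at(t[idx], e[idx], rb[idx], pt, horizon))
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return float(diff), (float(lo), float(hi))
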