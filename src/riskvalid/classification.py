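"""Censoring-adjusted classification metrics at fixed risk thresholds.

With censored follow-up the 2x2 table cannot be counted directly; expected
true/false positive and negative counts are reconstructed from separate
Kaplan-Meier curves in the test-positive (risk >= pt) and test-negative
groups, assuming censoring independent of the model's predictors:

    TP = n+ * (1 - S+(10)),  FP = n+ * S+(10),
    FN = n- * (1 - S-(10)),  TN = n- * S-(10).

The incidence ``pi`` carried on the result is the mixture (TP + FN) / n of
the two group curves, so the bookkeeping identities TP + FN = pi * n and
the standardized net-benefit algebra hold exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import ValidationError
from .performance import km_curve

DEFAULT_THRESHOLDS = (0.03, 0.05, 0.07, 0.10)


@dataclass
class ThresholdMetrics:
    """Expected classification counts and derived metrics at one threshold."""

    threshold: float
    n: int
    tp: float
    fp: float
    fn: float
    tn: float
    sensitivity: float
    specificity: float
    incidence: float
    ppv: float = np.nan
    npv: float = np.nan
    lr_pos: float = np.nan
    lr_neg: float = np.nan
    notes: list = field(default_factory=list)

    @property
    def w(self) -> float:
        """Harm-to-benefit weight: odds of the risk threshold."""
        return self.threshold / (1.0 - self.threshold)


def km_classification_counts(times, events, risks, pt,
                             horizon: float = 10.0) -> ThresholdMetrics:
    """KM-adjusted expected TP/FP/FN/TN counts at risk threshold ``pt``.

    Test-positive is ``risk >= pt`` (closed on the left, so pt below the
    minimum risk is the treat-all limit).  Empty groups are handled as
    limits: no positives -> sensitivity 0 / specificity 1 (treat none),
    no negatives -> sensitivity 1 / specificity 0 (treat all).
    """
    if not 0 < pt < 1:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    r = np.asarray(risks, dtype=float)
    pos = r >= pt
    n = len(r)
    notes = []

    def group_counts(mask):
        m = int(mask.sum())
        if m == 0:
            return 0, 0.0, 0.0
        surv = km_curve(t[mask], e[mask]).survival_at(horizon)
        return m, m * (1.0 - surv), m * surv

    n_pos, tp, fp = group_counts(pos)
    n_neg, fn, tn = group_counts(~pos)
    if n_pos == 0:
        notes.append("no test-positive subjects: treat-none limit")
    if n_neg == 0:
        notes.append("no test-negative subjects: treat-all limit")

    events_exp = tp + fn
    nonevents_exp = fp + tn
    sensitivity = tp / events_exp if events_exp > 0 else np.nan
    specificity = tn / nonevents_exp if nonevents_exp > 0 else np.nan
    if n_pos == 0:
        sensitivity, specificity = 0.0, 1.0
    if n_neg == 0:
        sensitivity, specificity = 1.0, 0.0
    incidence = events_exp / n
    return ThresholdMetrics(threshold=pt, n=n, tp=tp, fp=fp, fn=fn, tn=tn,
                            sensitivity=sensitivity, specificity=specificity,
                            incidence=incidence, notes=notes)


def predictive_values(metrics: ThresholdMetrics) -> ThresholdMetrics:
    """Fill predictive values and likelihood ratios from the counts.

    Quantities whose denominator is zero are reported as NaN with the
    reason appended to ``notes``.
    """
    m = metrics
    if m.tp + m.fp > 0:
        m.ppv = m.tp / (m.tp + m.fp)
    else:
        m.notes.append("ppv undefined: no test positives")
    if m.tn + m.fn > 0:
        m.npv = m.tn / (m.tn + m.fn)
    else:
        m.notes.append("npv undefined: no test negatives")
    if m.specificity < 1:
        m.lr_pos = m.sensitivity / (1.0 - m.specificity)
    else:
        m.notes.append("lr+ undefined: specificity = 1")
    if m.specificity > 0:
        m.lr_neg = (1.0 - m.sensitivity) / m.specificity
    else:
        m.notes.append("lr- undefined: specificity = 0")
    return m


def metrics_table(times, events, risks,
                  thresholds=DEFAULT_THRESHOLDS,
                  horizon: float = 10.0) -> list[ThresholdMetrics]:
    """One :class:`ThresholdMetrics` per threshold (3/5/7/10% by default),
    with predictive values filled; duplicate thresholds are dropped with a
    warning."""
    ts = list(thresholds)
    uniq = sorted(set(ts))
    if len(uniq) != len(ts):
        warnings.warn("duplicate thresholds removed", stacklevel=2)
    if any(not 0 < pt < 1 for pt in uniq):
        raise ValidationError("thresholds must lie strictly inside (0, 1)")
    return [predictive_values(
        km_classification_counts(times, events, risks, pt, horizon))
        for pt in uniq]
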