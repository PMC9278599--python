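"""Censoring-aware discrimination and calibration.

The product-limit (Kaplan-Meier) estimator is implemented directly on
numpy arrays because it is evaluated inside bootstrap loops downstream;
ties between events and censorings at the same time are handled
events-first (the censored subject remains in the risk set for events at
that time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ValidationError


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """A fitted product-limit curve: S(0) = 1, non-increasing steps at
    event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int

    def survival_at(self, t):
        """S(t), right-continuous step function."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValidationError("evaluation time must be non-negative")
        idx = np.searchsorted(self.event_times, t_arr, side="right")
        surv = np.concatenate([[1.0], self.survival])
        out = surv[idx]
        return float(out) if np.isscalar(t) else out

    def risk_at(self, t):
        """1 - S(t): cumulative incidence ignoring competing risks."""
        s = self.survival_at(t)
        return 1.0 - s


def km_curve(times, events) -> KMCurve:
    """Fit the product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.size == 0:
        raise ValidationError("empty input to Kaplan-Meier")
    if np.any(t <= 0):
        raise ValidationError("times must be positive")
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ev_times, d = np.unique(ts[es == 1], return_counts=True)
    at_risk = len(ts) - np.searchsorted(ts, ev_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=ev_times, survival=surv, at_risk=at_risk,
                   n_events=d, n=len(ts))


def km_survival(times, events, t) -> float:
    """Kaplan-Meier survival probability at time ``t``."""
    return km_curve(times, events).survival_at(t)


def km_risk(times, events, t=10.0) -> float:
    """KM-observed risk 1 - S(t) (the observed 10-year risk by default)."""
    return km_curve(times, events).risk_at(t)


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

@dataclass
class CIndexResult:
    c: float
    ci: tuple[float, float]
    concordant: int
    discordant: int
    tied_risk: int

    @property
    def comparable(self) -> int:
        return self.concordant + self.discordant + self.tied_risk


def harrell_c(times, events, risks, alpha=0.05) -> CIndexResult:
    """Harrell's concordance index with an asymptotic 95% CI.

    Pairs are usable when the subject with the shorter follow-up had the
    event (a pair whose shorter time is censored is not comparable); ties
    in predicted risk count one half.  The SE is the Hanley-McNeil
    approximation driven by the event and non-event counts (the raw
    comparable-pair count understates the variance because pairs sharing
    a subject are correlated).
    """
    from sksurv.metrics import concordance_index_censored

    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    r = np.asarray(risks, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValidationError("risks must be finite")
    try:
        c, conc, disc, tied_r, _ = concordance_index_censored(e, t, r)
    except ValueError as exc:
        raise ValidationError(f"no comparable pairs for the C-index: {exc}")
    m = conc + disc + tied_r
    if m < 1:
        raise ValidationError("no comparable pairs for the C-index")
    n1 = max(int(e.sum()), 1)
    n0 = max(int((~e).sum()), 1)
    a = min(max(c, 1e-12), 1 - 1e-12)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a)
           + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = np.sqrt(max(var, 1e-300))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, c - z * se), min(1.0, c + z * se))
    return CIndexResult(c=float(c), ci=ci, concordant=int(conc),
                        discordant=int(disc), tied_risk=int(tied_r))


# ---------------------------------------------------------------------------
# Decile calibration
# ---------------------------------------------------------------------------

def decile_calibration(times, events, risks, ids=None, n_groups=10,
                       horizon=10.0) -> pd.DataFrame:
    """Calibration by deciles of predicted risk.

    Subjects are ranked by predicted risk (ties broken deterministically
    by subject id) and split into ``n_groups`` near-equal groups; each
    group reports its mean predicted risk, the KM-observed risk at the
    horizon, and the predicted/observed ratio.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    r = np.asarray(risks, dtype=float)
    n = len(r)
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    if n < 100:
        warnings.warn("decile calibration is unstable below n = 100",
                      stacklevel=2)
    if np.ptp(r) == 0:
        raise ValidationError(
            "all predicted risks identical; cannot form risk deciles")
    order = np.lexsort((ids, r))
    rows = []
    for g, idx in enumerate(np.array_split(order, n_groups), start=1):
        obs = km_curve(t[idx], e[idx]).risk_at(horizon)
        pred = float(r[idx].mean())
        rows.append({
            "decile": g,
            "n": len(idx),
            "mean_predicted": pred,
            "observed": obs,
            "ratio": pred / obs if obs > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def po_ratio(times, events, risks, horizon=10.0) -> float:
    """Mean predicted risk divided by the KM-observed risk at the horizon
    (>1 means overestimation)."""
    observed = km_risk(times, events, horizon)
    if observed <= 0:
        raise ValidationError("observed risk is zero; P/O ratio undefined")
    return float(np.mean(risks)) / observed
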