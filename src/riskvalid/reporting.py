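"""Pipeline orchestration: predict, recalibrate, validate, decision curves
and agreement, emitted as a structured validation report.

All indices are computed separately for men and women; report numbers are
pulled from the module outputs, never recomputed for display.  A
consistency pass re-derives every standardized-net-benefit cell from the
report's own sensitivity/specificity/incidence and asserts agreement to
1e-9 before the report is returned.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decision
from .agreement import icc, kappa
from .classification import DEFAULT_THRESHOLDS, metrics_table
from .cohort import ValidationError, read_cohort
from .performance import decile_calibration, harrell_c, po_ratio
from .recalibration import SlopeRecalibrator

REPORT_GRID = tuple(np.round(np.arange(0.01, 0.2001, 0.01), 4))


@dataclass
class ModelBlock:
    """Per-sex, per-model validation output."""

    sex: str
    model_label: str
    c_index: object
    recalibration: object
    po_ratio: float
    deciles: pd.DataFrame
    metrics: list
    curve: object


@dataclass
class ValidationReport:
    blocks: dict = field(default_factory=dict)       # (sex, label) -> ModelBlock
    agreement: dict = field(default_factory=dict)    # sex -> dict
    metadata: dict = field(default_factory=dict)

    def to_text(self) -> str:
        out = io.StringIO()
        meta = self.metadata
        out.write("Validation report\n=================\n")
        out.write(f"n = {meta['n']}, events = {meta['events']}, "
                  f"person-years = {meta['person_years']:.1f}\n")
        out.write(f"seed = {meta['seed']}, models = "
                  f"{', '.join(meta['models'])}\n")
        out.write(f"cohort digest = {meta['cohort_digest']}\n\n")
        for (sex, label), blk in self.blocks.items():
            out.write(f"--- {label} / {sex} ---\n")
            c = blk.c_index
            out.write(f"C statistic: {c.c:.3f} "
                      f"({c.ci[0]:.3f}-{c.ci[1]:.3f})\n")
            for name, comp in blk.recalibration.components.items():
                out.write(f"Calibration slope [{name}]: {comp.slope:.3f} "
                          f"({comp.ci[0]:.3f}-{comp.ci[1]:.3f})\n")
            out.write(f"Predicted/observed ratio: {blk.po_ratio:.2f}\n")
            for m in blk.metrics:
                out.write(
                    f"  pt={m.threshold:.0%}: sens {m.sensitivity:.2f}, "
                    f"spec {m.specificity:.2f}, "
                    f"NBF {decision.nbf_from_metrics(m):.2f}\n")
            out.write("\n")
        for sex, block in self.agreement.items():
            out.write(f"--- agreement / {sex} ---\n")
            if "icc" not in block:
                out.write(f"{block.get('note', 'not computed')}\n\n")
                continue
            out.write(f"ICC: {block['icc'].estimate:.3f} "
                      f"({block['icc'].ci[0]:.3f}-{block['icc'].ci[1]:.3f})\n")
            out.write(f"kappa@5%: {block['kappa'].estimate:.2f} "
                      f"({block['kappa'].ci[0]:.2f}-{block['kappa'].ci[1]:.2f})\n\n")
        return out.getvalue()

    def table2(self) -> pd.DataFrame:
        rows = []
        for (sex, label), blk in self.blocks.items():
            for m in blk.metrics:
                rows.append({
                    "model": label, "sex": sex,
                    "threshold": m.threshold,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv, "npv": m.npv,
                    "lr_pos": m.lr_pos, "lr_neg": m.lr_neg,
                    "incidence": m.incidence,
                    "nb": decision.net_benefit(m),
                    "nbf": decision.nbf_from_metrics(m),
                    "c_index": blk.c_index.c,
                })
        return pd.DataFrame(rows)

    def decile_table(self) -> pd.DataFrame:
        frames = []
        for (sex, label), blk in self.blocks.items():
            d = blk.deciles.copy()
            d.insert(0, "model", label)
            d.insert(1, "sex", sex)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    def curve_table(self) -> pd.DataFrame:
        frames = []
        for (sex, label), blk in self.blocks.items():
            c = blk.curve.table.copy()
            c.insert(0, "model", label)
            c.insert(1, "sex", sex)
            frames.append(c)
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.to_text())
        self.table2().to_csv(out / "table2.csv", index=False)
        self.decile_table().to_csv(out / "calibration_deciles.csv", index=False)
        self.curve_table().to_csv(out / "decision_curve.csv", index=False)


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:12]


def _consistency_check(report: ValidationReport) -> None:
    for blk in report.blocks.values():
        for m in blk.metrics:
            stored = decision.nbf_from_metrics(m)
            rebuilt = decision.nbf_from_rates(
                m.sensitivity, m.specificity, m.threshold, m.incidence)
            if not np.isclose(stored, rebuilt, atol=1e-9):
                raise ValidationError(
                    "internal inconsistency: NBF does not match its "
                    "sensitivity/specificity reconstruction")


def run_validation(cohort, models, seed: int = 0,
                   thresholds=DEFAULT_THRESHOLDS, grid=REPORT_GRID,
                   n_bootstrap: int = 200, horizon: float = 10.0,
                   sex: str = "both",
                   kappa_threshold: float = 0.05) -> ValidationReport:
    """Run the full validation pipeline on a cohort.

    Parameters
    ----------
    cohort : DataFrame or path
        A validated cohort table (or a delimited file readable by
        :func:`riskvalid.cohort.read_cohort`).
    models : sequence of engines
        One or two risk engines (``ScoreModel`` / ``GloboriskModel``).
        With two, a between-model agreement block is added.
    sex : "both", "male" or "female"
    """
    if isinstance(cohort, (str, bytes)) or hasattr(cohort, "__fspath__"):
        cohort = read_cohort(cohort).data
    if not len(models):
        raise ValidationError("at least one model config is required")
    sexes = ("male", "female") if sex == "both" else (sex,)

    report = ValidationReport()
    report.metadata = {
        "seed": seed,
        "n": int(len(cohort)),
        "events": int(cohort["event"].sum()),
        "person_years": float(cohort["time"].sum()),
        "models": [m.label for m in models],
        "cohort_digest": _digest(cohort[["age", "time", "event"]]),
    }

    recal_risks = {}
    for s in sexes:
        sub = cohort[cohort["sex"] == s].reset_index(drop=True)
        if not len(sub):
            raise ValidationError(f"no subjects of sex {s!r} (stage: stratify)")
        t = sub["time"].to_numpy(float)
        e = sub["event"].to_numpy(int)
        for model in models:
            try:
                recal = SlopeRecalibrator(model, horizon=horizon).fit(sub)
                risks = recal.predict_risk(sub)
            except Exception as exc:
                raise type(exc)(
                    f"{exc} (stage: recalibration, sex={s}, "
                    f"model={model.label})") from exc
            recal_risks[(s, model.label)] = risks
            blk = ModelBlock(
                sex=s, model_label=model.label,
                c_index=harrell_c(t, e, risks),
                recalibration=recal.result_,
                po_ratio=po_ratio(t, e, risks, horizon),
                deciles=decile_calibration(t, e, risks, ids=sub["id"],
                                           horizon=horizon),
                metrics=metrics_table(t, e, risks, thresholds, horizon),
                curve=decision.decision_curve(
                    t, e, risks, grid=grid, n_bootstrap=n_bootstrap,
                    seed=seed, horizon=horizon, model_label=model.label),
            )
            report.blocks[(s, model.label)] = blk
        if len(models) >= 2:
            ra = recal_risks[(s, models[0].label)]
            rb = recal_risks[(s, models[1].label)]
            report.agreement[s] = {
                "icc": icc(ra, rb),
                "kappa": kappa(ra, rb, pt=kappa_threshold),
                "models": (models[0].label, models[1].label),
            }
        else:
            report.agreement[s] = {
                "note": "agreement requires two models; one supplied"}

    _consistency_check(report)
    return report
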