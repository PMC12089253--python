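"""End-to-end analysis: annotate a cohort, evaluate the nested low-risk rules,
and run the whole chain reproducibly from a config.

The three nested rules mirror the published risk strategy:

* ``grace_lt109`` — GRACE 1.0 score < 109;
* ``grace_lt109_le1_abnormal`` — additionally at most one abnormal marker;
* ``grace_lt109_no_abnormal`` — additionally no abnormal marker.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from . import __version__ as _version
from .cohort import Cohort, PatientRecord, read_cohort, write_cohort
from .grace import GraceCategory, grace_assessment
from .metrics import confusion_from_rule, performance, round_half_up
from .panel import DEFAULT_CUTOFFS, MarkerCutoffs, evaluate_panel
from .stratify import assign_stratum
from .survival import cohort_km, logrank, mortality_at
from .triage import DEFAULT_THRESHOLDS, TriageThresholds, triage

__all__ = [
    "RULES",
    "rule_predicate",
    "record_stratum",
    "annotate_cohort",
    "evaluate_rules",
    "survival_comparison",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]


def _is_low(rec: PatientRecord) -> bool:
    return grace_assessment(rec).category is GraceCategory.LOW


def rule_predicate(rule: str, cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS) -> Callable[[PatientRecord], bool]:
    if rule == "grace_lt109":
        return _is_low
    if rule == "grace_lt109_le1_abnormal":
        return lambda r: _is_low(r) and evaluate_panel(r, cutoffs).abnormal_count <= 1
    if rule == "grace_lt109_no_abnormal":
        return lambda r: _is_low(r) and evaluate_panel(r, cutoffs).abnormal_count == 0
    raise ValueError(f"unknown rule {rule!r}")


RULES = ("grace_lt109", "grace_lt109_le1_abnormal", "grace_lt109_no_abnormal")


def record_stratum(rec: PatientRecord, cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS):
    return assign_stratum(grace_assessment(rec), evaluate_panel(rec, cutoffs))


def annotate_cohort(
    cohort: Cohort,
    *,
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
    cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Per-patient table: triage category, GRACE score/category, abnormal
    count, risk stratum, and outcome fields."""
    rows = []
    for rec in cohort:
        tri = triage(rec, thresholds)
        g = grace_assessment(rec)
        p = evaluate_panel(rec, cutoffs)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "triage_category": tri.category.value,
                "triage_reason": tri.reason.value,
                "grace_score": g.score,
                "grace_category": g.category.value,
                "abnormal_count": p.abnormal_count,
                "measured_count": p.measured_count,
                "stratum": assign_stratum(g, p).value,
                "death": rec.death,
                "followup_days": rec.followup_days,
            }
        )
    return pd.DataFrame(rows)


def evaluate_rules(
    cohort: Cohort,
    horizon_days: int = 365,
    *,
    cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS,
    ci_method: str = "default",
) -> pd.DataFrame:
    """Performance table (one row per nested rule), percent scale, 1 d.p.

    Columns mirror a clinical performance table: NPV/Se/Sp/PPV with 95% CIs,
    eligibility and FNR, plus the raw confusion counts that generated them.
    """
    rows = []
    for rule in RULES:
        ct = confusion_from_rule(cohort, rule_predicate(rule, cutoffs), horizon_days)
        perf = performance(ct, ci_method=ci_method)
        row: dict = {"rule": rule, "horizon_days": horizon_days,
                     "tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn}
        for name, est in (("npv", perf.npv), ("se", perf.sensitivity),
                          ("sp", perf.specificity), ("ppv", perf.ppv),
                          ("eligibility", perf.eligibility), ("fnr", perf.fnr)):
            if est.defined:
                row[name] = round_half_up(100.0 * est.value, 1)
                row[f"{name}_ci_low"] = round_half_up(100.0 * est.ci[0], 1)
                row[f"{name}_ci_high"] = round_half_up(100.0 * est.ci[1], 1)
            else:
                row[name] = row[f"{name}_ci_low"] = row[f"{name}_ci_high"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def survival_comparison(
    cohort: Cohort,
    rule: str = "grace_lt109_le1_abnormal",
    horizons: tuple[int, ...] = (30, 365),
    *,
    cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS,
) -> dict:
    """KM curves and log-rank test, low-risk arm vs the rest, per horizon."""
    pred = rule_predicate(rule, cutoffs)
    low = cohort.select(pred)
    rest = cohort.select(lambda r: not pred(r))
    out: dict = {"rule": rule, "horizons": {}}
    for h in horizons:
        def _arm(c: Cohort):
            times, events = [], []
            for r in c:
                t, e = r.followup_days, bool(r.death)
                if t > h:
                    t, e = h, False
                times.append(t)
                events.append(e)
            return times, events

        a, b = _arm(low), _arm(rest)
        lr = logrank(a, b)
        out["horizons"][h] = {
            "km_low": cohort_km(low, h),
            "km_rest": cohort_km(rest, h),
            "logrank": lr,
            "deaths_low": int(sum(a[1])),
            "deaths_rest": int(sum(b[1])),
        }
    return out


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the offending stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    column_map: dict = field(default_factory=dict)
    triage_thresholds: TriageThresholds = DEFAULT_THRESHOLDS
    marker_cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS
    horizons: tuple[int, ...] = (30, 365)
    ci_method: str = "default"
    seed: int = 0
    label: str | None = None

    def __post_init__(self):
        if tuple(sorted(self.horizons)) != tuple(self.horizons):
            raise ValueError("horizons must be sorted ascending")
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")

    def digest(self) -> str:
        payload = {
            "input": str(self.input_path),
            "map": dict(self.column_map),
            "thresholds": vars(self.triage_thresholds).copy(),
            "cutoffs": vars(self.marker_cutoffs).copy(),
            "horizons": list(self.horizons),
            "ci": self.ci_method,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run cohort -> triage -> panel -> stratify -> evaluate -> survival.

    Writes the bundle (annotated per-patient CSV, performance CSV per
    horizon, KM step tables, JSON run log) atomically: outputs are staged in
    a temp directory inside ``output_dir`` and moved into place only when
    every stage succeeded.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": _version, "config_hash": config.digest(), "seed": config.seed,
                 "stages": {}}

    try:
        cohort = read_cohort(config.input_path, config.column_map or None,
                             label=config.label, on_invalid="drop")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("cohort_model", str(exc)) from exc
    if len(cohort) == 0:
        raise PipelineError("cohort_model", "no valid records in input")
    log["stages"]["cohort_model"] = {
        "records": len(cohort),
        "rejected_rows": len(cohort.diagnostics),
        "rejection_reasons": cohort.diagnostics,
    }

    staging = Path(tempfile.mkdtemp(prefix=".staging-", dir=out_dir))
    try:
        try:
            annotated = annotate_cohort(cohort, thresholds=config.triage_thresholds,
                                        cutoffs=config.marker_cutoffs)
        except Exception as exc:
            raise PipelineError("esc_triage", str(exc)) from exc
        log["stages"]["esc_triage"] = annotated["triage_category"].value_counts().to_dict()
        log["stages"]["grace"] = annotated["grace_category"].value_counts().to_dict()
        log["stages"]["stratification"] = annotated["stratum"].value_counts().to_dict()
        annotated.to_csv(staging / "annotated.csv", index=False)

        try:
            for h in config.horizons:
                evaluate_rules(cohort, h, cutoffs=config.marker_cutoffs,
                               ci_method=config.ci_method).to_csv(
                    staging / f"performance_{h}d.csv", index=False)
        except Exception as exc:
            raise PipelineError("performance_metrics", str(exc)) from exc

        try:
            surv = survival_comparison(cohort, horizons=config.horizons,
                                       cutoffs=config.marker_cutoffs)
            for h, res in surv["horizons"].items():
                res["km_low"].as_table().to_csv(staging / f"km_lowrisk_{h}d.csv", index=False)
                res["km_rest"].as_table().to_csv(staging / f"km_rest_{h}d.csv", index=False)
            log["stages"]["survival"] = {
                str(h): {"logrank_statistic": res["logrank"].statistic,
                         "logrank_p": res["logrank"].p_value,
                         "deaths_low": res["deaths_low"],
                         "deaths_rest": res["deaths_rest"]}
                for h, res in surv["horizons"].items()
            }
        except Exception as exc:
            raise PipelineError("survival", str(exc)) from exc

        (staging / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        for f in staging.iterdir():
            os.replace(f, out_dir / f.name)
    finally:
        for leftover in staging.glob("*"):
            leftover.unlink()
        staging.rmdir()
    return log
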