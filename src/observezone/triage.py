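"""ESC 0/1-h hs-cTnT triage: rule-out, rule-in, or observe zone.

The accelerated protocol classifies a presentation from the 0-h troponin, the
0-to-1-h absolute change, and the time since symptom onset:

* rule-out — presentation > 3 h after onset with 0-h below the assay's limit
  of detection (< 5 ng/L), or 0-h < 12 ng/L with an absolute 1-h change
  < 3 ng/L;
* rule-in — 0-h >= 52 ng/L, or an absolute 1-h change >= 5 ng/L;
* observe zone — neither rule fires.

A record whose 1-h sample is missing and for which no single-sample branch
applies is NOT_APPLICABLE rather than observe: serial sampling is required to
place it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import Cohort, PatientRecord

__all__ = [
    "TriageCategory",
    "TriageReason",
    "TriageThresholds",
    "TriageResult",
    "triage",
    "triage_cohort",
]


class TriageCategory(str, Enum):
    RULE_OUT = "RULE_OUT"
    RULE_IN = "RULE_IN"
    OBSERVE = "OBSERVE"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class TriageReason(str, Enum):
    LOD_SINGLE = "LOD_SINGLE"        # >3 h after onset, 0 h below limit of detection
    LOW_DELTA = "LOW_DELTA"          # 0 h < 12 ng/L and |delta| < 3 ng/L
    HIGH_BASELINE = "HIGH_BASELINE"  # 0 h >= 52 ng/L
    HIGH_DELTA = "HIGH_DELTA"        # |delta| >= 5 ng/L
    NEITHER = "NEITHER"              # observe zone
    MISSING_SERIAL = "MISSING_SERIAL"


@dataclass(frozen=True)
class TriageThresholds:
    """Assay-specific cutoffs (ng/L); defaults are the hs-cTnT values."""

    lod: float = 5.0              # limit of detection, single-sample rule-out
    low_baseline: float = 12.0    # 0-h ceiling for the delta rule-out
    low_delta: float = 3.0        # |delta| below this rules out
    high_baseline: float = 52.0   # 0-h at/above this rules in
    high_delta: float = 5.0       # |delta| at/above this rules in
    onset_h_min: float = 3.0      # minimum time since onset for the LoD rule

    def __post_init__(self):
        for name in ("lod", "low_baseline", "low_delta", "high_baseline", "high_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class TriageResult:
    category: TriageCategory
    reason: TriageReason


DEFAULT_THRESHOLDS = TriageThresholds()


def triage(record: PatientRecord, thresholds: TriageThresholds = DEFAULT_THRESHOLDS) -> TriageResult:
    """Classify one record. Rule-in is evaluated before rule-out (fail-safe).

    The absolute change is ``|1 h - 0 h|``, direction-agnostic. A missing
    time-since-onset disables only the LoD single-sample branch.
    """
    c0 = record.hs_ctnt_0h
    c1 = record.hs_ctnt_1h
    if c0 is None:
        raise ValueError("hs_ctnt_0h is required for triage")
    if c0 < 0 or (c1 is not None and c1 < 0):
        raise ValueError("troponin concentrations must be non-negative")
    t = thresholds
    delta = None if c1 is None else abs(c1 - c0)

    if c0 >= t.high_baseline:
        return TriageResult(TriageCategory.RULE_IN, TriageReason.HIGH_BASELINE)
    if delta is not None and delta >= t.high_delta:
        return TriageResult(TriageCategory.RULE_IN, TriageReason.HIGH_DELTA)

    onset = record.time_since_onset_h
    if onset is not None and onset > t.onset_h_min and c0 < t.lod:
        return TriageResult(TriageCategory.RULE_OUT, TriageReason.LOD_SINGLE)
    if c0 < t.low_baseline and delta is not None and delta < t.low_delta:
        return TriageResult(TriageCategory.RULE_OUT, TriageReason.LOW_DELTA)

    if c1 is None:
        return TriageResult(TriageCategory.NOT_APPLICABLE, TriageReason.MISSING_SERIAL)
    return TriageResult(TriageCategory.OBSERVE, TriageReason.NEITHER)


def triage_cohort(
    cohort: Cohort, thresholds: TriageThresholds = DEFAULT_THRESHOLDS
) -> tuple[pd.DataFrame, Counter]:
    """Per-patient triage table plus category counts.

    Applicable categories (rule-out / rule-in / observe) partition the
    applicable records; NOT_APPLICABLE is counted separately.
    """
    rows = []
    counts: Counter = Counter()
    for rec in cohort:
        res = triage(rec, thresholds)
        rows.append(
            {"patient_id": rec.patient_id, "category": res.category.value, "reason": res.reason.value}
        )
        counts[res.category] += 1
    table = pd.DataFrame(rows, columns=["patient_id", "category", "reason"])
    return table, counts
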