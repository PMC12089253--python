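"""Six-biomarker abnormality panel and the CKD-EPI 2021 eGFR equation.

A marker is NORMAL when it lies strictly inside its low-risk range
(CRP < 10 mg/dL, NT-proBNP < 300 ng/L, D-dimer < 5 mg/L, eGFR > 30
mL/min/1.73 m2, copeptin < 10 pmol/L, hemoglobin > 10 g/dL), ABNORMAL when
measured and outside it (boundary equality counts as abnormal, the normal
ranges being strict inequalities), and MISSING when not measured. Missing
markers never increment the abnormal count: in the source registries the
non-routine markers were ordered at clinical discretion, so absence of a
measurement carries no positive information. ``measured_count`` lets callers
restrict to fully measured subsets if they disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import Cohort, PatientRecord

__all__ = [
    "MarkerStatus",
    "MarkerCutoffs",
    "BiomarkerPanelResult",
    "MARKERS",
    "evaluate_panel",
    "egfr_ckdepi",
    "panel_prevalence",
    "DEFAULT_CUTOFFS",
]

#: panel markers in canonical order
MARKERS = ("crp", "ntprobnp", "ddimer", "egfr", "copeptin", "hemoglobin")


class MarkerStatus(str, Enum):
    NORMAL = "NORMAL"
    ABNORMAL = "ABNORMAL"
    MISSING = "MISSING"


@dataclass(frozen=True)
class MarkerCutoffs:
    """Cutoffs defining the low-risk side of each marker.

    ``*_max`` markers are normal strictly below the cutoff; ``*_min`` markers
    strictly above it.
    """

    crp_max: float = 10.0          # mg/dL
    ntprobnp_max: float = 300.0    # ng/L
    ddimer_max: float = 5.0        # mg/L FEU
    egfr_min: float = 30.0         # mL/min/1.73 m2
    copeptin_max: float = 10.0     # pmol/L
    hemoglobin_min: float = 10.0   # g/dL

    def __post_init__(self):
        for f in ("crp_max", "ntprobnp_max", "ddimer_max", "egfr_min",
                  "copeptin_max", "hemoglobin_min"):
            if getattr(self, f) <= 0:
                raise ValueError(f"cutoff {f} must be positive")


DEFAULT_CUTOFFS = MarkerCutoffs()


@dataclass(frozen=True)
class BiomarkerPanelResult:
    status: dict  # marker name -> MarkerStatus
    abnormal_count: int
    measured_count: int

    def __post_init__(self):
        assert 0 <= self.abnormal_count <= self.measured_count <= len(MARKERS)


def egfr_ckdepi(creatinine_mg_dl: float, age_y: float, sex: str | None) -> float | None:
    """Race-free CKD-EPI 2021 creatinine eGFR (Inker et al., NEJM 2021).

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age
    * 1.012 [if female], with k = 0.7 (F) / 0.9 (M) and a = -0.241 (F) /
    -0.302 (M). Returns ``None`` when sex is missing (the equation is
    sex-specific).
    """
    if sex is None:
        return None
    s = sex.upper()
    if s not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    if creatinine_mg_dl is None or creatinine_mg_dl <= 0:
        raise ValueError("creatinine must be positive")
    if age_y is None or age_y <= 0:
        raise ValueError("age must be positive")
    kappa = 0.7 if s == "F" else 0.9
    alpha = -0.241 if s == "F" else -0.302
    ratio = creatinine_mg_dl / kappa
    g = 142.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.200 * 0.9938 ** age_y
    if s == "F":
        g *= 1.012
    return g


def _record_egfr(record: PatientRecord) -> float | None:
    # site-reported eGFR wins over one derived from creatinine
    if record.egfr is not None:
        return record.egfr
    if record.creatinine_mg_dl is not None and record.age_y is not None:
        return egfr_ckdepi(record.creatinine_mg_dl, record.age_y, record.sex)
    return None


def evaluate_panel(
    record: PatientRecord, cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS
) -> BiomarkerPanelResult:
    """Per-marker status and the abnormal count used by the risk tree."""
    values = {
        "crp": record.crp,
        "ntprobnp": record.ntprobnp,
        "ddimer": record.ddimer,
        "egfr": _record_egfr(record),
        "copeptin": record.copeptin,
        "hemoglobin": record.hemoglobin,
    }
    normal_below = {
        "crp": cutoffs.crp_max,
        "ntprobnp": cutoffs.ntprobnp_max,
        "ddimer": cutoffs.ddimer_max,
        "copeptin": cutoffs.copeptin_max,
    }
    normal_above = {"egfr": cutoffs.egfr_min, "hemoglobin": cutoffs.hemoglobin_min}

    status: dict[str, MarkerStatus] = {}
    for marker in MARKERS:
        v = values[marker]
        if v is None:
            status[marker] = MarkerStatus.MISSING
            continue
        if v < 0:
            raise ValueError(f"{marker} is negative ({v})")
        if marker in normal_below:
            ok = v < normal_below[marker]
        else:
            ok = v > normal_above[marker]
        status[marker] = MarkerStatus.NORMAL if ok else MarkerStatus.ABNORMAL

    measured = sum(1 for s in status.values() if s is not MarkerStatus.MISSING)
    abnormal = sum(1 for s in status.values() if s is MarkerStatus.ABNORMAL)
    return BiomarkerPanelResult(status=status, abnormal_count=abnormal, measured_count=measured)


def panel_prevalence(
    cohort: Cohort, cutoffs: MarkerCutoffs = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Per-marker measurement frequency and the normal/abnormal split.

    Returns one row per marker with ``measured_fraction`` (of the cohort) and
    ``normal_fraction`` / ``abnormal_fraction`` (of the measured values).
    Empty cohort -> empty table.
    """
    if len(cohort) == 0:
        return pd.DataFrame(
            columns=["marker", "measured_fraction", "normal_fraction", "abnormal_fraction"]
        )
    measured = {m: 0 for m in MARKERS}
    abnormal = {m: 0 for m in MARKERS}
    for rec in cohort:
        res = evaluate_panel(rec, cutoffs)
        for m, s in res.status.items():
            if s is not MarkerStatus.MISSING:
                measured[m] += 1
                if s is MarkerStatus.ABNORMAL:
                    abnormal[m] += 1
    n = len(cohort)
    rows = []
    for m in MARKERS:
        meas = measured[m]
        rows.append(
            {
                "marker": m,
                "measured_fraction": meas / n,
                "normal_fraction": (meas - abnormal[m]) / meas if meas else float("nan"),
                "abnormal_fraction": abnormal[m] / meas if meas else float("nan"),
            }
        )
    return pd.DataFrame(rows)
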