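"""GRACE 1.0 risk score (eight admission variables) and risk categories.

The score sums banded points for age, heart rate, systolic blood pressure and
serum creatinine with Killip class and three binary findings (cardiac arrest
at admission, ST-segment deviation, elevated cardiac enzymes). Point
assignments follow the published GRACE 1.0 scoring table for the
eight-variable admission model (Granger et al., Arch Intern Med 2003; the
model shipped in the original GRACE risk calculator, cf. Fox et al., BMJ
2006). Categories use the conventional cutpoints: low < 109 points,
intermediate 109-140, high > 140.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .cohort import PatientRecord

__all__ = [
    "GraceCategory",
    "GraceAssessment",
    "grace_category",
    "compute_grace_score",
    "grace_assessment",
    "LOW_MAX",
    "INTERMEDIATE_MAX",
]

LOW_MAX = 108          # low risk is strictly < 109
INTERMEDIATE_MAX = 140  # high risk is strictly > 140


class GraceCategory(str, Enum):
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class GraceAssessment:
    score: int
    category: GraceCategory


# (upper bound exclusive, points); the last band is open-ended.
_AGE_BANDS = ((30, 0), (40, 8), (50, 25), (60, 41), (70, 58), (80, 75), (90, 91), (None, 100))
_HR_BANDS = ((50, 0), (70, 3), (90, 9), (110, 15), (150, 24), (200, 38), (None, 46))
_SBP_BANDS = ((80, 58), (100, 53), (120, 43), (140, 34), (160, 24), (200, 10), (None, 0))
_CREAT_BANDS = ((0.4, 1), (0.8, 4), (1.2, 7), (1.6, 10), (2.0, 13), (4.0, 21), (None, 28))
_KILLIP_POINTS = {1: 0, 2: 20, 3: 39, 4: 59}
_CARDIAC_ARREST_POINTS = 39
_ST_DEVIATION_POINTS = 28
_ELEVATED_ENZYMES_POINTS = 14


def _band_points(value: float, bands) -> int:
    for upper, pts in bands:
        if upper is None or value < upper:
            return pts
    raise AssertionError("unreachable")


def grace_category(score: int) -> GraceCategory:
    """Map a point total to the low / intermediate / high risk category."""
    if score < 0:
        raise ValueError("GRACE score must be non-negative")
    if score <= LOW_MAX:
        return GraceCategory.LOW
    if score <= INTERMEDIATE_MAX:
        return GraceCategory.INTERMEDIATE
    return GraceCategory.HIGH


def compute_grace_score(
    age_y: float,
    heart_rate_bpm: float,
    sbp_mmHg: float,
    creatinine_mg_dl: float,
    killip_class: int,
    cardiac_arrest: bool,
    st_deviation: bool,
    elevated_enzymes: bool,
) -> int:
    """Deterministic integer point total from the eight admission variables."""
    if killip_class not in _KILLIP_POINTS:
        raise ValueError(f"killip_class must be 1-4, got {killip_class}")
    for name, v in (("age_y", age_y), ("heart_rate_bpm", heart_rate_bpm),
                    ("sbp_mmHg", sbp_mmHg), ("creatinine_mg_dl", creatinine_mg_dl)):
        if v is None or v < 0:
            raise ValueError(f"{name} must be a non-negative number")
    score = (
        _band_points(age_y, _AGE_BANDS)
        + _band_points(heart_rate_bpm, _HR_BANDS)
        + _band_points(sbp_mmHg, _SBP_BANDS)
        + _band_points(creatinine_mg_dl, _CREAT_BANDS)
        + _KILLIP_POINTS[killip_class]
        + (_CARDIAC_ARREST_POINTS if cardiac_arrest else 0)
        + (_ST_DEVIATION_POINTS if st_deviation else 0)
        + (_ELEVATED_ENZYMES_POINTS if elevated_enzymes else 0)
    )
    return int(score)


def grace_assessment(record: PatientRecord) -> GraceAssessment:
    """Score + category for a record.

    A precomputed ``grace_score`` takes precedence; otherwise the score is
    computed from the eight raw inputs (all must be present).
    """
    if record.grace_score is not None:
        score = int(record.grace_score)
    elif record.has_grace_inputs():
        score = compute_grace_score(
            record.age_y,
            record.heart_rate_bpm,
            record.sbp_mmHg,
            record.creatinine_mg_dl,
            record.killip_class,
            record.cardiac_arrest,
            record.st_deviation,
            record.elevated_enzymes,
        )
    else:
        raise ValueError(
            f"record {record.patient_id!r}: no grace_score and incomplete GRACE inputs"
        )
    return GraceAssessment(score=score, category=grace_category(score))
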