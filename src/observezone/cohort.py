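"""Patient-level cohort schema, validation and delimited-text I/O.

One row is one emergency-department presentation with suspected NSTE-ACS:
serial high-sensitivity troponin T values, the eight GRACE 1.0 inputs (or a
precomputed score), the optional six-marker panel, and the all-cause-death
outcome with follow-up time.

Units are fixed by the schema and never auto-converted: hs-cTnT and NT-proBNP
in ng/L, CRP in mg/dL, D-dimer in mg/L (FEU), copeptin in pmol/L, hemoglobin
in g/dL, creatinine in mg/dL, eGFR in mL/min/1.73 m2.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_column_map",
    "validate_record",
    "GRACE_INPUT_FIELDS",
    "COLUMNS",
]

#: the eight clinical inputs of the GRACE 1.0 score
GRACE_INPUT_FIELDS = (
    "age_y",
    "heart_rate_bpm",
    "sbp_mmHg",
    "creatinine_mg_dl",
    "killip_class",
    "cardiac_arrest",
    "st_deviation",
    "elevated_enzymes",
)

_FLOAT_FIELDS = (
    "time_since_onset_h",
    "hs_ctnt_0h",
    "hs_ctnt_1h",
    "age_y",
    "heart_rate_bpm",
    "sbp_mmHg",
    "creatinine_mg_dl",
    "crp",
    "ntprobnp",
    "ddimer",
    "copeptin",
    "hemoglobin",
    "egfr",
)
_INT_FIELDS = ("killip_class", "grace_score", "followup_days")
_BOOL_FIELDS = ("cardiac_arrest", "st_deviation", "elevated_enzymes", "death", "admitted")

#: canonical column order of the CSV layout
COLUMNS = (
    "patient_id",
    "time_since_onset_h",
    "hs_ctnt_0h",
    "hs_ctnt_1h",
    "age_y",
    "sex",
    "heart_rate_bpm",
    "sbp_mmHg",
    "creatinine_mg_dl",
    "killip_class",
    "cardiac_arrest",
    "st_deviation",
    "elevated_enzymes",
    "grace_score",
    "crp",
    "ntprobnp",
    "ddimer",
    "copeptin",
    "hemoglobin",
    "egfr",
    "death",
    "followup_days",
    "admitted",
)

_MANDATORY_COLUMNS = ("patient_id", "hs_ctnt_0h", "death", "followup_days")

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


class SchemaError(ValueError):
    """The file layout does not match the cohort schema (e.g. missing column)."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; carries row-indexed diagnostics."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        preview = "; ".join(self.diagnostics[:5])
        more = "" if len(self.diagnostics) <= 5 else f" (+{len(self.diagnostics) - 5} more)"
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {preview}{more}")


@dataclass
class PatientRecord:
    """A single validated presentation.

    Mandatory: ``patient_id``, ``hs_ctnt_0h`` (ng/L), ``death``,
    ``followup_days`` (day of death when ``death`` is true). Everything else
    may be missing (``None``), subject to the invariant that either
    ``grace_score`` or all eight GRACE inputs are present.
    """

    patient_id: str
    hs_ctnt_0h: float
    death: bool
    followup_days: int
    time_since_onset_h: float | None = None
    hs_ctnt_1h: float | None = None
    age_y: float | None = None
    sex: str | None = None  # "F" / "M"; needed only to derive eGFR from creatinine
    heart_rate_bpm: float | None = None
    sbp_mmHg: float | None = None
    creatinine_mg_dl: float | None = None
    killip_class: int | None = None
    cardiac_arrest: bool | None = None
    st_deviation: bool | None = None
    elevated_enzymes: bool | None = None
    grace_score: int | None = None
    crp: float | None = None
    ntprobnp: float | None = None
    ddimer: float | None = None
    copeptin: float | None = None
    hemoglobin: float | None = None
    egfr: float | None = None
    admitted: bool | None = None

    def has_grace_inputs(self) -> bool:
        return all(getattr(self, f) is not None for f in GRACE_INPUT_FIELDS)

    def copy(self, **changes) -> "PatientRecord":
        return replace(self, **changes)


def validate_record(rec: PatientRecord) -> list[str]:
    """Return a list of problems (empty when the record is valid)."""
    problems: list[str] = []
    if not rec.patient_id:
        problems.append("patient_id is empty")
    if rec.hs_ctnt_0h is None:
        problems.append("hs_ctnt_0h is missing")
    for name in ("hs_ctnt_0h", "hs_ctnt_1h", "time_since_onset_h", "crp", "ntprobnp",
                 "ddimer", "copeptin", "hemoglobin", "egfr", "creatinine_mg_dl",
                 "heart_rate_bpm", "sbp_mmHg"):
        v = getattr(rec, name)
        if v is not None and v < 0:
            problems.append(f"{name} is negative ({v})")
    if rec.age_y is not None and rec.age_y <= 0:
        problems.append(f"age_y must be positive ({rec.age_y})")
    if rec.followup_days is None or rec.followup_days < 0:
        problems.append("followup_days must be a non-negative integer")
    if rec.killip_class is not None and rec.killip_class not in (1, 2, 3, 4):
        problems.append(f"killip_class outside 1-4 ({rec.killip_class})")
    if rec.grace_score is not None and rec.grace_score < 0:
        problems.append(f"grace_score is negative ({rec.grace_score})")
    if rec.sex is not None and rec.sex.upper() not in ("F", "M"):
        problems.append(f"sex must be 'F' or 'M' ({rec.sex!r})")
    if rec.grace_score is None and not rec.has_grace_inputs():
        missing = [f for f in GRACE_INPUT_FIELDS if getattr(rec, f) is None]
        problems.append(
            "grace_score absent and GRACE inputs incomplete (missing: " + ", ".join(missing) + ")"
        )
    return problems


@dataclass
class Cohort:
    """An ordered collection of validated :class:`PatientRecord`."""

    records: list[PatientRecord] = field(default_factory=list)
    label: str = ""
    diagnostics: list[str] = field(default_factory=list)

    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def select(self, predicate: Callable[[PatientRecord], bool]) -> "Cohort":
        return Cohort([r for r in self.records if predicate(r)], label=self.label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_record_to_row(r) for r in self.records], columns=list(COLUMNS))

    def check_unique_ids(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.patient_id in seen:
                raise CohortValidationError([f"duplicate patient_id {r.patient_id!r}"])
            seen.add(r.patient_id)


def _parse_value(name: str, raw: str, na_values: Iterable[str]):
    if raw is None or raw.strip() in na_values:
        return None
    raw = raw.strip()
    if name in _FLOAT_FIELDS:
        try:
            return float(raw)
        except ValueError:
            raise ValueError(f"non-numeric value {raw!r} in numeric field {name}")
    if name in _INT_FIELDS:
        try:
            f = float(raw)
        except ValueError:
            raise ValueError(f"non-numeric value {raw!r} in integer field {name}")
        if f != int(f):
            raise ValueError(f"non-integer value {raw!r} in integer field {name}")
        return int(f)
    if name in _BOOL_FIELDS:
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"non-boolean value {raw!r} in boolean field {name}")
    return raw


def read_column_map(path: str | Path) -> dict[str, str]:
    """Parse a ``user_column = schema_column`` key-value mapping file.

    Lines starting with '#' and blank lines are ignored.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"bad mapping line (expected 'user = schema'): {line!r}")
        user, schema = (p.strip() for p in line.split("=", 1))
        if schema not in COLUMNS:
            raise SchemaError(f"unknown schema column {schema!r} in mapping file")
        mapping[user] = schema
    return mapping


def read_cohort(
    path: str | Path,
    schema_config: Mapping[str, str] | str | Path | None = None,
    *,
    label: str | None = None,
    sep: str = ",",
    na_values: Sequence[str] = ("", "NA"),
    on_invalid: str = "error",
) -> Cohort:
    """Read a delimited cohort file into a validated :class:`Cohort`.

    Parameters
    ----------
    schema_config
        Optional mapping from the file's column names to schema names, either
        a dict or the path of a ``key = value`` file (see
        :func:`read_column_map`).
    on_invalid
        ``"error"`` (default) raises :class:`CohortValidationError` listing
        every bad row; ``"drop"`` rejects bad rows and records one diagnostic
        per row in ``Cohort.diagnostics``.
    """
    if on_invalid not in ("error", "drop"):
        raise ValueError("on_invalid must be 'error' or 'drop'")
    if isinstance(schema_config, (str, Path)):
        schema_config = read_column_map(schema_config)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=sep)
    if schema_config:
        df = df.rename(columns=dict(schema_config))
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    na = tuple(na_values)
    records: list[PatientRecord] = []
    diagnostics: list[str] = []
    known = [c for c in df.columns if c in COLUMNS]
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        values: dict[str, object] = {}
        problems: list[str] = []
        for name in known:
            try:
                values[name] = _parse_value(name, raw[name], na)
            except ValueError as exc:
                problems.append(str(exc))
        if not problems:
            if values.get("patient_id") is None or values.get("hs_ctnt_0h") is None \
                    or values.get("death") is None or values.get("followup_days") is None:
                problems.append("mandatory field missing (patient_id/hs_ctnt_0h/death/followup_days)")
        if not problems:
            rec = PatientRecord(**values)  # type: ignore[arg-type]
            problems = validate_record(rec)
        if problems:
            diagnostics.append(f"row {i}: " + "; ".join(problems))
        else:
            records.append(rec)

    if diagnostics and on_invalid == "error":
        raise CohortValidationError(diagnostics)
    cohort = Cohort(records, label=label or Path(path).stem, diagnostics=diagnostics)
    cohort.check_unique_ids()
    return cohort


def _format_value(name: str, value) -> str:
    if value is None:
        return ""
    if name in _BOOL_FIELDS:
        return "1" if value else "0"
    if name in _INT_FIELDS:
        return str(int(value))
    if name in _FLOAT_FIELDS:
        return repr(float(value))  # repr round-trips exactly in Python 3
    return str(value)


def _record_to_row(rec: PatientRecord) -> dict[str, str]:
    return {name: _format_value(name, getattr(rec, name)) for name in COLUMNS}


def write_cohort(cohort: Cohort, path: str | Path, *, sep: str = ",") -> None:
    """Write a cohort as delimited text; ``read_cohort`` round-trips it exactly."""
    problems: list[str] = []
    for i, rec in enumerate(cohort.records):
        for p in validate_record(rec):
            problems.append(f"record {i}: {p}")
    if problems:
        raise CohortValidationError(problems)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(COLUMNS), delimiter=sep)
        writer.writeheader()
        for rec in cohort.records:
            writer.writerow(_record_to_row(rec))
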