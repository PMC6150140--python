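"""Admission and prescription record containers and their file dialect.

Records travel as plain CSV (one row per admission, one column per
dictionary variable, an empty cell meaning *undocumented*) or as JSON
lines.  Column headers match the data-dictionary variable names exactly,
so a file can always be checked against its dictionary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .schema import BASELINE, REVISED2014, NARSchema, SchemaError, load_schema

#: structural (non-dictionary) admission columns, in file order
ADMISSION_FIELDS = (
    "record_id",
    "admission_date",
    "date_of_birth",
    "discharge_date",
    "outcome",
    "sex",
    "birth_weight_kg",
    "gestational_age_weeks",
    "admission_diagnoses",
    "schema_version",
    "full_dataset",
)

PRESCRIPTION_FIELDS = (
    "prescription_id",
    "record_id",
    "drug",
    "dose_mg",
    "frequency",
    "date",
    "weight_kg",
    "age_days",
)

SEPSIS_LABEL = "neonatal sepsis"


@dataclass
class AdmissionRecord:
    """One neonate's admission.

    ``values`` maps dictionary variable names to their documented raw value;
    a missing key (or blank value) means the variable was not documented.
    Structural fields (dates, outcome, weight) are the simulator's or
    abstractor's ground truth and may be populated even when the
    corresponding form field was left blank.
    """

    record_id: str
    admission_date: date
    date_of_birth: date
    schema_version: str = REVISED2014
    discharge_date: date | None = None
    outcome: str = "unknown"  # alive | dead | unknown
    sex: str | None = None
    birth_weight_kg: float | None = None
    gestational_age_weeks: float | None = None
    admission_diagnoses: list[str] = field(default_factory=list)
    full_dataset: bool = False
    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.schema_version not in (BASELINE, REVISED2014):
            raise SchemaError(f"unknown schema version: {self.schema_version!r}")
        if self.admission_date < self.date_of_birth:
            raise ValueError(
                f"record {self.record_id}: admission_date before date_of_birth"
            )
        if self.discharge_date is not None and self.discharge_date < self.admission_date:
            raise ValueError(
                f"record {self.record_id}: discharge_date before admission_date"
            )

    @property
    def has_sepsis_diagnosis(self) -> bool:
        return SEPSIS_LABEL in self.admission_diagnoses


@dataclass
class PrescriptionRecord:
    """One drug order, linked to its admission's weight and age."""

    prescription_id: str
    record_id: str
    drug: str
    dose_mg: float
    frequency: str = "once_daily"
    date: date | None = None
    weight_kg: float | None = None
    age_days: int | None = None


# ---- serialisation helpers -------------------------------------------------


def _fmt_date(value: date | None) -> str:
    return value.isoformat() if value is not None else ""


def _parse_date(raw) -> date | None:
    if raw is None or (isinstance(raw, str) and raw.strip() == "") or pd.isna(raw):
        return None
    if isinstance(raw, date) and not isinstance(raw, datetime):
        return raw
    return datetime.fromisoformat(str(raw)).date()


def _parse_float(raw) -> float | None:
    if raw is None or (isinstance(raw, str) and raw.strip() == "") or pd.isna(raw):
        return None
    return float(raw)


def admissions_to_frame(records: Iterable[AdmissionRecord], schema: NARSchema) -> pd.DataFrame:
    """Flatten records to the CSV dialect (empty cell = undocumented)."""
    var_names = schema.variable_names()
    rows = []
    for rec in records:
        row = {
            "record_id": rec.record_id,
            "admission_date": _fmt_date(rec.admission_date),
            "date_of_birth": _fmt_date(rec.date_of_birth),
            "discharge_date": _fmt_date(rec.discharge_date),
            "outcome": rec.outcome,
            "sex": rec.sex or "",
            "birth_weight_kg": rec.birth_weight_kg,
            "gestational_age_weeks": rec.gestational_age_weeks,
            "admission_diagnoses": ";".join(rec.admission_diagnoses),
            "schema_version": rec.schema_version,
            "full_dataset": int(rec.full_dataset),
        }
        for name in var_names:
            value = rec.values.get(name, "")
            row[f"nar_{name}"] = "" if value is None else value
        rows.append(row)
    columns = list(ADMISSION_FIELDS) + [f"nar_{n}" for n in var_names]
    return pd.DataFrame(rows, columns=columns)


def frame_to_admissions(
    frame: pd.DataFrame, schemas: Mapping[str, NARSchema] | None = None
) -> list[AdmissionRecord]:
    if schemas is None:
        schemas = {v: load_schema(v) for v in (BASELINE, REVISED2014)}
    records = []
    for row in frame.to_dict("records"):
        version = row.get("schema_version") or REVISED2014
        if version not in schemas:
            raise SchemaError(f"no dictionary supplied for schema version {version!r}")
        names = set(schemas[version].variable_names())
        values = {}
        for key, raw in row.items():
            if not key.startswith("nar_"):
                continue
            name = key[4:]
            if raw is None or pd.isna(raw) or str(raw).strip() == "":
                continue
            if name not in names:
                # column belongs to another schema version; a value here is
                # a structural inconsistency
                raise SchemaError(
                    f"record {row.get('record_id')}: value for {name!r} not in "
                    f"the {version} dictionary"
                )
            values[name] = raw
        diagnoses = str(row.get("admission_diagnoses") or "")
        records.append(
            AdmissionRecord(
                record_id=str(row["record_id"]),
                admission_date=_parse_date(row["admission_date"]),
                date_of_birth=_parse_date(row["date_of_birth"]),
                discharge_date=_parse_date(row.get("discharge_date")),
                outcome=str(row.get("outcome") or "unknown"),
                sex=str(row["sex"]) if row.get("sex") and not pd.isna(row["sex"]) else None,
                birth_weight_kg=_parse_float(row.get("birth_weight_kg")),
                gestational_age_weeks=_parse_float(row.get("gestational_age_weeks")),
                admission_diagnoses=[d for d in diagnoses.split(";") if d],
                schema_version=version,
                full_dataset=bool(int(row.get("full_dataset") or 0)),
                values=values,
            )
        )
    return records


def write_admissions_csv(records: Sequence[AdmissionRecord], path: str | Path,
                         schema: NARSchema | None = None) -> None:
    schema = schema or load_schema(REVISED2014)
    admissions_to_frame(records, schema).to_csv(path, index=False)


def read_admissions_csv(path: str | Path,
                        schemas: Mapping[str, NARSchema] | None = None) -> list[AdmissionRecord]:
    frame = pd.read_csv(path, dtype={"schema_version": str}, keep_default_na=True)
    return frame_to_admissions(frame, schemas)


def write_admissions_jsonl(records: Sequence[AdmissionRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            payload = dataclasses.asdict(rec)
            for key in ("admission_date", "date_of_birth", "discharge_date"):
                payload[key] = _fmt_date(payload[key])
            handle.write(json.dumps(payload) + "\n")


def read_admissions_jsonl(path: str | Path) -> list[AdmissionRecord]:
    records = []
    with open(path) as handle:
        for line in handle:
            payload = json.loads(line)
            for key in ("admission_date", "date_of_birth", "discharge_date"):
                payload[key] = _parse_date(payload[key])
            records.append(AdmissionRecord(**payload))
    return records


def prescriptions_to_frame(prescriptions: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    rows = []
    for rx in prescriptions:
        row = dataclasses.asdict(rx)
        row["date"] = _fmt_date(rx.date)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PRESCRIPTION_FIELDS))


def write_prescriptions_csv(prescriptions: Sequence[PrescriptionRecord], path: str | Path) -> None:
    prescriptions_to_frame(prescriptions).to_csv(path, index=False)


def read_prescriptions_csv(path: str | Path) -> list[PrescriptionRecord]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.to_dict("records"):
        age = row.get("age_days")
        out.append(
            PrescriptionRecord(
                prescription_id=str(row["prescription_id"]),
                record_id=str(row["record_id"]),
                drug=str(row["drug"]),
                dose_mg=float(row["dose_mg"]),
                frequency=str(row.get("frequency") or "once_daily"),
                date=_parse_date(row.get("date")),
                weight_kg=_parse_float(row.get("weight_kg")),
                age_days=None if age is None or pd.isna(age) else int(age),
            )
        )
    return out
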