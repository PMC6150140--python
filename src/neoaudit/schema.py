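"""Versioned data dictionary for the newborn admission record (NAR).

The NAR groups the variables recommended for documentation at admission
into six clinical domains (maternal history, demographics and diagnosis,
presenting complaints, cardinal signs on examination, other physical
examination, vital signs).  The form exists in two versions: a *baseline*
form and a *revised2014* form that added maternal-history items and a
number of examination and vital-sign variables.  This module provides the
default dictionary for both versions, a YAML/JSON dictionary format for
user-supplied variants, and record-level range/validity checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

BASELINE = "baseline"
REVISED2014 = "revised2014"
SCHEMA_VERSIONS = (BASELINE, REVISED2014)

#: the six analysis domains, in form order
DOMAIN_LABELS = (
    "maternal history",
    "demographics and diagnosis",
    "presenting complaints",
    "cardinal signs on examination",
    "other physical examination",
    "vital signs",
)

NUMERIC = "numeric"
CATEGORICAL = "categorical"
DATE = "date"
FREE_TEXT = "free_text"
VALUE_KINDS = (NUMERIC, CATEGORICAL, DATE, FREE_TEXT)

YES_NO = ("yes", "no")


class SchemaError(ValueError):
    """Raised for malformed dictionaries or unknown schema versions."""


@dataclass(frozen=True)
class VariableSpec:
    """One NAR variable: its domain, value kind and validity rule.

    ``valid_range`` is a ``(low, high)`` pair for numeric variables and a
    tuple of admissible category labels for categorical ones; date and
    free-text variables carry no range (dates are checked by cross-field
    ordering rules instead).
    """

    name: str
    domain: str
    value_kind: str
    valid_range: tuple | None = None
    introduced_in: str = BASELINE

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_LABELS:
            raise SchemaError(f"unknown domain label: {self.domain!r}")
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(f"unknown value kind: {self.value_kind!r}")
        if self.introduced_in not in SCHEMA_VERSIONS:
            raise SchemaError(f"unknown schema version tag: {self.introduced_in!r}")
        needs_range = self.value_kind in (NUMERIC, CATEGORICAL)
        if needs_range and self.valid_range is None:
            raise SchemaError(f"{self.name}: {self.value_kind} variable needs a valid_range")
        if not needs_range and self.valid_range is not None:
            raise SchemaError(f"{self.name}: {self.value_kind} variable must not carry a valid_range")
        if self.value_kind == NUMERIC:
            lo, hi = self.valid_range
            if not lo < hi:
                raise SchemaError(f"{self.name}: numeric bounds must be ordered")


# Default dictionary, revised2014 version.  Domain sizes 6/12/6/4/18/4 = 50.
# ``introduced_in=REVISED2014`` marks the variables added when the form was
# revised (the whole maternal-history section, seven examination signs and
# oxygen saturation); the baseline form is the dictionary minus those.
_V = VariableSpec
_DEFAULT_SPECS: tuple[VariableSpec, ...] = (
    # maternal history (added with the 2014 revision)
    _V("mothers_age", DOMAIN_LABELS[0], NUMERIC, (12.0, 55.0), REVISED2014),
    _V("parity", DOMAIN_LABELS[0], NUMERIC, (0.0, 20.0), REVISED2014),
    _V("gravidity", DOMAIN_LABELS[0], NUMERIC, (1.0, 25.0), REVISED2014),
    _V("mothers_blood_group", DOMAIN_LABELS[0], CATEGORICAL, ("A", "B", "AB", "O"), REVISED2014),
    _V("hiv_status", DOMAIN_LABELS[0], CATEGORICAL, ("positive", "negative", "unknown"), REVISED2014),
    _V("vdrl_status", DOMAIN_LABELS[0], CATEGORICAL, ("reactive", "non_reactive", "unknown"), REVISED2014),
    # demographics and diagnosis
    _V("date_of_birth", DOMAIN_LABELS[1], DATE),
    _V("admission_date", DOMAIN_LABELS[1], DATE),
    _V("gender", DOMAIN_LABELS[1], CATEGORICAL, ("male", "female")),
    _V("birth_weight", DOMAIN_LABELS[1], NUMERIC, (0.4, 6.0)),
    _V("age_in_days", DOMAIN_LABELS[1], NUMERIC, (0.0, 60.0)),
    _V("gestational_age", DOMAIN_LABELS[1], NUMERIC, (20.0, 45.0)),
    _V("mode_of_delivery", DOMAIN_LABELS[1], CATEGORICAL,
       ("svd", "caesarean_section", "breech", "assisted")),
    _V("apgar_score_5min", DOMAIN_LABELS[1], NUMERIC, (0.0, 10.0)),
    _V("admission_diagnosis", DOMAIN_LABELS[1], FREE_TEXT),
    _V("discharge_date", DOMAIN_LABELS[1], DATE),
    _V("outcome", DOMAIN_LABELS[1], CATEGORICAL, ("alive", "dead")),
    _V("discharge_diagnosis", DOMAIN_LABELS[1], FREE_TEXT),
    # presenting complaints
    _V("fever", DOMAIN_LABELS[2], CATEGORICAL, YES_NO),
    _V("convulsions", DOMAIN_LABELS[2], CATEGORICAL, YES_NO),
    _V("difficulty_breathing", DOMAIN_LABELS[2], CATEGORICAL, YES_NO),
    _V("vomiting", DOMAIN_LABELS[2], CATEGORICAL, YES_NO),
    _V("difficulty_feeding", DOMAIN_LABELS[2], CATEGORICAL, YES_NO),
    _V("apnoea", DOMAIN_LABELS[2], CATEGORICAL, YES_NO),
    # cardinal signs on examination
    _V("grunting", DOMAIN_LABELS[3], CATEGORICAL, YES_NO),
    _V("central_cyanosis", DOMAIN_LABELS[3], CATEGORICAL, YES_NO),
    _V("bulging_fontanelle", DOMAIN_LABELS[3], CATEGORICAL, YES_NO),
    _V("floppy", DOMAIN_LABELS[3], CATEGORICAL, YES_NO),
    # other physical examination
    _V("stridor", DOMAIN_LABELS[4], CATEGORICAL, YES_NO, REVISED2014),
    _V("bilateral_air_entry", DOMAIN_LABELS[4], CATEGORICAL, YES_NO, REVISED2014),
    _V("crackles", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("chest_indrawing", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("skin_pinch", DOMAIN_LABELS[4], CATEGORICAL, ("normal", "slow")),
    _V("femoral_pulses", DOMAIN_LABELS[4], CATEGORICAL, ("present", "weak", "absent"), REVISED2014),
    _V("capillary_refill_time", DOMAIN_LABELS[4], NUMERIC, (0.0, 15.0)),
    _V("heart_murmur", DOMAIN_LABELS[4], CATEGORICAL, YES_NO, REVISED2014),
    _V("pallor", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("skin_temperature_gradient", DOMAIN_LABELS[4], CATEGORICAL, YES_NO, REVISED2014),
    _V("eye_infection", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("umbilical_infection", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("skin_rashes_pustules", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("stiff_neck", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("irritability", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("jaundice", DOMAIN_LABELS[4], CATEGORICAL, YES_NO),
    _V("gestational_size", DOMAIN_LABELS[4], CATEGORICAL, ("sga", "aga", "lga"), REVISED2014),
    _V("severe_wasting", DOMAIN_LABELS[4], CATEGORICAL, YES_NO, REVISED2014),
    # vital signs
    _V("temperature", DOMAIN_LABELS[5], NUMERIC, (30.0, 42.0)),
    _V("respiratory_rate", DOMAIN_LABELS[5], NUMERIC, (10.0, 120.0)),
    _V("heart_rate", DOMAIN_LABELS[5], NUMERIC, (40.0, 250.0)),
    _V("oxygen_saturation", DOMAIN_LABELS[5], NUMERIC, (0.0, 100.0), REVISED2014),
)


@dataclass
class NARSchema:
    """A versioned NAR data dictionary: six ordered domains of variables."""

    version: str
    domains: dict[str, list[VariableSpec]]

    def __post_init__(self) -> None:
        if self.version not in SCHEMA_VERSIONS:
            raise SchemaError(f"unknown schema version: {self.version!r}")
        if tuple(self.domains) != DOMAIN_LABELS:
            raise SchemaError(
                f"schema must contain exactly the six domains {DOMAIN_LABELS}, "
                f"got {tuple(self.domains)}"
            )
        seen: set[str] = set()
        for label, specs in self.domains.items():
            for spec in specs:
                if spec.domain != label:
                    raise SchemaError(f"{spec.name}: listed under {label!r} but tagged {spec.domain!r}")
                if spec.name in seen:
                    raise SchemaError(f"duplicate variable name: {spec.name!r}")
                seen.add(spec.name)
        self._by_name = {s.name: s for s in self.variables()}

    def variables(self) -> Iterator[VariableSpec]:
        for specs in self.domains.values():
            yield from specs

    def variable(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def domain_sizes(self) -> dict[str, int]:
        return {label: len(specs) for label, specs in self.domains.items()}

    def variable_names(self) -> list[str]:
        return list(self._by_name)

    # ---- dictionary (de)serialisation -------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "variables": [
                {
                    "name": s.name,
                    "domain": s.domain,
                    "kind": s.value_kind,
                    "range": list(s.valid_range) if s.valid_range is not None else None,
                    "introduced_in": s.introduced_in,
                }
                for s in self.variables()
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "NARSchema":
        version = payload.get("version")
        specs = []
        for row in payload.get("variables", []):
            rng = row.get("range")
            kind = row["kind"]
            if rng is not None:
                rng = tuple(float(v) for v in rng) if kind == NUMERIC else tuple(rng)
            specs.append(
                VariableSpec(
                    name=row["name"],
                    domain=row["domain"],
                    value_kind=kind,
                    valid_range=rng,
                    introduced_in=row.get("introduced_in", BASELINE),
                )
            )
        return cls(version=version, domains=_group_by_domain(specs))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _group_by_domain(specs: Sequence[VariableSpec]) -> dict[str, list[VariableSpec]]:
    domains: dict[str, list[VariableSpec]] = {label: [] for label in DOMAIN_LABELS}
    for spec in specs:
        domains[spec.domain].append(spec)
    return domains


def load_schema(version: str, config: str | Path | Mapping | None = None) -> NARSchema:
    """Build the NAR dictionary for ``version`` (``baseline``/``revised2014``).

    Without ``config`` the shipped default dictionary is used: the
    revised2014 form with six domains of 6/12/6/4/18/4 variables (50 in
    total), of which 14 are tagged as added by the 2014 revision.  ``config``
    may be a YAML/JSON file path or an already-parsed mapping in the same
    shape; it always describes the full revised2014 dictionary, and the
    baseline version is obtained by dropping revised-only variables.
    """
    if version not in SCHEMA_VERSIONS:
        raise SchemaError(f"unknown schema version: {version!r}")
    if config is None:
        specs: Sequence[VariableSpec] = _DEFAULT_SPECS
    else:
        if isinstance(config, (str, Path)):
            text = Path(config).read_text()
            payload = json.loads(text) if str(config).endswith(".json") else yaml.safe_load(text)
        else:
            payload = dict(config)
        payload = dict(payload)
        payload.setdefault("version", REVISED2014)
        specs = list(NARSchema.from_dict(payload).variables())
    if version == BASELINE:
        specs = [s for s in specs if s.introduced_in == BASELINE]
    return NARSchema(version=version, domains=_group_by_domain(specs))


# ---- record validation -----------------------------------------------------


@dataclass(frozen=True)
class ValidationFinding:
    """One violated validity rule on one record."""

    record_id: str
    variable: str | None
    rule: str  # one of: range, category, type, date_order
    message: str


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, str) and value.strip() == "")


def validate_record(record, schema: NARSchema) -> list[ValidationFinding]:
    """Apply the dictionary's range/validity checks to one admission record.

    Returns one finding per violated rule; an empty list means the record is
    clean.  Missingness is *not* a finding — undocumented variables are
    scored by the completeness statistics, not flagged as invalid.  The
    record is never mutated.
    """
    if record.schema_version != schema.version:
        raise SchemaError(
            f"record {record.record_id}: schema version {record.schema_version!r} "
            f"does not match dictionary version {schema.version!r}"
        )
    unknown = set(record.values) - set(schema.variable_names())
    if unknown:
        raise SchemaError(
            f"record {record.record_id}: values for variables not in the "
            f"{schema.version} dictionary: {sorted(unknown)}"
        )

    findings: list[ValidationFinding] = []

    def add(variable, rule, message):
        findings.append(ValidationFinding(record.record_id, variable, rule, message))

    for name, raw in record.values.items():
        if _is_blank(raw):
            continue
        spec = schema.variable(name)
        if spec.value_kind == NUMERIC:
            try:
                value = float(raw)
            except (TypeError, ValueError):
                add(name, "type", f"{name}: not a number: {raw!r}")
                continue
            lo, hi = spec.valid_range
            if not lo <= value <= hi:
                add(name, "range", f"{name}: {value} outside [{lo}, {hi}]")
        elif spec.value_kind == CATEGORICAL:
            if str(raw).strip() not in spec.valid_range:
                add(name, "category", f"{name}: {raw!r} not in {spec.valid_range}")

    if record.admission_date is not None and record.date_of_birth is not None:
        if record.admission_date < record.date_of_birth:
            add(None, "date_order", "admission_date before date_of_birth")
    if record.discharge_date is not None and record.admission_date is not None:
        if record.discharge_date < record.admission_date:
            add(None, "date_order", "discharge_date before admission_date")
    return findings
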