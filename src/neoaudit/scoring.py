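"""Documentation-completeness scoring.

Each dictionary variable on each record gets a binary availability score
(1 = a non-blank value was documented, 0 = not).  Scores are pooled into
domain × period completeness proportions (documented slots over
documentable slots), per-patient completeness fractions, and a
variable-level stratification that labels items *very poorly* (<25%),
*poorly* (25–50%) or adequately (>50%) documented.

A slot only counts when the variable exists in the record's form version:
a baseline-form record is not penalised for variables that were only
added by the 2014 revision.  Those slots are NOT_APPLICABLE and excluded
from numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import AdmissionRecord
from .schema import BASELINE, REVISED2014, NARSchema, SchemaError, VariableSpec
from .trend import (EmptyDenominatorError, PeriodBin, ProportionEstimate,
                    WILSON, proportion_estimate)


class _NotApplicable:
    """Slot sentinel: variable absent from the record's schema version."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_APPLICABLE"


NOT_APPLICABLE = _NotApplicable()

VERY_POOR = "very_poor"
POOR = "poor"
ADEQUATE = "adequate"

#: stratification thresholds on the documented fraction; both boundaries
#: belong to the poor stratum
VERY_POOR_BELOW = 0.25
POOR_UP_TO = 0.50


@dataclass(frozen=True)
class CompletenessResult:
    """Pooled documentation completeness for one domain in one period."""

    domain: str
    period: PeriodBin | None
    documented_count: int
    possible_count: int
    estimate: ProportionEstimate


@dataclass(frozen=True)
class VariableStratum:
    """A variable's documented fraction and its documentation stratum."""

    variable: str
    domain: str
    documented_fraction: float
    applicable_records: int
    stratum: str


def _applicable(record: AdmissionRecord, spec: VariableSpec) -> bool:
    if record.schema_version == REVISED2014:
        return True
    return spec.introduced_in == BASELINE


def doc_indicator(record: AdmissionRecord, variable: VariableSpec):
    """Binary availability score for one variable on one record.

    Returns 1 when the record documents a non-blank value, 0 when the slot
    is blank or missing, and :data:`NOT_APPLICABLE` when the variable is
    not part of the record's form version.
    """
    if not _applicable(record, variable):
        return NOT_APPLICABLE
    value = record.values.get(variable.name)
    if value is None:
        return 0
    if isinstance(value, str) and value.strip() == "":
        return 0
    return 1


def domain_completeness(
    records: Iterable[AdmissionRecord],
    domain: str,
    schema: NARSchema,
    period: PeriodBin | None = None,
    conf_level: float = 0.95,
    ci_method: str = WILSON,
) -> CompletenessResult:
    """Pooled completeness x/n for one domain over a set of records.

    ``x`` counts documented slots and ``n`` documentable slots across all
    records and the domain's variables; callers bin records into periods
    first.  Raises :class:`EmptyDenominatorError` when no slot is
    applicable (e.g. the maternal-history domain on a purely baseline-form
    cohort).
    """
    if domain not in schema.domains:
        raise SchemaError(f"unknown domain label: {domain!r}")
    specs = schema.domains[domain]
    x = n = 0
    for record in records:
        for spec in specs:
            score = doc_indicator(record, spec)
            if score is NOT_APPLICABLE:
                continue
            n += 1
            x += score
    if n == 0:
        raise EmptyDenominatorError(
            f"no documentable slots for domain {domain!r} in this record set"
        )
    estimate = proportion_estimate(x, n, conf_level=conf_level, method=ci_method)
    return CompletenessResult(domain=domain, period=period,
                              documented_count=x, possible_count=n, estimate=estimate)


def patient_completeness(record: AdmissionRecord, schema: NARSchema) -> float:
    """Fraction of the record's applicable variables that are documented."""
    x = n = 0
    for spec in schema.variables():
        score = doc_indicator(record, spec)
        if score is NOT_APPLICABLE:
            continue
        n += 1
        x += score
    if n == 0:
        raise EmptyDenominatorError(
            f"record {record.record_id}: no applicable variables"
        )
    return x / n


def classify_fraction(fraction: float) -> str:
    """Stratum label for a documented fraction (boundaries belong to poor)."""
    if fraction < VERY_POOR_BELOW:
        return VERY_POOR
    if fraction <= POOR_UP_TO:
        return POOR
    return ADEQUATE


def stratify_variable(
    records: Iterable[AdmissionRecord],
    variable: VariableSpec | str,
    schema: NARSchema,
) -> VariableStratum:
    """Documented fraction and stratum of one variable across records."""
    spec = schema.variable(variable) if isinstance(variable, str) else variable
    x = n = 0
    for record in records:
        score = doc_indicator(record, spec)
        if score is NOT_APPLICABLE:
            continue
        n += 1
        x += score
    if n == 0:
        raise EmptyDenominatorError(f"variable {spec.name!r}: no applicable records")
    fraction = x / n
    return VariableStratum(variable=spec.name, domain=spec.domain,
                           documented_fraction=fraction, applicable_records=n,
                           stratum=classify_fraction(fraction))


def stratify_all(records: Sequence[AdmissionRecord], schema: NARSchema) -> list[VariableStratum]:
    """Stratify every dictionary variable with at least one applicable record."""
    out = []
    for spec in schema.variables():
        try:
            out.append(stratify_variable(records, spec, schema))
        except EmptyDenominatorError:
            continue
    return out


def completeness_table(
    records: Sequence[AdmissionRecord],
    schema: NARSchema,
    periods: Sequence[PeriodBin],
    conf_level: float = 0.95,
    ci_method: str = WILSON,
) -> list[CompletenessResult]:
    """Domain × period completeness over a cohort, binned by admission date.

    Domain/period cells with no documentable slots (no records in the
    period, or a domain empty under every represented form version) are
    omitted rather than reported as 0/0.
    """
    results = []
    for period in periods:
        in_period = [r for r in records if r.admission_date in period]
        if not in_period:
            continue
        for domain in schema.domains:
            try:
                results.append(
                    domain_completeness(in_period, domain, schema, period=period,
                                        conf_level=conf_level, ci_method=ci_method)
                )
            except EmptyDenominatorError:
                continue
    return results
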