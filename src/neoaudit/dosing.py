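"""Weight-banded gentamicin dosing-correctness audit.

Kenyan national guidance for neonates in the first week of life is once
daily gentamicin at 3 mg/kg below 2 kg and 5 mg/kg at or above 2 kg.  A
prescription is *correct* when the prescribed amount is within a relative
margin (default ±20%) of the guideline dose for the baby's weight band;
above the margin it is an *overdose*, below it an *underdose*.
Prescriptions that cannot be judged against the rule — missing weight,
non-positive weight, or an age outside the rule's window — are
*unassessable* and excluded from accuracy denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .records import AdmissionRecord, PrescriptionRecord
from .trend import PeriodBin, ProportionEstimate, WILSON, proportion_estimate

CORRECT = "correct"
OVERDOSE = "overdose"
UNDERDOSE = "underdose"
UNASSESSABLE = "unassessable"

UNDER_2KG = "under_2kg"
AT_LEAST_2KG = "at_least_2kg"
WEIGHT_BANDS = (UNDER_2KG, AT_LEAST_2KG)

#: relative slack on the margin boundaries so that a ratio of exactly
#: (1 ± m) is classified correct despite floating-point noise
_BOUNDARY_RTOL = 1e-9


@dataclass(frozen=True)
class Unassessable:
    """Why a prescription could not be judged against the rule."""

    reason: str  # missing_weight | non_positive_weight | age_outside_window | missing_age

    def __bool__(self) -> bool:  # pragma: no cover
        return False


@dataclass(frozen=True)
class DoseRule:
    """A weight-banded mg/kg dosing rule with a correctness margin.

    ``bands`` is an ordered list of ``(weight_upper_bound_kg, dose_per_kg)``
    pairs; a weight belongs to the first band whose (exclusive) upper bound
    exceeds it, so the default gentamicin bands ``[(2.0, 3.0), (inf, 5.0)]``
    give 3 mg/kg strictly below 2 kg and 5 mg/kg from 2 kg up.
    ``age_window_days`` is the inclusive age span (days of life) the rule
    applies to; ``margin`` is the relative tolerance m defining correct
    doses as [(1−m)·expected, (1+m)·expected].
    """

    drug: str = "gentamicin"
    bands: tuple[tuple[float, float], ...] = ((2.0, 3.0), (math.inf, 5.0))
    frequency: str = "once_daily"
    age_window_days: tuple[int, int] = (0, 7)
    margin: float = 0.20

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("rule needs at least one weight band")
        uppers = [b[0] for b in self.bands]
        if uppers != sorted(uppers) or len(set(uppers)) != len(uppers):
            raise ValueError("band upper bounds must be strictly increasing")
        if not math.isinf(uppers[-1]):
            raise ValueError("last band must cover all weights (upper bound inf)")
        if any(d <= 0 for _, d in self.bands):
            raise ValueError("dose_per_kg must be positive")
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")
        if self.age_window_days[0] > self.age_window_days[1]:
            raise ValueError("age window must be ordered")

    def dose_per_kg(self, weight_kg: float) -> float:
        for upper, per_kg in self.bands:
            if weight_kg < upper:
                return per_kg
        raise AssertionError("bands cover all positive weights")  # pragma: no cover


DEFAULT_GENTAMICIN_RULE = DoseRule()


@dataclass(frozen=True)
class DoseAssessment:
    """Classification of one prescription against a dosing rule."""

    prescription_id: str
    classification: str  # correct | overdose | underdose | unassessable
    expected_dose_mg: float | None = None
    prescribed_mg: float | None = None
    ratio: float | None = None
    reason: str | None = None  # set iff unassessable
    record_id: str | None = None
    weight_band: str | None = None


def expected_dose(weight_kg: float | None, age_days: int | None,
                  rule: DoseRule = DEFAULT_GENTAMICIN_RULE) -> float | Unassessable:
    """Guideline dose in mg for a weight and age, or why none applies.

    Missing or non-positive weights and ages outside the rule's window are
    reported as :class:`Unassessable` rather than raised, so a cohort audit
    can tally them.
    """
    if age_days is None:
        return Unassessable("missing_age")
    lo, hi = rule.age_window_days
    if not lo <= age_days <= hi:
        return Unassessable("age_outside_window")
    if weight_kg is None:
        return Unassessable("missing_weight")
    if weight_kg <= 0:
        return Unassessable("non_positive_weight")
    return rule.dose_per_kg(weight_kg) * weight_kg


def weight_band(weight_kg: float) -> str:
    return UNDER_2KG if weight_kg < 2.0 else AT_LEAST_2KG


def classify_dose(prescribed_mg: float, weight_kg: float | None, age_days: int | None,
                  rule: DoseRule = DEFAULT_GENTAMICIN_RULE,
                  prescription_id: str = "", record_id: str | None = None) -> DoseAssessment:
    """Classify a prescribed amount as correct/overdose/underdose.

    The ratio prescribed/expected is kept at full precision; the margin
    boundaries are inclusive for *correct* (a ratio of exactly 1 + m is
    still correct).
    """
    if prescribed_mg is None or prescribed_mg <= 0:
        return DoseAssessment(prescription_id, UNASSESSABLE, reason="non_positive_dose",
                              record_id=record_id)
    expected = expected_dose(weight_kg, age_days, rule)
    if isinstance(expected, Unassessable):
        return DoseAssessment(prescription_id, UNASSESSABLE, prescribed_mg=prescribed_mg,
                              reason=expected.reason, record_id=record_id)
    ratio = prescribed_mg / expected
    hi = (1 + rule.margin) * (1 + _BOUNDARY_RTOL)
    lo = (1 - rule.margin) * (1 - _BOUNDARY_RTOL)
    if ratio > hi:
        label = OVERDOSE
    elif ratio < lo:
        label = UNDERDOSE
    else:
        label = CORRECT
    return DoseAssessment(prescription_id, label, expected_dose_mg=expected,
                          prescribed_mg=prescribed_mg, ratio=ratio, record_id=record_id,
                          weight_band=weight_band(weight_kg))


def assess_prescription(rx: PrescriptionRecord,
                        rule: DoseRule = DEFAULT_GENTAMICIN_RULE) -> DoseAssessment:
    """Classify one prescription record against the rule for its drug."""
    return classify_dose(rx.dose_mg, rx.weight_kg, rx.age_days, rule,
                         prescription_id=rx.prescription_id, record_id=rx.record_id)


def assess_cohort(prescriptions: Iterable[PrescriptionRecord],
                  rule: DoseRule = DEFAULT_GENTAMICIN_RULE,
                  drug: str | None = None) -> list[DoseAssessment]:
    """Classify every prescription (optionally only ``drug``) in a cohort."""
    drug = drug or rule.drug
    return [assess_prescription(rx, rule) for rx in prescriptions
            if rx.drug.lower() == drug.lower()]


@dataclass(frozen=True)
class AccuracyPoint:
    """Dosing accuracy (correct among assessable) in one period."""

    period: PeriodBin
    weight_band: str
    correct: int
    assessable: int
    estimate: ProportionEstimate | None  # None when assessable == 0


def dose_accuracy_series(
    assessments: Sequence[DoseAssessment],
    records: Sequence[AdmissionRecord],
    band: str,
    periods: Sequence[PeriodBin],
    conf_level: float = 0.95,
    ci_method: str = WILSON,
) -> list[AccuracyPoint]:
    """Per-period fraction of correct doses within one weight band.

    Prescriptions are binned by their admission's date; unassessable ones
    are excluded from both numerator and denominator.  Periods with no
    assessable prescriptions are reported with n = 0 and no estimate.
    """
    if band not in WEIGHT_BANDS:
        raise ValueError(f"unknown weight band {band!r}")
    by_record = {r.record_id: r for r in records}
    points = []
    for period in periods:
        correct = assessable = 0
        for a in assessments:
            if a.classification == UNASSESSABLE or a.weight_band != band:
                continue
            record = by_record.get(a.record_id)
            if record is None or record.admission_date not in period:
                continue
            assessable += 1
            correct += a.classification == CORRECT
        estimate = (proportion_estimate(correct, assessable, conf_level, ci_method)
                    if assessable else None)
        points.append(AccuracyPoint(period=period, weight_band=band,
                                    correct=correct, assessable=assessable,
                                    estimate=estimate))
    return points


# ---- rule registry ---------------------------------------------------------


def load_rules(path: str | Path | Mapping | None = None) -> dict[str, DoseRule]:
    """Load a drug → rule registry from YAML (gentamicin shipped by default).

    The YAML maps drug names to ``{bands: [[upper_kg, mg_per_kg], ...],
    frequency, age_window_days: [lo, hi], margin}``; ``upper_kg: null`` (or
    ``.inf``) marks the open-ended top band.
    """
    if path is None:
        return {"gentamicin": DEFAULT_GENTAMICIN_RULE}
    payload = path if isinstance(path, Mapping) else yaml.safe_load(Path(path).read_text())
    rules = {}
    for drug, spec in payload.items():
        bands = tuple(
            (math.inf if upper is None else float(upper), float(per_kg))
            for upper, per_kg in spec["bands"]
        )
        rules[drug] = DoseRule(
            drug=drug,
            bands=bands,
            frequency=spec.get("frequency", "once_daily"),
            age_window_days=tuple(spec.get("age_window_days", (0, 7))),
            margin=float(spec.get("margin", 0.20)),
        )
    return rules
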