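"""Seeded synthetic neonatal admission cohort generator.

The hospital data behind the audit are not publicly deposited, so the
pipeline ships a generator that emulates their statistical structure: a
stream of admissions over a multi-year window, a form-revision date that
switches records from the baseline to the revised dictionary,
per-variable documentation probabilities that may ramp over calendar
time (audit-and-feedback cycles improve documentation), sepsis
prevalence and in-hospital mortality near the unit's reported marginals,
birth weights from a truncated normal centred at 2.88 kg, a random 60%
subsample flagged for full-data abstraction, and gentamicin
prescriptions whose doses are guideline doses perturbed by configurable
over-/under-dose error rates.

Documentation draws are independent across variables and records — the
simplest structure sufficient to exercise the scoring pipeline.  All
randomness flows from a single integer seed: identical parameters and
seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .records import (AdmissionRecord, PrescriptionRecord, SEPSIS_LABEL,
                      write_admissions_csv, write_prescriptions_csv)
from .schema import (BASELINE, CATEGORICAL, DATE, FREE_TEXT, NARSchema, NUMERIC,
                     REVISED2014, load_schema)
from .dosing import DEFAULT_GENTAMICIN_RULE, DoseRule

#: documentation probability spec: a constant, or a (start, end) linear ramp
#: over the study window
DocProb = float | tuple[float, float]

_NON_SEPSIS_DIAGNOSES = ("prematurity", "birth asphyxia", "respiratory distress", "jaundice")


@dataclass
class DoseErrorParams:
    """Rates and magnitudes of simulated dosing errors.

    Erroneous doses are multiplicative perturbations of the guideline
    dose: an overdose multiplies it by at least ``(1 + margin) * (1 +
    clearance)`` times a log-normal magnitude, an underdose divides by the
    same, so simulated errors always fall outside the correctness margin;
    correct doses sit uniformly well inside it.
    """

    overdose_rate: float = 0.044
    underdose_rate: float = 0.024
    magnitude_sigma: float = 0.25
    clearance: float = 0.02

    def validate(self) -> None:
        if not 0 <= self.overdose_rate <= 1 or not 0 <= self.underdose_rate <= 1:
            raise ValueError("error rates must be probabilities")
        if self.overdose_rate + self.underdose_rate > 1:
            raise ValueError("overdose_rate + underdose_rate must not exceed 1")


@dataclass
class CohortParams:
    """Everything the cohort generator needs, with study-scale defaults.

    Defaults describe a busy urban newborn unit observed from January 2013
    to November 2016 with the form revised on 1 April 2014: sepsis
    prevalence 16.7%, mortality 9%, birth weight ~N(2.88, 0.6²) kg
    truncated to [0.5, 5.5], 60% of admissions flagged for full-data
    abstraction, 81.4% of sepsis babies (and 47% of the rest) receiving
    gentamicin.  ``doc_prob`` maps variable names to a constant
    probability or a ``(start, end)`` linear ramp across the window;
    ``default_doc_prob`` covers unmapped variables and defaults to a
    0.55 → 0.80 ramp, with birth weight nearly always documented and
    gestational age ramping 0.10 → 0.80 as feedback takes hold.
    """

    start_date: date = date(2013, 1, 1)
    end_date: date = date(2016, 11, 30)
    revision_date: date = date(2014, 4, 1)
    admissions_per_month: float = 200.0
    sepsis_prevalence: float = 0.167
    mortality: float = 0.09
    weight_mean_kg: float = 2.88
    weight_sd_kg: float = 0.6
    weight_bounds_kg: tuple[float, float] = (0.5, 5.5)
    full_dataset_fraction: float = 0.6
    default_doc_prob: DocProb = (0.55, 0.80)
    doc_prob: dict[str, DocProb] = field(default_factory=lambda: {
        "birth_weight": 0.97,
        "gestational_age": (0.10, 0.80),
        "temperature": 0.40,
        "severe_wasting": 0.15,
        "skin_pinch": 0.18,
        "skin_temperature_gradient": 0.15,
        "femoral_pulses": 0.20,
        "eye_infection": 0.22,
    })
    sepsis_gentamicin_rate: float = 0.814
    nonsepsis_gentamicin_rate: float = 0.47
    late_prescription_rate: float = 0.05
    missing_weight_rate: float = 0.02
    dose_error: DoseErrorParams = field(default_factory=DoseErrorParams)
    seed: int = 0

    def validate(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("empty date span: end_date must be after start_date")
        for name in ("sepsis_prevalence", "mortality", "full_dataset_fraction",
                     "sepsis_gentamicin_rate", "nonsepsis_gentamicin_rate",
                     "late_prescription_rate", "missing_weight_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.weight_bounds_kg
        if not 0 < lo < hi:
            raise ValueError("weight truncation bounds must be positive and ordered")
        if self.weight_sd_kg <= 0 or self.admissions_per_month <= 0:
            raise ValueError("weight_sd_kg and admissions_per_month must be positive")
        for name, spec in {"default": self.default_doc_prob, **self.doc_prob}.items():
            for p in ((spec,) if isinstance(spec, (int, float)) else tuple(spec)):
                if not 0 <= p <= 1:
                    raise ValueError(f"doc_prob[{name}] out of [0, 1]: {spec}")
        self.dose_error.validate()

    # ---- config file round trip -------------------------------------------

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        for key in ("start_date", "end_date", "revision_date"):
            payload[key] = payload[key].isoformat()
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CohortParams":
        payload = dict(payload)
        for key in ("start_date", "end_date", "revision_date"):
            if key in payload and isinstance(payload[key], str):
                payload[key] = date.fromisoformat(payload[key])
        if "dose_error" in payload and isinstance(payload["dose_error"], Mapping):
            payload["dose_error"] = DoseErrorParams(**payload["dose_error"])
        if "doc_prob" in payload:
            payload["doc_prob"] = {
                k: (tuple(v) if isinstance(v, (list, tuple)) else float(v))
                for k, v in payload["doc_prob"].items()
            }
        if "default_doc_prob" in payload and isinstance(payload["default_doc_prob"], (list, tuple)):
            payload["default_doc_prob"] = tuple(payload["default_doc_prob"])
        if "weight_bounds_kg" in payload:
            payload["weight_bounds_kg"] = tuple(payload["weight_bounds_kg"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def doc_probability(self, variable: str, when: date) -> float:
        """Documentation probability of ``variable`` on calendar day ``when``."""
        spec = self.doc_prob.get(variable, self.default_doc_prob)
        if isinstance(spec, (int, float)):
            return float(spec)
        p0, p1 = spec
        span = (self.end_date - self.start_date).days
        frac = min(max((when - self.start_date).days / span, 0.0), 1.0)
        return p0 + (p1 - p0) * frac


# age at admission: most babies arrive on their date of birth, nearly all
# within 48 hours
_AGE_DAYS = np.arange(11)
_AGE_PROBS = np.array([0.783, 0.07, 0.052] + [0.095 / 8] * 8)
_AGE_PROBS = _AGE_PROBS / _AGE_PROBS.sum()


def _months(start: date, end: date) -> list[date]:
    out, current = [], date(start.year, start.month, 1)
    while current <= end:
        out.append(current)
        current = (date(current.year + 1, 1, 1) if current.month == 12
                   else date(current.year, current.month + 1, 1))
    return out


def _simulate_value(spec, record_truth: dict, rng: np.random.Generator):
    """A plausible documented value for one variable, consistent with the
    record's ground truth where the variable mirrors a structural field."""
    if spec.name in record_truth:
        return record_truth[spec.name]
    if spec.value_kind == NUMERIC:
        lo, hi = spec.valid_range
        return round(float(rng.uniform(lo, hi)), 1)
    if spec.value_kind == CATEGORICAL:
        return str(rng.choice(spec.valid_range))
    if spec.value_kind == DATE:
        return record_truth.get("admission_date", "")
    return "documented"  # free-text presence


def simulate_cohort(
    params: CohortParams | None = None,
    schema: NARSchema | None = None,
    rule: DoseRule = DEFAULT_GENTAMICIN_RULE,
) -> tuple[list[AdmissionRecord], list[PrescriptionRecord]]:
    """Draw a synthetic admission + prescription cohort.

    ``schema`` is the revised2014 dictionary; records admitted before the
    revision date carry the baseline version (starred variables never
    documented for them).  Returns records sorted by admission date.
    """
    params = params or CohortParams()
    params.validate()
    schema = schema or load_schema(REVISED2014)
    rng = np.random.default_rng(params.seed)

    specs_by_version = {
        REVISED2014: list(schema.variables()),
        BASELINE: [s for s in schema.variables() if s.introduced_in == BASELINE],
    }

    records: list[AdmissionRecord] = []
    prescriptions: list[PrescriptionRecord] = []
    admissions: list[tuple[date, int]] = []
    for month_start in _months(params.start_date, params.end_date):
        n = rng.poisson(params.admissions_per_month)
        month_end = min(
            (date(month_start.year + (month_start.month == 12), month_start.month % 12 + 1, 1)
             - timedelta(days=1)),
            params.end_date,
        )
        month_start = max(month_start, params.start_date)
        span = (month_end - month_start).days + 1
        offsets = rng.integers(0, span, size=n)
        for off in offsets:
            admissions.append((month_start + timedelta(days=int(off)), 0))
    admissions.sort(key=lambda t: t[0])

    a, b = params.weight_bounds_kg
    z0 = (a - params.weight_mean_kg) / params.weight_sd_kg
    z1 = (b - params.weight_mean_kg) / params.weight_sd_kg
    weights = stats.truncnorm.rvs(z0, z1, loc=params.weight_mean_kg,
                                  scale=params.weight_sd_kg,
                                  size=len(admissions), random_state=rng)

    for i, (adm_date, _) in enumerate(admissions):
        record_id = f"R{i:06d}"
        weight = round(float(weights[i]), 3)
        age_at_admission = int(rng.choice(_AGE_DAYS, p=_AGE_PROBS))
        dob = adm_date - timedelta(days=age_at_admission)
        sepsis = rng.random() < params.sepsis_prevalence
        dead = rng.random() < params.mortality
        los = 1 + int(rng.poisson(4))
        discharge = adm_date + timedelta(days=los)
        sex = "female" if rng.random() < 0.46 else "male"
        ga_weeks = round(float(np.clip(rng.normal(38.0, 2.5), 26.0, 43.0)), 1)
        version = BASELINE if adm_date < params.revision_date else REVISED2014
        if sepsis:
            diagnoses = [SEPSIS_LABEL]
        else:
            diagnoses = [str(rng.choice(_NON_SEPSIS_DIAGNOSES))]
        outcome = "dead" if dead else "alive"

        truth = {
            "date_of_birth": dob.isoformat(),
            "admission_date": adm_date.isoformat(),
            "discharge_date": discharge.isoformat(),
            "gender": sex,
            "birth_weight": weight,
            "age_in_days": age_at_admission,
            "gestational_age": ga_weeks,
            "outcome": outcome,
            "admission_diagnosis": "; ".join(diagnoses),
            "discharge_diagnosis": "; ".join(diagnoses),
        }
        specs = specs_by_version[version]
        documented = rng.random(len(specs))
        values = {}
        for spec, u in zip(specs, documented):
            if u < params.doc_probability(spec.name, adm_date):
                values[spec.name] = _simulate_value(spec, truth, rng)

        records.append(AdmissionRecord(
            record_id=record_id,
            admission_date=adm_date,
            date_of_birth=dob,
            discharge_date=discharge,
            outcome=outcome,
            sex=sex,
            birth_weight_kg=weight,
            gestational_age_weeks=ga_weeks,
            admission_diagnoses=diagnoses,
            schema_version=version,
            full_dataset=bool(rng.random() < params.full_dataset_fraction),
            values=values,
        ))

        gent_rate = (params.sepsis_gentamicin_rate if sepsis
                     else params.nonsepsis_gentamicin_rate)
        if rng.random() < gent_rate:
            prescriptions.append(_simulate_prescription(
                rng, params, rule, record_id, weight, age_at_admission, dob,
                index=len(prescriptions)))
    return records, prescriptions


def _simulate_prescription(rng, params: CohortParams, rule: DoseRule,
                           record_id: str, weight: float, age_at_admission: int,
                           dob: date, index: int) -> PrescriptionRecord:
    if rng.random() < params.late_prescription_rate:
        age_days = int(rng.integers(8, 15))
    else:
        age_days = min(age_at_admission + int(rng.integers(0, 2)),
                       rule.age_window_days[1])
    guideline = rule.dose_per_kg(weight) * weight
    err = params.dose_error
    u = rng.random()
    floor = (1 + rule.margin) * (1 + err.clearance)
    if u < err.overdose_rate:
        factor = floor * float(np.exp(abs(rng.normal(0.0, err.magnitude_sigma))))
    elif u < err.overdose_rate + err.underdose_rate:
        factor = 1.0 / (floor * float(np.exp(abs(rng.normal(0.0, err.magnitude_sigma)))))
    else:
        factor = 1.0 + float(rng.uniform(-0.5, 0.5)) * rule.margin
    weight_recorded = None if rng.random() < params.missing_weight_rate else weight
    return PrescriptionRecord(
        prescription_id=f"P{index:06d}",
        record_id=record_id,
        drug=rule.drug,
        dose_mg=round(guideline * factor, 3),
        frequency=rule.frequency,
        date=dob + timedelta(days=age_days),
        weight_kg=weight_recorded,
        age_days=age_days,
    )


def write_cohort(records: Sequence[AdmissionRecord],
                 prescriptions: Sequence[PrescriptionRecord],
                 out_dir: str | Path,
                 schema: NARSchema | None = None) -> dict[str, Path]:
    """Write admissions.csv + prescriptions.csv in the standard dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = schema or load_schema(REVISED2014)
    paths = {
        "admissions": out_dir / "admissions.csv",
        "prescriptions": out_dir / "prescriptions.csv",
    }
    write_admissions_csv(records, paths["admissions"], schema)
    write_prescriptions_csv(prescriptions, paths["prescriptions"])
    return paths
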