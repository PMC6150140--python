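"""Gentamicin dose rule, classification and accuracy series."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoaudit import (DEFAULT_GENTAMICIN_RULE, DoseRule, PrescriptionRecord,
                      Unassessable, assess_cohort, classify_dose,
                      dose_accuracy_series, expected_dose)
from neoaudit.dosing import weight_band
from neoaudit.trend import make_periods


class TestExpectedDose:
    def test_lower_band_is_3_mg_per_kg(self):
        assert expected_dose(1.5, 3) == pytest.approx(4.5)

    def test_band_boundary_2kg_uses_upper_band(self):
        """Exactly 2 kg belongs to the ≥2 kg band: 5 mg/kg."""
        assert expected_dose(2.0, 3) == pytest.approx(10.0)
        assert expected_dose(1.999, 3) == pytest.approx(1.999 * 3)

    def test_age_outside_first_week_is_unassessable(self):
        result = expected_dose(2.5, 10)
        assert isinstance(result, Unassessable)
        assert result.reason == "age_outside_window"

    @pytest.mark.parametrize("weight,reason", [
        (None, "missing_weight"), (0.0, "non_positive_weight"), (-1.0, "non_positive_weight"),
    ])
    def test_bad_weight_flagged_not_raised(self, weight, reason):
        result = expected_dose(weight, 3)
        assert isinstance(result, Unassessable) and result.reason == reason

    def test_age_window_is_inclusive_days_0_to_7(self):
        assert expected_dose(3.0, 0) == pytest.approx(15.0)
        assert expected_dose(3.0, 7) == pytest.approx(15.0)
        assert isinstance(expected_dose(3.0, 8), Unassessable)


class TestClassifyDose:
    def test_exact_guideline_dose_is_correct(self):
        a = classify_dose(4.5, 1.5, 3)
        assert a.classification == "correct"
        assert a.ratio == pytest.approx(1.0)

    def test_overdose_beyond_margin(self):
        a = classify_dose(6.0, 1.5, 3)
        assert a.classification == "overdose"
        assert a.ratio == pytest.approx(6.0 / 4.5)

    def test_underdose_below_margin(self):
        a = classify_dose(7.9, 2.0, 3)
        assert a.classification == "underdose"
        assert a.ratio == pytest.approx(0.79)

    def test_margin_boundaries_inclusive_for_correct(self):
        assert classify_dose(4.5 * 1.2, 1.5, 3).classification == "correct"
        assert classify_dose(4.5 * 0.8, 1.5, 3).classification == "correct"
        assert classify_dose(4.5 * 1.201, 1.5, 3).classification == "overdose"
        assert classify_dose(4.5 * 0.799, 1.5, 3).classification == "underdose"

    def test_unassessable_propagates_reason(self):
        a = classify_dose(10.0, None, 3)
        assert (a.classification, a.reason) == ("unassessable", "missing_weight")
        a = classify_dose(10.0, 2.5, 12)
        assert (a.classification, a.reason) == ("unassessable", "age_outside_window")

    @given(weight=st.floats(0.5, 5.5), age=st.integers(0, 7),
           factor=st.floats(0.3, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_scale_equivariance(self, weight, age, factor):
        """Multiplying prescribed and expected dose by a common factor
        (e.g. expressing both per kg) leaves classification unchanged."""
        expected = expected_dose(weight, age)
        base = classify_dose(expected * factor, weight, age)
        scaled_rule = DoseRule(bands=tuple((b, d * 2) for b, d in
                                           DEFAULT_GENTAMICIN_RULE.bands))
        scaled = classify_dose(expected * factor * 2, weight, age, scaled_rule)
        assert base.classification == scaled.classification

    def test_margin_monotonicity(self):
        """Widening the margin never shrinks the correct set."""
        rng = np.random.default_rng(7)
        weights = rng.uniform(0.5, 5.5, 500)
        factors = rng.uniform(0.5, 1.8, 500)
        for m_small, m_big in [(0.1, 0.2), (0.2, 0.35)]:
            small = DoseRule(margin=m_small)
            big = DoseRule(margin=m_big)
            for w, f in zip(weights, factors):
                dose = expected_dose(w, 3) * f
                if classify_dose(dose, w, 3, small).classification == "correct":
                    assert classify_dose(dose, w, 3, big).classification == "correct"

    def test_equivalence_with_absolute_interval_oracle(self):
        """Classification agrees with an oracle that tests the prescribed
        amount against the explicit interval [(1−m)·d, (1+m)·d], on 1e5
        random prescriptions."""
        rng = np.random.default_rng(20140401)
        n = 100_000
        weights = rng.uniform(0.5, 5.5, n)
        ages = rng.integers(0, 8, n)
        doses = rng.uniform(0.5, 30.0, n)
        m = DEFAULT_GENTAMICIN_RULE.margin
        mismatches = 0
        for w, a, d in zip(weights, ages, doses):
            got = classify_dose(float(d), float(w), int(a)).classification
            exp = (3.0 if w < 2.0 else 5.0) * w
            if (1 - m) * exp <= d <= (1 + m) * exp:
                want = "correct"
            elif d > (1 + m) * exp:
                want = "overdose"
            else:
                want = "underdose"
            mismatches += got != want
        assert mismatches == 0

    def test_partition_of_cohort_counts(self, small_cohort):
        """correct/overdose/underdose/unassessable partition every
        prescription: class counts sum to the total."""
        records, prescriptions = small_cohort
        assessments = assess_cohort(prescriptions)
        counts = {}
        for a in assessments:
            counts[a.classification] = counts.get(a.classification, 0) + 1
        assert sum(counts.values()) == len(assessments) == len(prescriptions)
        assert set(counts) <= {"correct", "overdose", "underdose", "unassessable"}


class TestAccuracySeries:
    def _cohort(self, make_record, doses):
        records, rxs = [], []
        for i, (weight, dose) in enumerate(doses):
            rec = make_record({}, record_id=f"D{i:03d}",
                              admission_date=date(2015, 2, 1),
                              date_of_birth=date(2015, 2, 1),
                              birth_weight_kg=weight)
            records.append(rec)
            rxs.append(PrescriptionRecord(
                prescription_id=f"X{i:03d}", record_id=rec.record_id,
                drug="gentamicin", dose_mg=dose, weight_kg=weight, age_days=1))
        return records, rxs

    def test_all_guideline_doses_give_100_percent(self, make_record):
        records, rxs = self._cohort(make_record,
                                    [(1.5, 4.5), (1.8, 5.4), (1.2, 3.6)])
        series = dose_accuracy_series(assess_cohort(rxs), records,
                                      "under_2kg", make_periods())
        point = next(p for p in series if p.assessable)
        assert point.estimate.point == 1.0
        assert point.period.label == "2015-P1"

    def test_periods_without_prescriptions_have_no_estimate(self, make_record):
        records, rxs = self._cohort(make_record, [(1.5, 4.5)])
        series = dose_accuracy_series(assess_cohort(rxs), records,
                                      "under_2kg", make_periods())
        empty = [p for p in series if p.period.label != "2015-P1"]
        assert all(p.assessable == 0 and p.estimate is None for p in empty)

    def test_band_split_at_2kg(self):
        assert weight_band(1.999) == "under_2kg"
        assert weight_band(2.0) == "at_least_2kg"

    def test_unassessable_excluded_from_denominator(self, make_record):
        records, rxs = self._cohort(make_record, [(1.5, 4.5), (1.5, 4.5)])
        rxs[1].age_days = 12  # outside the rule window
        series = dose_accuracy_series(assess_cohort(rxs), records,
                                      "under_2kg", make_periods())
        point = next(p for p in series if p.assessable)
        assert (point.correct, point.assessable) == (1, 1)


def test_rule_registry_roundtrip(tmp_path):
    """A YAML rule registry reproduces the shipped gentamicin rule."""
    path = tmp_path / "rules.yaml"
    path.write_text(
        "gentamicin:\n"
        "  bands: [[2.0, 3.0], [null, 5.0]]\n"
        "  frequency: once_daily\n"
        "  age_window_days: [0, 7]\n"
        "  margin: 0.2\n")
    from neoaudit import load_rules
    rule = load_rules(path)["gentamicin"]
    assert rule == DEFAULT_GENTAMICIN_RULE
    assert math.isinf(rule.bands[-1][0])
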