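"""Documentation-completeness scoring: indicators, pooling, stratification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from neoaudit import (EmptyDenominatorError, NOT_APPLICABLE, domain_completeness,
                      doc_indicator, patient_completeness, stratify_variable)
from neoaudit.scoring import classify_fraction, completeness_table
from neoaudit.trend import make_periods

VITALS = "vital signs"
OTHER_EXAM = "other physical examination"
MATERNAL = "maternal history"


class TestDocIndicator:
    def test_documented_value_scores_one(self, make_record, revised_schema):
        record = make_record({"temperature": 36.8})
        assert doc_indicator(record, revised_schema.variable("temperature")) == 1

    @pytest.mark.parametrize("raw", ["", "   ", None])
    def test_blank_or_missing_scores_zero(self, make_record, revised_schema, raw):
        record = make_record({} if raw is None else {"temperature": raw})
        assert doc_indicator(record, revised_schema.variable("temperature")) == 0

    def test_revised_only_variable_na_on_baseline_record(self, make_record, revised_schema):
        """A post-revision variable queried on a baseline-form record is
        not applicable, not merely undocumented."""
        record = make_record({}, schema_version="baseline")
        assert doc_indicator(record, revised_schema.variable("stridor")) is NOT_APPLICABLE
        assert doc_indicator(record, revised_schema.variable("crackles")) == 0

    def test_zero_value_counts_as_documented(self, make_record, revised_schema):
        record = make_record({"parity": 0})
        assert doc_indicator(record, revised_schema.variable("parity")) == 1


class TestDomainCompleteness:
    def test_direct_slot_count(self, make_record, revised_schema):
        """2 records x 4 vital-sign variables with 6 documented slots: 6/8 = 75%."""
        r1 = make_record({"temperature": 36.8, "respiratory_rate": 40,
                          "heart_rate": 130, "oxygen_saturation": 97})
        r2 = make_record({"temperature": 37.0, "heart_rate": 120})
        result = domain_completeness([r1, r2], VITALS, revised_schema)
        assert (result.documented_count, result.possible_count) == (6, 8)
        assert result.estimate.point == 0.75

    def test_fully_documented_is_100_percent(self, make_record, revised_schema):
        record = make_record({v.name: "x" if v.value_kind != "numeric" else 1
                              for v in revised_schema.domains[VITALS]})
        result = domain_completeness([record], VITALS, revised_schema)
        assert result.estimate.point == 1.0

    def test_mixed_version_denominator_excludes_na_slots(self, make_record, revised_schema):
        """One baseline + one revised record in 'other physical examination':
        the denominator is 11 + 18 slots, never 18 + 18."""
        base = make_record({}, schema_version="baseline")
        revised = make_record({})
        result = domain_completeness([base, revised], OTHER_EXAM, revised_schema)
        assert result.possible_count == 11 + 18

    def test_no_applicable_slots_is_explicit_error(self, make_record, revised_schema):
        base = make_record({}, schema_version="baseline")
        with pytest.raises(EmptyDenominatorError):
            domain_completeness([base], MATERNAL, revised_schema)

    def test_monotone_under_filling_in_a_value(self, make_record, revised_schema):
        """Documenting one previously-blank applicable variable never
        decreases any completeness statistic."""
        records = [make_record({"temperature": 36.5}), make_record({})]
        before = domain_completeness(records, VITALS, revised_schema)
        records[1].values["heart_rate"] = 140
        after = domain_completeness(records, VITALS, revised_schema)
        assert after.estimate.point >= before.estimate.point
        assert after.possible_count == before.possible_count

    @given(data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_double_loop(self, data, revised_schema):
        """Pooled x/n equals an independent brute-force double loop over
        records and applicable domain variables, on cohorts of ≤ 50 records."""
        from datetime import date as _date

        from neoaudit import AdmissionRecord

        n_records = data.draw(st.integers(1, 50))
        specs = revised_schema.domains[VITALS]
        records = []
        for i in range(n_records):
            version = data.draw(st.sampled_from(["baseline", "revised2014"]))
            applicable = [s for s in specs
                          if version == "revised2014" or s.introduced_in == "baseline"]
            values = {s.name: 36.0 for s in applicable if data.draw(st.booleans())}
            records.append(AdmissionRecord(
                record_id=f"H{i:03d}", admission_date=_date(2015, 3, 10),
                date_of_birth=_date(2015, 3, 10), schema_version=version,
                values=values))
        result = domain_completeness(records, VITALS, revised_schema)
        # oracle: explicit loop, no shared code with the implementation path
        x = n = 0
        for rec in records:
            for spec in specs:
                if rec.schema_version == "baseline" and spec.introduced_in != "baseline":
                    continue
                n += 1
                x += spec.name in rec.values
        assert (result.documented_count, result.possible_count) == (x, n)


class TestPatientCompleteness:
    def test_extremes_and_half(self, make_record, revised_schema):
        names = revised_schema.variable_names()
        assert patient_completeness(make_record({n: "v" for n in names}),
                                    revised_schema) == 1.0
        assert patient_completeness(make_record({}), revised_schema) == 0.0
        half = make_record({n: "v" for n in names[:25]})
        assert patient_completeness(half, revised_schema) == 0.5

    def test_baseline_record_denominator_is_its_own_form(self, make_record,
                                                         revised_schema, baseline_schema):
        names = baseline_schema.variable_names()
        record = make_record({n: "v" for n in names}, schema_version="baseline")
        assert patient_completeness(record, revised_schema) == 1.0


class TestStratification:
    @pytest.mark.parametrize("fraction,stratum", [
        (0.0, "very_poor"), (0.10, "very_poor"), (0.2499, "very_poor"),
        (0.25, "poor"), (0.30, "poor"), (0.50, "poor"),
        (0.5001, "adequate"), (1.0, "adequate"),
    ])
    def test_thresholds_partition_unit_interval(self, fraction, stratum):
        """<25% very poor, 25–50% poor (boundaries included), >50% adequate."""
        assert classify_fraction(fraction) == stratum

    def test_stratify_counts_applicable_records_only(self, make_record, revised_schema):
        recs = ([make_record({"temperature": 37}) for _ in range(3)]
                + [make_record({}) for _ in range(7)])
        stratum = stratify_variable(recs, "temperature", revised_schema)
        assert stratum.documented_fraction == 0.3
        assert stratum.stratum == "poor"
        assert stratum.applicable_records == 10

    def test_zero_applicable_records_raises(self, make_record, revised_schema):
        base = make_record({}, schema_version="baseline")
        with pytest.raises(EmptyDenominatorError):
            stratify_variable([base], "stridor", revised_schema)


def test_completeness_table_recovers_generating_probability(small_cohort, revised_schema):
    """On a synthetic cohort with a constant per-variable documentation
    probability, pooled domain completeness lands inside its own Wilson
    95% CI of an average that brackets the generating rates."""
    records, _ = small_cohort
    periods = make_periods()
    table = completeness_table(records, revised_schema, periods)
    assert table, "expected populated table"
    for row in table:
        assert row.documented_count <= row.possible_count
        assert row.estimate.ci_low <= row.estimate.point <= row.estimate.ci_high
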