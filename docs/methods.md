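# Methods

## The record model

An admission is one row: structural fields (identifiers, admission and
birth dates, outcome, birth weight) plus a `values` map from dictionary
variable names to documented raw values, where a missing key or blank
string means *undocumented*. The dictionary is versioned: the revised
form has six domains with 6/12/6/4/18/4 variables (50 total); the
baseline form that preceded the 2014 revision is the same dictionary
minus the 14 variables tagged `introduced_in: revised2014` (the whole
maternal-history section, seven "other physical examination" signs —
stridor, bilateral air entry, femoral pulses, heart murmur, peripheral-
to-central skin temperature gradient, gestational size, severe wasting —
and oxygen saturation). Records admitted before the configurable
revision date (default 2014-04-01) carry the baseline version.

Validity checking is rule-per-finding: out-of-range numerics, unknown
categories and date inversions each produce one finding; missingness
never does, because missingness is the quantity the completeness
statistics measure. The shipped numeric bounds (temperature 30–42 °C,
birth weight 0.4–6.0 kg, respiratory rate 10–120/min, and so on) are
package defaults chosen to be clinically generous; any of them can be
overridden through the YAML/JSON dictionary format, which round-trips
losslessly.

## Completeness scoring

The documentation indicator is binary per (record, variable): 1 when a
non-blank value is present (free-text variables count as documented when
non-empty after whitespace trimming), 0 otherwise, and NOT_APPLICABLE
when the variable does not exist in the record's form version.
NOT_APPLICABLE slots are excluded from numerator *and* denominator — the
denominator is "variables that could be documented" — so mixed-version
cohorts aggregate without penalising older records.

Domain × period completeness is the *pooled* proportion across all slot
indicators in the cell. A per-patient fraction (documented applicable
variables over applicable variables) is also provided; pooling is the
default for period trends because the six-month estimate is naturally a
population-level slot count, and at equal per-record denominators the
two coincide. An empty cell (no applicable slots) raises an explicit
empty-denominator error rather than reporting 0/0.

Variable stratification uses the documented fraction with both
boundaries assigned to the middle stratum: very poor < 0.25,
0.25 ≤ poor ≤ 0.50, adequate > 0.50. The stratification could equally be
phrased on the *missing* fraction; this package stratifies on the
documented fraction because the stratum labels describe documentation
levels. Internally everything is unrounded; CSV outputs round
percentages to one decimal.

## Interval estimation and periods

All proportions use the Wilson score interval (via
`statsmodels.stats.proportion.proportion_confint`), with the plain x/n
as the point estimate. Wilson was chosen over the normal approximation
because it is the method that reproduces the worked mortality bound
(712/7985 → upper bound 9.6%; Wald gives 9.5%) and behaves correctly at
small per-period counts and extreme rates; Clopper–Pearson is available
through `ci_method="clopper_pearson"` for users who want a conservative
exact interval. Bounds are clipped so `ci_low ≤ point ≤ ci_high` holds
exactly despite float rounding at x = 0 or x = n.

Periods default to calendar half-years Jan–Jun ("P1") and Jul–Dec
("P2") from 2013 through 2016, the last bin clipped to the study end
(default 2016-11-30). A bin is `post_AF` when it ends on or after the
revision date, so 2014-P1 — which straddles the April 2014 revision —
counts as post-feedback. Arbitrary explicit bin edges can be supplied
when the half-year convention does not fit a study's calendar.

## Dose audit

The shipped rule is once-daily gentamicin, 3 mg/kg strictly below 2 kg
and 5 mg/kg at or above 2 kg (the band boundary belongs to the upper
band), applicable on days 0–7 of life. Classification is by the ratio
prescribed/guideline with margin m = 0.20; the margin boundaries are
inclusive for "correct" (a ratio of exactly 1.2 is correct — "within" a
±20% margin), guarded by a 1e-9 relative tolerance so exact-boundary
arithmetic is not at the mercy of float noise. The weight used is the
admission birth weight. Prescriptions outside the age window are
unassessable rather than judged against a rule that does not claim to
cover them; a config switch (`age_window_days`) can extend the window.
Frequency correctness is recorded on the rule but not folded into the
dose classification, which concerns the dose amount only. Other drugs
can be added through the YAML rule registry.

## Synthetic cohort generator

The generator stands in for hospital data that cannot be shared. Its
defaults describe the study conditions the pipeline is designed for: a
unit observed January 2013 – November 2016 with the form revised on
1 April 2014; sepsis prevalence 0.167; in-hospital mortality 0.09; birth
weight from a truncated normal, mean 2.88 kg, sd 0.6 kg (the sd and the
[0.5, 5.5] kg truncation are package choices — only the mean is pinned
by the audit design), 60% of admissions flagged for full-data
abstraction; 81.4% of sepsis babies and 47% of the rest receiving
gentamicin; dose errors as multiplicative perturbations at rates 4.4%
over / 2.4% under, with log-normal magnitudes placed strictly outside
the correctness margin and correct doses uniformly well inside it, so
classification recovers the generating rates exactly in expectation.
Admission volume defaults to 200/month (a high-volume unit admitting
thousands per year); tests and examples scale it down via
`admissions_per_month`, which changes n but no rates.

Documentation draws are independent Bernoulli per (record, variable)
with a probability that is either constant or a linear ramp across the
study window; the default configuration ramps most variables 0.55 → 0.80
(feedback improving documentation), keeps birth weight at 0.97, ramps
gestational age 0.10 → 0.80 and fixes a handful of examination signs at
very-poor levels, mirroring the qualitative pattern such audits report.
What the generator does **not** emulate: correlation between variables'
documentation (real missingness clusters by clerk, shift and form
page), correlation of documentation with severity or outcome, duplicate
or contradictory entries, and the census dips real units experience.
Passing recovery tests therefore shows the *scoring pipeline* is
correct and unbiased under independent missingness — not that the
pipeline's estimates are robust to structured missingness in real data.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical parameters and seed reproduce the
cohort bit for bit, and report regeneration from the same inputs is
byte-identical (nothing in the outputs depends on wall-clock time).

## Headline summary conventions

The report's sepsis, mortality and full-data proportions all use one
denominator: every record inside the audited window. Mixing
denominators (e.g. quoting prevalence over one record set and
demographics over another) is a common source of irreproducible audit
numbers, so the report notes the convention in its metadata instead of
silently harmonising anything.

## Problem sizes in the shipped tests

The test suite exercises parameter recovery on cohorts of ≈5000
admissions (109/month over the 47-month window), oracle equivalence of
the dose classifier on 10⁵ random prescriptions, Wilson coverage on
2000 simulated binomials, and brute-force aggregation equivalence on
cohorts of up to 50 records; the full suite runs in well under a minute
on one CPU.

## Known limitations

- Completeness measures availability, not correctness, of documented
  values; a wrong but present value scores 1.
- The dictionary ships exactly the 50 enumerable variables; studies
  tracking additional items must extend it through the dictionary file.
- The dose audit uses admission birth weight, not daily weights, and
  audits dose amount only (not frequency or duration).
- The per-patient and pooled completeness statistics differ when record
  counts per period are very uneven; the pooled form is the default.
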