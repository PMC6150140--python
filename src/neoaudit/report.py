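"""End-to-end audit pipeline: validate → bin → score → stratify → dose audit.

``run_audit`` takes admission and prescription records (in memory or as
CSV paths), applies the dictionary validity checks, bins admissions into
six-month periods, computes domain × period documentation completeness,
stratifies individual variables over a chosen period, audits gentamicin
dosing accuracy by weight band, and summarises cohort headline figures
(admissions, sepsis prevalence, mortality) with Wilson intervals.  All
headline proportions share a single denominator: every record loaded in
the audited window.

Report regeneration from the same inputs is byte-identical — nothing in
the outputs depends on wall-clock time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dosing import (AccuracyPoint, DEFAULT_GENTAMICIN_RULE, DoseAssessment,
                     DoseRule, UNASSESSABLE, WEIGHT_BANDS, assess_cohort,
                     dose_accuracy_series)
from .records import (AdmissionRecord, PrescriptionRecord, read_admissions_csv,
                      read_prescriptions_csv)
from .schema import BASELINE, NARSchema, REVISED2014, load_schema, validate_record
from .scoring import (CompletenessResult, VariableStratum, completeness_table,
                      stratify_all)
from .trend import (OutOfWindowError, PeriodBin, PeriodConfig,
                    ProportionEstimate, assign_period, make_periods,
                    proportion_estimate)

logger = logging.getLogger("neoaudit")


@dataclass
class AuditConfig:
    """Knobs of a full audit run."""

    periods: PeriodConfig = field(default_factory=PeriodConfig)
    dose_rule: DoseRule = field(default_factory=lambda: DEFAULT_GENTAMICIN_RULE)
    strata_period_label: str | None = None  # default: last period with records
    schema_config: str | None = None  # optional data-dictionary file
    seed: int | None = None  # recorded in metadata only


@dataclass
class AuditReport:
    """All tables a feedback meeting needs, plus provenance metadata."""

    metadata: dict
    completeness: list[CompletenessResult]
    strata: list[VariableStratum]
    strata_period: PeriodBin | None
    dosing: dict[str, list[AccuracyPoint]]
    assessments: list[DoseAssessment]
    summary: dict[str, ProportionEstimate]
    admission_count: int
    excluded_out_of_window: int
    validation_finding_count: int


def run_audit(
    records: Sequence[AdmissionRecord] | str | Path,
    prescriptions: Sequence[PrescriptionRecord] | str | Path | None = None,
    config: AuditConfig | None = None,
) -> AuditReport:
    """Run the full audit pipeline over a cohort.

    Records whose admission date falls outside the configured study window
    are excluded (and counted in the report metadata); everything else
    flows through scoring, stratification and the dosing audit.
    """
    config = config or AuditConfig()
    schemas = {v: load_schema(v, config.schema_config) for v in (BASELINE, REVISED2014)}
    schema = schemas[REVISED2014]

    if isinstance(records, (str, Path)):
        records = read_admissions_csv(records, schemas)
    if isinstance(prescriptions, (str, Path)):
        prescriptions = read_prescriptions_csv(prescriptions)
    prescriptions = prescriptions or []
    if not records:
        raise ValueError("empty cohort: no admission records")

    finding_count = 0
    for record in records:
        finding_count += len(validate_record(record, schemas[record.schema_version]))
    logger.info("validated %d records: %d findings", len(records), finding_count)

    periods = make_periods(config.periods)
    in_window: list[AdmissionRecord] = []
    excluded = 0
    for record in records:
        try:
            assign_period(record.admission_date, periods)
        except OutOfWindowError:
            excluded += 1
            continue
        in_window.append(record)
    logger.info("binned %d records (%d outside the study window)", len(in_window), excluded)
    if not in_window:
        raise ValueError("empty cohort: no records inside the study window")

    conf, method = config.periods.conf_level, config.periods.ci_method
    completeness = completeness_table(in_window, schema, periods, conf, method)

    if config.strata_period_label is not None:
        candidates = [p for p in periods if p.label == config.strata_period_label]
        if not candidates:
            raise ValueError(f"unknown period label {config.strata_period_label!r}")
        strata_period = candidates[0]
    else:
        populated = {r.period.label for r in completeness}
        strata_period = next((p for p in reversed(periods) if p.label in populated), None)
    if strata_period is not None:
        strata = stratify_all(
            [r for r in in_window if r.admission_date in strata_period], schema)
    else:
        strata = []

    in_window_ids = {r.record_id for r in in_window}
    assessments = assess_cohort(
        [rx for rx in prescriptions if rx.record_id in in_window_ids],
        config.dose_rule)
    dosing = {
        band: dose_accuracy_series(assessments, in_window, band, periods, conf, method)
        for band in WEIGHT_BANDS
    }

    n = len(in_window)
    sepsis = sum(r.has_sepsis_diagnosis for r in in_window)
    deaths = sum(r.outcome == "dead" for r in in_window)
    summary = {
        "sepsis": proportion_estimate(sepsis, n, conf, method),
        "mortality": proportion_estimate(deaths, n, conf, method),
        "full_dataset": proportion_estimate(sum(r.full_dataset for r in in_window), n, conf, method),
    }

    version_counts = {v: sum(r.schema_version == v for r in in_window)
                      for v in (BASELINE, REVISED2014)}
    metadata = {
        "config": {
            "study_start": config.periods.study_start.isoformat(),
            "study_end": config.periods.study_end.isoformat(),
            "revision_date": config.periods.revision_date.isoformat(),
            "conf_level": conf,
            "ci_method": method,
            "dose_rule": {
                "drug": config.dose_rule.drug,
                "bands": [[None if b == float("inf") else b, d]
                          for b, d in config.dose_rule.bands],
                "margin": config.dose_rule.margin,
                "age_window_days": list(config.dose_rule.age_window_days),
            },
        },
        "seed": config.seed,
        "schema_version_counts": version_counts,
        "records_loaded": len(records),
        "records_in_window": n,
        "records_excluded_out_of_window": excluded,
        "prescriptions_loaded": len(prescriptions),
        "validation_findings": finding_count,
        "notes": [
            "headline proportions use a single denominator: all records in the audited window",
        ],
    }
    return AuditReport(
        metadata=metadata,
        completeness=completeness,
        strata=strata,
        strata_period=strata_period,
        dosing=dosing,
        assessments=assessments,
        summary=summary,
        admission_count=n,
        excluded_out_of_window=excluded,
        validation_finding_count=finding_count,
    )


# ---- serialisation ---------------------------------------------------------


def completeness_frame(report: AuditReport) -> pd.DataFrame:
    rows = [
        {
            "domain": r.domain,
            "period_label": r.period.label if r.period else "",
            "phase": r.period.phase if r.period else "",
            "x": r.documented_count,
            "n": r.possible_count,
            "pct": round(r.estimate.point * 100, 1),
            "ci_low": round(r.estimate.ci_low * 100, 1),
            "ci_high": round(r.estimate.ci_high * 100, 1),
        }
        for r in report.completeness
    ]
    return pd.DataFrame(rows, columns=["domain", "period_label", "phase", "x", "n",
                                       "pct", "ci_low", "ci_high"])


def strata_frame(report: AuditReport) -> pd.DataFrame:
    rows = [
        {
            "variable": s.variable,
            "domain": s.domain,
            "fraction_documented_pct": round(s.documented_fraction * 100, 1),
            "n_records": s.applicable_records,
            "stratum": s.stratum,
        }
        for s in report.strata
    ]
    return pd.DataFrame(rows, columns=["variable", "domain", "fraction_documented_pct",
                                       "n_records", "stratum"])


def dosing_frame(report: AuditReport) -> pd.DataFrame:
    rows = []
    for band, series in report.dosing.items():
        for point in series:
            est = point.estimate
            rows.append({
                "weight_band": band,
                "period_label": point.period.label,
                "phase": point.period.phase,
                "correct": point.correct,
                "assessable": point.assessable,
                "pct_correct": round(est.point * 100, 1) if est else "",
                "ci_low": round(est.ci_low * 100, 1) if est else "",
                "ci_high": round(est.ci_high * 100, 1) if est else "",
            })
    return pd.DataFrame(rows, columns=["weight_band", "period_label", "phase", "correct",
                                       "assessable", "pct_correct", "ci_low", "ci_high"])


def summary_frame(report: AuditReport) -> pd.DataFrame:
    rows = [{"measure": "admissions", "x": report.admission_count,
             "n": report.admission_count, "pct": "", "ci_low": "", "ci_high": ""}]
    for name, est in report.summary.items():
        pct, lo, hi = est.as_percent()
        rows.append({"measure": name, "x": est.x, "n": est.n,
                     "pct": pct, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows, columns=["measure", "x", "n", "pct", "ci_low", "ci_high"])


def summary_json(report: AuditReport) -> dict:
    return {
        "metadata": report.metadata,
        "summary": {
            name: {"x": est.x, "n": est.n, "point": est.point,
                   "ci_low": est.ci_low, "ci_high": est.ci_high,
                   "conf_level": est.conf_level, "method": est.method}
            for name, est in report.summary.items()
        },
        "strata_period": report.strata_period.label if report.strata_period else None,
    }


def write_report(report: AuditReport, out_dir: str | Path,
                 formats: Sequence[str] = ("csv",), plots: bool = False) -> dict[str, Path]:
    """Write the report tables (CSV always; JSON summary and plots optional)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "csv" in formats:
        for name, frame in [
            ("completeness", completeness_frame(report)),
            ("variable_strata", strata_frame(report)),
            ("dosing_accuracy", dosing_frame(report)),
            ("summary", summary_frame(report)),
        ]:
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written[name] = path
    if "json" in formats:
        path = out_dir / "summary.json"
        path.write_text(json.dumps(summary_json(report), indent=2, sort_keys=True) + "\n")
        written["summary_json"] = path
    if plots:
        written.update(_write_plots(report, out_dir))
    return written


def _write_plots(report: AuditReport, out_dir: Path) -> dict[str, Path]:
    """Trend plots with CI ribbons (needs matplotlib; flag-gated)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    comp = completeness_frame(report)
    if not comp.empty:
        fig, ax = plt.subplots(figsize=(9, 5))
        for domain, sub in comp.groupby("domain", sort=False):
            xs = range(len(sub))
            ax.plot(list(xs), sub["pct"], marker="o", label=domain)
            ax.fill_between(list(xs), sub["ci_low"], sub["ci_high"], alpha=0.2)
        ax.set_xticks(range(comp["period_label"].nunique()))
        ax.set_xticklabels(sorted(comp["period_label"].unique()), rotation=45)
        ax.set_ylabel("documented slots (%)")
        ax.set_ylim(0, 100)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / "completeness_trend.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["completeness_plot"] = path

    dose = dosing_frame(report)
    dose = dose[dose["assessable"] > 0]
    if not dose.empty:
        fig, axes = plt.subplots(len(report.dosing), 1, figsize=(9, 6), sharex=True)
        for ax, (band, sub) in zip(axes, dose.groupby("weight_band", sort=False)):
            xs = range(len(sub))
            ax.plot(list(xs), sub["pct_correct"], marker="o", color="tab:blue")
            ax.fill_between(list(xs), sub["ci_low"].astype(float),
                            sub["ci_high"].astype(float), alpha=0.25, color="grey")
            ax.set_title(band)
            ax.set_ylabel("% correct dose")
            ax.set_ylim(0, 100)
            ax.set_xticks(list(xs))
            ax.set_xticklabels(sub["period_label"], rotation=45)
        fig.tight_layout()
        path = out_dir / "dosing_trend.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["dosing_plot"] = path
    return written
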