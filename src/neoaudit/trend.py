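"""Period binning and binomial interval estimation.

Every proportion the audit reports — documentation completeness, sepsis
prevalence, dosing accuracy — is an ``x`` of ``n`` with a score-test
(Wilson) confidence interval.  The Wilson interval is the default because
it behaves well near 0 and 1 and at the modest per-period sample sizes a
single unit produces; Clopper–Pearson is available as a configuration
alternative.  Trends are plain per-period estimates over six-month
calendar bins, split into a pre- and post-feedback phase at the form
revision date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

WILSON = "wilson"
CLOPPER_PEARSON = "clopper_pearson"
_STATSMODELS_METHOD = {WILSON: "wilson", CLOPPER_PEARSON: "beta"}

PRE_AF = "pre_AF"
POST_AF = "post_AF"


class OutOfWindowError(ValueError):
    """A date falls outside the configured study window."""


class EmptyDenominatorError(ZeroDivisionError):
    """A proportion was requested with n = 0."""


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its confidence interval.

    ``point`` is the plain ``x/n`` (not the interval midpoint); the CI is
    computed by ``method`` at ``conf_level``.
    """

    x: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    method: str = WILSON

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """Point and bounds on the 0–100 scale, rounded for display."""
        return tuple(round(v * 100, decimals) for v in (self.point, self.ci_low, self.ci_high))


def proportion_estimate(x: int, n: int, conf_level: float = 0.95,
                        method: str = WILSON) -> ProportionEstimate:
    """Point estimate x/n with a binomial CI (Wilson by default)."""
    if n < 1:
        raise EmptyDenominatorError("proportion requested with n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if method not in _STATSMODELS_METHOD:
        raise ValueError(f"unknown CI method {method!r}")
    low, high = proportion_confint(x, n, alpha=1 - conf_level,
                                   method=_STATSMODELS_METHOD[method])
    point = x / n
    # guard against float noise at the boundaries (e.g. an upper bound of
    # 1 - 1e-16 when x = n) so ci_low <= point <= ci_high always holds
    low = min(max(float(low), 0.0), point)
    high = max(min(float(high), 1.0), point)
    return ProportionEstimate(x=int(x), n=int(n), point=point,
                              ci_low=low, ci_high=high,
                              conf_level=conf_level, method=method)


def wilson_interval(x: int, n: int, conf_level: float = 0.95) -> ProportionEstimate:
    """Wilson score interval for x successes out of n trials."""
    return proportion_estimate(x, n, conf_level=conf_level, method=WILSON)


@dataclass(frozen=True)
class PeriodBin:
    """One six-month reporting interval with inclusive calendar bounds."""

    label: str
    start_date: date
    end_date: date
    phase: str  # pre_AF | post_AF

    def __contains__(self, when: date) -> bool:
        return self.start_date <= when <= self.end_date


@dataclass
class PeriodConfig:
    """Study window, feedback start date and optional explicit bin edges.

    With no explicit ``bin_edges`` the bins are calendar half-years
    (Jan–Jun = "P1", Jul–Dec = "P2") covering the study window; the first
    and last bins are clipped to it.  A bin is post-feedback when it ends
    on or after ``revision_date``.
    """

    study_start: date = date(2013, 1, 1)
    study_end: date = date(2016, 11, 30)
    revision_date: date = date(2014, 4, 1)
    bin_edges: list[date] | None = None  # explicit inclusive bin starts + final end
    conf_level: float = 0.95
    ci_method: str = WILSON

    def __post_init__(self) -> None:
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")


def make_periods(config: PeriodConfig | None = None) -> list[PeriodBin]:
    """Materialise the period bins for a study configuration."""
    config = config or PeriodConfig()
    edges: list[tuple[date, date]] = []
    if config.bin_edges:
        pts = sorted(config.bin_edges)
        if len(pts) < 2:
            raise ValueError("bin_edges needs at least two dates")
        from datetime import timedelta
        for lo, hi in zip(pts[:-1], pts[1:]):
            edges.append((lo, hi - timedelta(days=1)))
        labels = [f"B{i + 1}" for i in range(len(edges))]
    else:
        edges, labels = [], []
        year = config.study_start.year
        while year <= config.study_end.year:
            for half, (m0, m1, d1) in enumerate([(1, 6, 30), (7, 12, 31)], start=1):
                lo, hi = date(year, m0, 1), date(year, m1, d1)
                if hi < config.study_start or lo > config.study_end:
                    continue
                edges.append((max(lo, config.study_start), min(hi, config.study_end)))
                labels.append(f"{year}-P{half}")
            year += 1
    return [
        PeriodBin(label=lab, start_date=lo, end_date=hi,
                  phase=POST_AF if hi >= config.revision_date else PRE_AF)
        for lab, (lo, hi) in zip(labels, edges)
    ]


def assign_period(when: date, periods: Sequence[PeriodBin] | PeriodConfig | None = None) -> PeriodBin:
    """Map a calendar date to its reporting bin.

    ``periods`` may be a prebuilt bin list or a :class:`PeriodConfig`
    (defaults apply when omitted).  Dates outside every bin raise
    :class:`OutOfWindowError`.
    """
    if periods is None or isinstance(periods, PeriodConfig):
        periods = make_periods(periods)
    for bin_ in periods:
        if when in bin_:
            return bin_
    raise OutOfWindowError(f"{when.isoformat()} is outside the configured study window")
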