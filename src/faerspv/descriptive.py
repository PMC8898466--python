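"""Descriptive analytics for a drug cohort: clinical-characteristics table,
chi-square subgroup comparisons, case-fatality rate and time-to-onset.

The central object is :class:`CohortSummary`: stratified case counts for the
event cohort (reports flagged for the umbrella event group) side by side with
the other-AE cohort (reports of the same drug without the event), mirroring
the usual "Table 1" of a pharmacovigilance study.  Outcome strata are not
mutually exclusive — one FAERS case can carry several outcome codes — and
their percentages use the cohort size as denominator, so an outcome column
need not sum to 100%.

Time-to-onset is days from the earliest target-drug therapy start to the
event date, restricted to day-precision dates; negative intervals (event
before therapy start, data-entry noise) are excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import (DrugDictionary, EventDictionary, PRIMARY_SUSPECT,
                     classify_dose_regimen, flag_events)
from .faers_io import CaseReport

logger = logging.getLogger(__name__)

ELDERLY_AGE = 65.0
YEAR_BINS = (("2005-2010", 2005, 2010), ("2011-2015", 2011, 2015),
             ("2016-2020", 2016, 2020))
OUTCOME_ORDER = ("death", "life_threatening", "disability", "hospitalization",
                 "other_serious", "required_intervention")


class EmptyCohortError(ValueError):
    pass


@dataclass
class StratumCounts:
    """Counts and percentages of one stratification for one cohort."""

    counts: dict[str, int]
    denominator: int
    exclusive: bool = True

    def pct(self, stratum: str) -> float:
        return 100.0 * self.counts[stratum] / self.denominator


@dataclass
class CohortSummary:
    """Table-1 analogue: stratified counts for event vs other-AE cohorts."""

    target: str
    n_event: int
    n_other: int
    strata: dict[str, tuple[StratumCounts, StratumCounts]]
    case_fatality_rate: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (ev, ot) in self.strata.items():
            for stratum in ev.counts:
                rows.append({
                    "stratification": name, "stratum": stratum,
                    "event_n": ev.counts[stratum],
                    "event_pct": round(ev.pct(stratum), 2),
                    "other_n": ot.counts[stratum],
                    "other_pct": round(ot.pct(stratum), 2),
                })
        return pd.DataFrame(rows)


def _count(reports: Sequence[CaseReport], keys: Sequence[str],
           classify: Callable[[CaseReport], str]) -> dict[str, int]:
    counts = {k: 0 for k in keys}
    for r in reports:
        counts[classify(r)] += 1
    return counts


def _sex(r: CaseReport) -> str:
    return r.sex if r.sex in ("M", "F") else "missing"


def _age_band(r: CaseReport) -> str:
    if r.age_years is None:
        return "missing"
    return ">=65" if r.age_years >= ELDERLY_AGE else "<65"


def _year_band(r: CaseReport) -> str:
    if r.year is None:
        return "missing"
    for label, lo, hi in YEAR_BINS:
        if lo <= r.year <= hi:
            return label
    return "other"


def summarize(reports: Sequence[CaseReport], drug_dict: DrugDictionary,
              event_dict: EventDictionary, target: str,
              roles: frozenset[str] = PRIMARY_SUSPECT) -> CohortSummary:
    """Stratify a (deduplicated) target-drug cohort by event status.

    ``reports`` must be the target-drug cohort; it is split on the umbrella
    event-group flag into event and other-AE sub-cohorts and each is counted
    over sex, age band (<65 / >=65), reporter class, receipt-year bins,
    outcome codes (non-exclusive) and dose regimen.
    """
    if not reports:
        raise EmptyCohortError("empty target cohort")
    umbrella = event_dict.umbrella
    event_cohort = [r for r in reports if flag_events(r, event_dict)[umbrella]]
    other_cohort = [r for r in reports if not flag_events(r, event_dict)[umbrella]]
    if not event_cohort:
        raise EmptyCohortError("no reports flagged for the event group")

    strata: dict[str, tuple[StratumCounts, StratumCounts]] = {}

    def both(name: str, keys: Sequence[str],
             classify: Callable[[CaseReport], str], exclusive: bool = True) -> None:
        strata[name] = (
            StratumCounts(_count(event_cohort, keys, classify),
                          len(event_cohort), exclusive),
            StratumCounts(_count(other_cohort, keys, classify),
                          len(other_cohort) or 1, exclusive),
        )

    both("sex", ("M", "F", "missing"), _sex)
    both("age", ("<65", ">=65", "missing"), _age_band)
    both("reporter", ("healthcare", "non_healthcare", "unknown"),
         lambda r: r.reporter_class)
    both("year", tuple(b[0] for b in YEAR_BINS) + ("other", "missing"),
         _year_band)

    # outcomes: non-exclusive rows; 'missing' = report with no outcome code
    def outcome_counts(cohort: Sequence[CaseReport]) -> StratumCounts:
        counts = {k: 0 for k in OUTCOME_ORDER + ("missing",)}
        for r in cohort:
            if not r.outcomes:
                counts["missing"] += 1
            for o in r.outcomes:
                counts[o] += 1
        return StratumCounts(counts, len(cohort) or 1, exclusive=False)

    strata["outcome"] = (outcome_counts(event_cohort), outcome_counts(other_cohort))

    # dose regimen: loading/non-loading and standard/high maintenance overlap,
    # so the rows are kept as one non-exclusive stratification (as in the
    # conventional Table-1 layout)
    def regimen_counts(cohort: Sequence[CaseReport]) -> StratumCounts:
        keys = ("loading", "non_loading", "standard_maintenance",
                "high_maintenance", "missing")
        counts = {k: 0 for k in keys}
        for r in cohort:
            loading, maintenance = classify_dose_regimen(r, drug_dict, target,
                                                         roles)
            if loading is None and maintenance is None:
                counts["missing"] += 1
                continue
            if loading is not None:
                counts["loading" if loading else "non_loading"] += 1
            if maintenance == "standard":
                counts["standard_maintenance"] += 1
            elif maintenance == "high":
                counts["high_maintenance"] += 1
        return StratumCounts(counts, len(cohort) or 1, exclusive=False)

    strata["dose_regimen"] = (regimen_counts(event_cohort),
                              regimen_counts(other_cohort))

    cfr = 100.0 * strata["outcome"][0].counts["death"] / len(event_cohort)
    return CohortSummary(target=target, n_event=len(event_cohort),
                         n_other=len(other_cohort), strata=strata,
                         case_fatality_rate=cfr)


def case_fatality(summary: CohortSummary) -> float:
    """Percentage of event-cohort cases with a death outcome."""
    return summary.case_fatality_rate


def chisq_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    Raises on a zero marginal (expected counts undefined).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    stat, p, _, _ = chi2_contingency(arr, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Time to onset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeToEventRecord:
    caseid: str
    onset_days: int


@dataclass
class TimeToEventSummary:
    """Onset-interval records with median/IQR and the cumulative-onset curve."""

    records: list[TimeToEventRecord]
    median: float
    iqr: tuple[float, float]
    excluded: dict[str, int]

    def fraction_within(self, days: int) -> float:
        """Percentage of records with onset within ``days`` days (inclusive)."""
        n = len(self.records)
        return 100.0 * sum(r.onset_days <= days for r in self.records) / n

    def curve(self) -> pd.DataFrame:
        """Cumulative onset percentage on the integer day grid 0..max."""
        top = max(r.onset_days for r in self.records)
        days = np.arange(top + 1)
        return pd.DataFrame({
            "day": days,
            "cumulative_pct": [self.fraction_within(int(d)) for d in days],
        })


def _earliest_target_start(report: CaseReport, drug_dict: DrugDictionary,
                           target: str, roles: frozenset[str]):
    starts = []
    for e in report.drugs:
        if e.role not in roles or e.therapy_start is None:
            continue
        if e.therapy_start.precision != "day":
            continue
        if drug_dict.matches_name(target, e.name_raw) or (
                e.active_ingredient_raw
                and drug_dict.matches_name(target, e.active_ingredient_raw)):
            starts.append(e.therapy_start.to_date())
    return min(starts) if starts else None


def time_to_event(reports: Sequence[CaseReport], drug_dict: DrugDictionary,
                  target: str,
                  roles: frozenset[str] = PRIMARY_SUSPECT) -> TimeToEventSummary:
    """Onset intervals: event date minus earliest target-drug therapy start.

    Only day-precision dates enter; reports with missing or partial dates and
    negative intervals are excluded (tallied in ``excluded``).  Median and
    IQR use linear interpolation between order statistics.
    """
    records: list[TimeToEventRecord] = []
    excluded = {"no_event_date": 0, "partial_event_date": 0,
                "no_therapy_start": 0, "negative_interval": 0}
    for r in reports:
        if r.event_date is None:
            excluded["no_event_date"] += 1
            continue
        if r.event_date.precision != "day":
            excluded["partial_event_date"] += 1
            continue
        start = _earliest_target_start(r, drug_dict, target, roles)
        if start is None:
            excluded["no_therapy_start"] += 1
            continue
        onset = (r.event_date.to_date() - start).days
        if onset < 0:
            excluded["negative_interval"] += 1
            logger.warning("case %s: event %d day(s) before therapy start; "
                           "excluded", r.caseid, -onset)
            continue
        records.append(TimeToEventRecord(caseid=r.caseid, onset_days=onset))
    if not records:
        raise EmptyCohortError(
            f"no eligible time-to-event records; exclusions: {excluded}")
    days = np.array([r.onset_days for r in records], dtype=float)
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # linear interpolation
    return TimeToEventSummary(records=records, median=float(med),
                              iqr=(float(q1), float(q3)), excluded=excluded)
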