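"""Cohort construction: deduplication, drug/event matching, comparison designs.

Turns assembled :class:`~faerspv.faers_io.CaseReport` lists into the analysis
cohorts behind a disproportionality study: keep the latest version of each
case, match drugs of interest as primary suspect via a name dictionary, map
reaction preferred terms to event groups, and count the 2x2 cells for each
comparison design (full database or named comparator drug sets, pooled or
per drug).

All counting is at case level: one deduplicated case contributes at most one
count to any cell, however many matching PTs or drug entries it carries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .faers_io import CaseReport, DrugEntry
from .signals import ContingencyTable

logger = logging.getLogger(__name__)

UMBRELLA_GROUP = "coagulation_dysfunction"

#: default drug roles that qualify a report for a drug cohort
PRIMARY_SUSPECT = frozenset({"primary_suspect"})


class DictionaryError(ValueError):
    """Raised on malformed or inconsistent dictionary files."""


# ---------------------------------------------------------------------------
# Dictionaries
# ---------------------------------------------------------------------------

def _parse_blocks(text: str) -> dict[str, list[str]]:
    """Parse the plain-text block format: '[label]' then one entry per line."""
    blocks: dict[str, list[str]] = {}
    label: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            label = line[1:-1].strip()
            if not label:
                raise DictionaryError(f"line {lineno}: empty label")
            if label in blocks:
                raise DictionaryError(f"line {lineno}: duplicate label {label!r}")
            blocks[label] = []
        elif label is None:
            raise DictionaryError(f"line {lineno}: entry before any [label]")
        else:
            blocks[label].append(line)
    for label, entries in blocks.items():
        if not entries:
            raise DictionaryError(f"label {label!r} has no entries")
    return blocks


@dataclass
class DrugDictionary:
    """Per drug label, the generic and brand name patterns that identify it."""

    patterns: dict[str, list[str]]
    _regexes: dict[str, list[re.Pattern]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for label, pats in self.patterns.items():
            if not pats:
                raise DictionaryError(f"drug label {label!r} has no patterns")
            # word-boundary substring: pattern must not be glued to another
            # alphanumeric run ("TIGECYCLINE 50MG VIAL" matches, "XTIGECYCLINEX"
            # does not)
            self._regexes[label] = [
                re.compile(r"(?<![a-z0-9])" + re.escape(" ".join(p.lower().split()))
                           + r"(?![a-z0-9])")
                for p in pats
            ]

    @property
    def labels(self) -> list[str]:
        return list(self.patterns)

    def matches_name(self, label: str, name: str) -> bool:
        if label not in self._regexes:
            raise KeyError(f"unknown drug label {label!r}")
        normalized = " ".join(name.lower().split())
        return any(rx.search(normalized) for rx in self._regexes[label])

    @classmethod
    def from_text(cls, text: str) -> "DrugDictionary":
        return cls(_parse_blocks(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugDictionary":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


@dataclass
class EventDictionary:
    """Per event group, the set of MedDRA preferred terms that define it.

    The umbrella group ``coagulation_dysfunction`` must be a superset of the
    union of the named subgroups (enforced on construction).
    """

    terms: dict[str, list[str]]
    umbrella: str = UMBRELLA_GROUP
    _lowered: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for group, pts in self.terms.items():
            if not pts:
                raise DictionaryError(f"event group {group!r} has no terms")
            self._lowered[group] = frozenset(pt.lower().strip() for pt in pts)
        if self.umbrella in self.terms:
            union = set().union(*(self._lowered[g] for g in self.terms
                                  if g != self.umbrella))
            missing = union - self._lowered[self.umbrella]
            if missing:
                raise DictionaryError(
                    f"umbrella group {self.umbrella!r} is missing subgroup "
                    f"terms: {sorted(missing)[:5]}"
                )

    @property
    def groups(self) -> list[str]:
        return list(self.terms)

    @property
    def subgroups(self) -> list[str]:
        return [g for g in self.terms if g != self.umbrella]

    def group_terms_lower(self, group: str) -> frozenset[str]:
        return self._lowered[group]

    def umbrella_only_terms(self) -> list[str]:
        """PTs in the umbrella group that belong to no named subgroup."""
        union = set().union(*(self._lowered[g] for g in self.subgroups)) \
            if self.subgroups else set()
        return [pt for pt in self.terms[self.umbrella]
                if pt.lower().strip() not in union]

    @classmethod
    def from_text(cls, text: str, umbrella: str = UMBRELLA_GROUP) -> "EventDictionary":
        return cls(_parse_blocks(text), umbrella=umbrella)

    @classmethod
    def from_file(cls, path: str | Path,
                  umbrella: str = UMBRELLA_GROUP) -> "EventDictionary":
        return cls.from_text(Path(path).read_text(encoding="utf-8"), umbrella)


def default_drug_dictionary() -> DrugDictionary:
    """Bundled drug dictionary: tigecycline and its comparator antibiotics."""
    text = resources.files("faerspv.data").joinpath("drug_dictionary.txt") \
        .read_text(encoding="utf-8")
    return DrugDictionary.from_text(text)


def default_event_dictionary() -> EventDictionary:
    """Bundled coagulation-dysfunction PT groups (six subgroups + umbrella)."""
    text = resources.files("faerspv.data").joinpath("event_dictionary.txt") \
        .read_text(encoding="utf-8")
    return EventDictionary.from_text(text)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _primaryid_key(pid: str) -> tuple[int, str]:
    # numeric order for digit strings == (length, lexicographic); the same key
    # stays deterministic for non-digit ids
    return (len(pid), pid)


def _version_key(report: CaseReport) -> tuple[tuple[int, int, int], tuple[int, str]]:
    receipt = report.receipt_date.sort_key() if report.receipt_date else (0, 0, 0)
    return (receipt, _primaryid_key(report.primaryid))


def deduplicate(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep, per caseid, the report with the latest FDA receipt date.

    Ties are broken by the greatest primaryid (numeric order on digit
    strings).  Idempotent; input order of surviving reports is preserved.
    """
    best: dict[str, CaseReport] = {}
    order: list[str] = []
    for report in reports:
        incumbent = best.get(report.caseid)
        if incumbent is None:
            best[report.caseid] = report
            order.append(report.caseid)
        elif _version_key(report) > _version_key(incumbent):
            best[report.caseid] = report
    return [best[cid] for cid in order]


# ---------------------------------------------------------------------------
# Matching and flagging
# ---------------------------------------------------------------------------

def match_drug(report: CaseReport, drug_dict: DrugDictionary, label: str,
               roles: frozenset[str] = PRIMARY_SUSPECT) -> bool:
    """True iff some drug entry with a qualifying role matches ``label``.

    Both the verbatim drug name and the active-ingredient field are checked
    against the label's patterns (case-insensitive, whitespace-normalized,
    word-boundary substring).
    """
    if label not in drug_dict.patterns:
        raise KeyError(f"unknown drug label {label!r}")
    for entry in report.drugs:
        if entry.role not in roles:
            continue
        if drug_dict.matches_name(label, entry.name_raw):
            return True
        if entry.active_ingredient_raw and \
                drug_dict.matches_name(label, entry.active_ingredient_raw):
            return True
    return False


def flag_events(report: CaseReport, event_dict: EventDictionary) -> dict[str, bool]:
    """Report-level event-group flags from the reaction PT list.

    A group is flagged iff the report lists at least one of its PTs
    (case-insensitive exact match); several matching PTs still yield a single
    flag — counting stays at case level.
    """
    pts = {pt.lower().strip() for pt in report.reactions}
    return {group: not pts.isdisjoint(event_dict.group_terms_lower(group))
            for group in event_dict.groups}


# ---------------------------------------------------------------------------
# Comparison designs
# ---------------------------------------------------------------------------

FULL_DATABASE = "full_database"


@dataclass(frozen=True)
class ComparisonDesign:
    """One comparison: target drug vs the full database or a drug set."""

    label: str
    target: str
    comparator: tuple[str, ...] | str  # FULL_DATABASE or drug labels
    pairing: str = "pooled"  # 'pooled' | 'per_drug'

    def __post_init__(self) -> None:
        if self.pairing not in ("pooled", "per_drug"):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")
        if isinstance(self.comparator, tuple):
            if self.target in self.comparator:
                raise ValueError("target drug cannot be its own comparator")
            if not self.comparator:
                raise ValueError("empty comparator drug set")
        elif self.comparator != FULL_DATABASE:
            raise ValueError(f"unknown comparator {self.comparator!r}")


def default_designs(target: str = "tigecycline") -> list[ComparisonDesign]:
    """The four standard comparisons: full database, anti-MRSA drugs
    (vancomycin/linezolid/daptomycin, per drug), anti-ESBL carbapenems
    (meropenem/imipenem-cilastatin, per drug), and NMTT-side-chain
    cephalosporins (cefoperazone)."""
    return [
        ComparisonDesign("full_database", target, FULL_DATABASE),
        ComparisonDesign("anti_mrsa", target,
                         ("vancomycin", "linezolid", "daptomycin"), "per_drug"),
        ComparisonDesign("anti_esbl", target,
                         ("meropenem", "imipenem_cilastatin"), "per_drug"),
        ComparisonDesign("nmtt_cephalosporin", target, ("cefoperazone",),
                         "per_drug"),
    ]


class EmptyCohortError(ValueError):
    """Raised when a design's target cohort contains no reports."""


def build_design_tables(reports: Sequence[CaseReport],
                        drug_dict: DrugDictionary,
                        event_dict: EventDictionary,
                        design: ComparisonDesign,
                        roles: frozenset[str] = PRIMARY_SUSPECT,
                        exclude_target_from_full_db: bool = True,
                        ) -> list[ContingencyTable]:
    """Count the 2x2 cells of ``design`` for every event group.

    ``reports`` must already be deduplicated.  The full-database comparator
    draws c/d from all reports whose primary suspect is *not* the target drug
    (standard case/non-case practice; configurable).  A report qualifying for
    both the target and a comparator drug is assigned to the target only, to
    prevent double counting.
    """
    target_mask = [match_drug(r, drug_dict, design.target, roles) for r in reports]
    if not any(target_mask):
        raise EmptyCohortError(f"no target reports for {design.target!r}")
    flags = [flag_events(r, event_dict) for r in reports]

    if design.comparator == FULL_DATABASE:
        comparator_sets: list[tuple[str, list[int]]] = [(
            FULL_DATABASE,
            [i for i, is_t in enumerate(target_mask)
             if not (exclude_target_from_full_db and is_t)],
        )]
    else:
        per_drug: dict[str, list[int]] = {}
        overlap = 0
        for drug in design.comparator:
            idx = []
            for i, r in enumerate(reports):
                if not match_drug(r, drug_dict, drug, roles):
                    continue
                if target_mask[i]:
                    overlap += 1
                    continue  # target assignment wins
                idx.append(i)
            per_drug[drug] = idx
        if overlap:
            logger.info("%d report(s) matched both target and a comparator; "
                        "assigned to target", overlap)
        if design.pairing == "per_drug":
            comparator_sets = list(per_drug.items())
        else:
            pooled = sorted(set().union(*per_drug.values()))
            comparator_sets = [("+".join(design.comparator), pooled)]

    empty = [label for label, idx in comparator_sets if not idx]
    if empty:
        logger.warning("design %s: empty comparator cohort(s) skipped: %s",
                       design.label, ", ".join(empty))
        comparator_sets = [(l, idx) for l, idx in comparator_sets if idx]

    target_idx = [i for i, is_t in enumerate(target_mask) if is_t]
    n_target = len(target_idx)
    tables: list[ContingencyTable] = []
    for comp_label, comp_idx in comparator_sets:
        n_comp = len(comp_idx)
        for group in event_dict.groups:
            a = sum(1 for i in target_idx if flags[i][group])
            c = sum(1 for i in comp_idx if flags[i][group])
            tables.append(ContingencyTable(
                a=a, b=n_target - a, c=c, d=n_comp - c,
                target=design.target, comparator=comp_label,
                event_group=group, design=design.label,
            ))
    return tables


# ---------------------------------------------------------------------------
# Dose-regimen classification (descriptive strata)
# ---------------------------------------------------------------------------

#: dose_freq code -> administrations per day
FREQ_PER_DAY = {
    "": 1.0, "QD": 1.0, "QOD": 0.5, "BID": 2.0, "TID": 3.0, "QID": 4.0,
    "Q12H": 2.0, "Q8H": 3.0, "Q6H": 4.0,
}

LOADING_DOSE_MG = 200.0
STANDARD_MAINTENANCE_MG = 100.0
HIGH_MAINTENANCE_MG = 200.0


def _target_entries(report: CaseReport, drug_dict: DrugDictionary, label: str,
                    roles: frozenset[str]) -> list[DrugEntry]:
    out = []
    for e in report.drugs:
        if e.role not in roles:
            continue
        if drug_dict.matches_name(label, e.name_raw) or (
                e.active_ingredient_raw
                and drug_dict.matches_name(label, e.active_ingredient_raw)):
            out.append(e)
    return out


def _daily_dose(entry: DrugEntry) -> float | None:
    if entry.dose_amount is None:
        return None
    if entry.dose_unit and entry.dose_unit.upper() != "MG":
        return None
    mult = FREQ_PER_DAY.get(entry.dose_freq.upper())
    if mult is None:
        logger.warning("unknown dose_freq %r treated as once daily",
                       entry.dose_freq)
        mult = 1.0
    return entry.dose_amount * mult


def classify_dose_regimen(report: CaseReport, drug_dict: DrugDictionary,
                          label: str,
                          roles: frozenset[str] = PRIMARY_SUSPECT,
                          ) -> tuple[bool | None, str | None]:
    """(loading, maintenance) classification of the target-drug regimen.

    Loading dose: any target-drug entry with a single dose of at least 200 mg
    whose therapy start is the earliest target-drug therapy date.  Maintenance
    class: modal daily dose across the remaining dosed entries — 'standard'
    at 100 mg/day, 'high' at 200 mg/day or more, otherwise None.  Returns
    ``(None, None)`` when no dose information is usable.
    """
    entries = _target_entries(report, drug_dict, label, roles)
    dosed = [e for e in entries if e.dose_amount is not None]
    if not dosed:
        return (None, None)
    starts = [e.therapy_start.sort_key() for e in dosed
              if e.therapy_start is not None]
    earliest = min(starts) if starts else None
    loading_entries = [
        e for e in dosed
        if e.dose_amount >= LOADING_DOSE_MG
        and e.therapy_start is not None
        and e.therapy_start.sort_key() == earliest
    ]
    loading = bool(loading_entries) if earliest is not None else False

    maintenance_pool = [e for e in dosed if e not in loading_entries]
    doses = [d for d in (_daily_dose(e) for e in maintenance_pool)
             if d is not None and d > 0]
    if not doses:
        return (loading, None)
    modal = max(sorted(set(doses)), key=doses.count)  # ties -> larger dose
    if modal >= HIGH_MAINTENANCE_MG:
        return (loading, "high")
    if modal == STANDARD_MAINTENANCE_MG:
        return (loading, "standard")
    return (loading, None)
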