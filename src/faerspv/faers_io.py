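"""Data model and readers/writers for FAERS quarterly ASCII tables.

The FDA Adverse Event Reporting System distributes each quarter as a set of
'$'-delimited ASCII files, one per table: DEMO (one row per report version),
DRUG, REAC, THER and OUTC (one row per drug entry / reaction / therapy episode
/ outcome code).  Reports are keyed by ``primaryid`` (a report *version*) and
``caseid`` (the underlying case, which may accumulate several versions over
time).  This module parses those tables verbatim into :class:`RawTables`,
writes them back bit-exactly, and joins the five tables into per-report
:class:`CaseReport` records with decoded demographics, outcomes and drug
entries.

Only the modern (post-2012Q4, primaryid/caseid-keyed) dialect is supported.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: mandatory columns per table (FAERS quarterly ASCII layout)
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "event_dt", "sex", "age", "age_cod",
             "occp_cod", "fda_dt"),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "prod_ai", "dose_amt", "dose_unit", "dose_freq"),
    "reac": ("primaryid", "caseid", "pt"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
}

TABLE_NAMES = tuple(REQUIRED_COLUMNS)

#: outc_cod -> canonical outcome label
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "DS": "disability",
    "HO": "hospitalization",
    "RI": "required_intervention",
    "OT": "other_serious",
}

#: occp_cod -> reporter class (physician, pharmacist, health professional and
#: "other health professional" count as healthcare; consumers and lawyers do not)
REPORTER_CLASSES = {
    "MD": "healthcare",
    "PH": "healthcare",
    "HP": "healthcare",
    "OT": "healthcare",
    "CN": "non_healthcare",
    "LW": "non_healthcare",
}

#: age_cod -> multiplicative factor converting the reported age to years
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

DRUG_ROLES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}


class FaersFormatError(ValueError):
    """Raised when a FAERS ASCII file violates the expected layout."""


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to day, month or year precision.

    FAERS date fields are digit strings of 8 (YYYYMMDD), 6 (YYYYMM) or 4
    (YYYY) characters.  The precision is retained explicitly so that
    day-level arithmetic (time-to-onset) can be restricted to day-precision
    dates rather than imputing missing components.
    """

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def to_date(self) -> datetime.date:
        """Exact :class:`datetime.date`; only valid at day precision."""
        if self.precision != "day":
            raise ValueError(f"date {self} has {self.precision} precision")
        return datetime.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Total order for versioning comparisons; missing parts sort first."""
        return (self.year, self.month or 0, self.day or 0)

    @classmethod
    def parse(cls, raw: str) -> "PartialDate | None":
        """Parse a FAERS digit-string date; None for blank/unparseable input."""
        raw = raw.strip()
        if not raw or not raw.isdigit():
            return None
        try:
            if len(raw) == 8:
                d = datetime.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
                return cls(d.year, d.month, d.day)
            if len(raw) == 6:
                y, m = int(raw[:4]), int(raw[4:6])
                if not 1 <= m <= 12:
                    return None
                return cls(y, m)
            if len(raw) == 4:
                return cls(int(raw))
        except ValueError:
            return None
        return None

    def format(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


# ---------------------------------------------------------------------------
# Raw tables
# ---------------------------------------------------------------------------

@dataclass
class RawTables:
    """The five FAERS quarterly tables as string-typed DataFrames.

    Invariants: ``primaryid`` is unique within ``demo``; every primaryid in
    drug/reac/ther/outc appears in demo; ``caseid`` may repeat across demo
    rows (report versions of the same case).
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame

    def __iter__(self):
        return iter((self.demo, self.drug, self.reac, self.ther, self.outc))

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> None:
        if self.demo["primaryid"].duplicated().any():
            dup = self.demo.loc[self.demo["primaryid"].duplicated(), "primaryid"].iloc[0]
            raise FaersFormatError(f"duplicate primaryid in demo: {dup}")
        demo_ids = set(self.demo["primaryid"])
        for name in ("drug", "reac", "ther", "outc"):
            ids = set(self.table(name)["primaryid"])
            orphans = ids - demo_ids
            if orphans:
                raise FaersFormatError(
                    f"{name} references primaryid(s) absent from demo: "
                    f"{sorted(orphans)[:5]}"
                )

    def equals(self, other: "RawTables") -> bool:
        return all(
            self.table(n).reset_index(drop=True).equals(
                other.table(n).reset_index(drop=True))
            for n in TABLE_NAMES
        )


def _parse_table(path: Path, name: str, delimiter: str) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file (no header)")
    header = lines[0].split(delimiter)
    for col in REQUIRED_COLUMNS[name]:
        if col not in header:
            raise FaersFormatError(f"{path}: missing mandatory column '{col}'")
    ncol = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(delimiter)
        if len(fields) != ncol:
            raise FaersFormatError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        rows.append(fields)
    return pd.DataFrame(rows, columns=header, dtype=str)


def read_quarter(paths: Mapping[str, Path] | str | Path,
                 delimiter: str = DELIMITER) -> RawTables:
    """Read one FAERS quarter from '$'-delimited ASCII files.

    Parameters
    ----------
    paths
        Either a mapping ``{"demo": path, "drug": path, ...}`` or a directory
        containing ``DEMO.txt``, ``DRUG.txt``, ``REAC.txt``, ``THER.txt`` and
        ``OUTC.txt`` (case-insensitive stems).
    delimiter
        Field separator; FAERS uses ``'$'``.

    All field values are preserved verbatim as text — no coercion beyond the
    line split.  Raises :class:`FaersFormatError` naming the column when a
    mandatory column is absent, or naming the line number when a row has an
    inconsistent field count.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        resolved: dict[str, Path] = {}
        for name in TABLE_NAMES:
            matches = [p for p in directory.iterdir()
                       if p.stem.lower() == name and p.suffix.lower() == ".txt"]
            if not matches:
                raise FileNotFoundError(f"no {name.upper()}.txt in {directory}")
            resolved[name] = matches[0]
        paths = resolved
    tables = {name: _parse_table(Path(paths[name]), name, delimiter)
              for name in TABLE_NAMES}
    result = RawTables(**tables)
    result.validate()
    return result


def write_quarter(tables: RawTables, directory: str | Path,
                  delimiter: str = DELIMITER) -> dict[str, Path]:
    """Write a quarter as '$'-delimited ASCII files (DEMO.txt, DRUG.txt, ...).

    ``read_quarter(write_quarter(t)) == t`` on field values.  Field values
    containing the delimiter are rejected — FAERS itself does not escape, so
    the bit-exact round-trip contract is only achievable by refusing them.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in TABLE_NAMES:
        df = tables.table(name)
        for col in df.columns:
            bad = df[col].str.contains(re.escape(delimiter), na=False)
            if bad.any():
                raise FaersFormatError(
                    f"{name}.{col}: value contains the field delimiter "
                    f"{delimiter!r}: {df.loc[bad, col].iloc[0]!r}"
                )
        path = directory / f"{name.upper()}.txt"
        lines = [delimiter.join(df.columns)]
        lines.extend(delimiter.join(row) for row in df.itertuples(index=False))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# Case reports
# ---------------------------------------------------------------------------

@dataclass
class DrugEntry:
    """One drug row of a report: names, role, dose and therapy start."""

    name_raw: str
    active_ingredient_raw: str
    role: str | None  # primary_suspect / secondary_suspect / concomitant / interacting
    dose_amount: float | None = None
    dose_unit: str = ""
    dose_freq: str = ""
    therapy_start: PartialDate | None = None


@dataclass
class CaseReport:
    """One safety report (a single primaryid; pre-deduplication).

    ``receipt_date`` is the FDA receipt date (fda_dt), the versioning key used
    to keep the latest report per case.  ``reactions`` holds the MedDRA
    preferred terms; a report must list at least one.
    """

    caseid: str
    primaryid: str
    receipt_date: PartialDate | None
    event_date: PartialDate | None
    sex: str  # 'M' / 'F' / 'missing'
    age_years: float | None
    reporter_class: str  # healthcare / non_healthcare / unknown
    year: int | None
    outcomes: frozenset[str]
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)


def convert_age(age_raw: str, age_cod: str) -> float | None:
    """Reported age + unit code -> age in years; None when unusable.

    Unknown unit codes and out-of-range results (outside [0, 150] years) are
    logged and treated as missing rather than raised — spontaneous-report data
    are dirty and a single bad row must not abort a quarter.
    """
    age_raw = age_raw.strip()
    if not age_raw:
        return None
    try:
        value = float(age_raw)
    except ValueError:
        logger.warning("unparseable age %r ignored", age_raw)
        return None
    code = age_cod.strip().upper()
    if code not in AGE_FACTORS:
        logger.warning("unknown age_cod %r ignored", age_cod)
        return None
    years = value * AGE_FACTORS[code]
    if not 0.0 <= years <= 150.0:
        logger.warning("implausible age %s %s (= %.2f yr) ignored",
                       age_raw, code, years)
        return None
    return years


def _decode_sex(raw: str) -> str:
    s = raw.strip().upper()
    return s if s in ("M", "F") else "missing"


def _decode_reporter(raw: str) -> str:
    return REPORTER_CLASSES.get(raw.strip().upper(), "unknown")


def _parse_dose(raw: str) -> float | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        logger.warning("unparseable dose_amt %r ignored", raw)
        return None


def assemble_reports(tables: RawTables) -> list[CaseReport]:
    """Join the five raw tables into one :class:`CaseReport` per demo row.

    Drugs are joined to therapy start dates on ``(primaryid, drug_seq)``;
    outcome and reporter codes are decoded (unknown codes are logged and
    skipped); ages are converted to years.  Demo rows with no reaction rows
    violate the report invariant and are dropped with a warning.
    """
    tables.validate()
    reac_by_id: dict[str, list[str]] = {}
    for row in tables.reac.itertuples(index=False):
        pt = row.pt.strip()
        if pt:
            reac_by_id.setdefault(row.primaryid, []).append(pt)

    outc_by_id: dict[str, set[str]] = {}
    for row in tables.outc.itertuples(index=False):
        code = row.outc_cod.strip().upper()
        if not code:
            continue
        if code not in OUTCOME_CODES:
            logger.warning("unknown outc_cod %r ignored (primaryid %s)",
                           row.outc_cod, row.primaryid)
            continue
        outc_by_id.setdefault(row.primaryid, set()).add(OUTCOME_CODES[code])

    ther_by_key: dict[tuple[str, str], PartialDate] = {}
    for row in tables.ther.itertuples(index=False):
        start = PartialDate.parse(row.start_dt)
        if start is not None:
            ther_by_key[(row.primaryid, row.dsg_drug_seq.strip())] = start

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for row in tables.drug.itertuples(index=False):
        role_code = row.role_cod.strip().upper()
        role = DRUG_ROLES.get(role_code)
        if role is None and role_code:
            logger.warning("unknown role_cod %r (primaryid %s)",
                           row.role_cod, row.primaryid)
        entry = DrugEntry(
            name_raw=row.drugname.strip(),
            active_ingredient_raw=row.prod_ai.strip(),
            role=role,
            dose_amount=_parse_dose(row.dose_amt),
            dose_unit=row.dose_unit.strip(),
            dose_freq=row.dose_freq.strip(),
            therapy_start=ther_by_key.get((row.primaryid, row.drug_seq.strip())),
        )
        drugs_by_id.setdefault(row.primaryid, []).append(entry)

    reports: list[CaseReport] = []
    dropped = 0
    for row in tables.demo.itertuples(index=False):
        pid = row.primaryid
        reactions = reac_by_id.get(pid, [])
        if not reactions:
            dropped += 1
            logger.warning("report %s has no reactions; dropped", pid)
            continue
        receipt = PartialDate.parse(row.fda_dt)
        reports.append(CaseReport(
            caseid=row.caseid,
            primaryid=pid,
            receipt_date=receipt,
            event_date=PartialDate.parse(row.event_dt),
            sex=_decode_sex(row.sex),
            age_years=convert_age(row.age, row.age_cod),
            reporter_class=_decode_reporter(row.occp_cod),
            year=receipt.year if receipt is not None else None,
            outcomes=frozenset(outc_by_id.get(pid, set())),
            drugs=drugs_by_id.get(pid, []),
            reactions=reactions,
        ))
    if dropped:
        logger.info("dropped %d reaction-less report(s) of %d",
                    dropped, len(tables.demo))
    return reports
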