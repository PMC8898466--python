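"""Reporting-odds-ratio disproportionality statistics.

The reporting odds ratio (ROR) compares, within a spontaneous-report
database, the odds that a report of the drug of interest lists a given event
against the same odds among comparator reports.  For the 2x2 table

    ==============  =======  ==========
                    event    other AEs
    ==============  =======  ==========
    drug            a        b
    comparator      c        d
    ==============  =======  ==========

the point estimate is ROR = (a*d)/(b*c), with the Woolf log-normal 95%
confidence interval exp(ln ROR +/- z*sqrt(1/a + 1/b + 1/c + 1/d)).  A signal
of disproportionate reporting is flagged when ROR >= 2.0 and the event count
a >= 3 — a screening threshold, not evidence of causation.

Zero cells make the ROR undefined; the default policy reports them as such,
and the optional Haldane–Anscombe correction adds 0.5 to all four cells
(flagged in the result).  No multiple-testing adjustment is applied; batch
results are screening statistics and should be read as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

#: standard-normal quantile at 0.975, fixed for the default 95% level
Z_95 = 1.959964

#: signal thresholds: ROR >= 2.0 with at least 3 cases
SIGNAL_ROR_THRESHOLD = 2.0
SIGNAL_MIN_CASES = 3


class UndefinedRORError(ValueError):
    """Raised when a zero cell makes the ROR undefined and no correction applies."""


@dataclass(frozen=True)
class ContingencyTable:
    """Case counts behind one (target, comparator, event group) comparison.

    a/b: target-drug reports with / without the event;
    c/d: comparator reports with / without the event.
    Counts are deduplicated cases, not report versions or PT rows.
    """

    a: int
    b: int
    c: int
    d: int
    target: str = ""
    comparator: str = ""
    event_group: str = ""
    design: str = ""

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"cell {cell} is negative")
        if self.a + self.b == 0:
            raise ValueError("empty target margin (a + b = 0)")
        if self.c + self.d == 0:
            raise ValueError("empty comparator margin (c + d = 0)")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalResult:
    """ROR, 95% CI, case count and signal flag for one contingency table."""

    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    is_signal: bool
    correction_applied: bool = False
    undefined: bool = False
    note: str = ""


def _corrected_cells(t: ContingencyTable, zero_cell: str) -> tuple[float, float, float, float]:
    a, b, c, d = t.cells()
    if min(a, b, c, d) > 0:
        return float(a), float(b), float(c), float(d)
    if zero_cell == "haldane":
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if zero_cell == "error":
        zero = next(name for name, v in zip("abcd", (a, b, c, d)) if v == 0)
        raise UndefinedRORError(
            f"cell {zero} is zero ({t.target} vs {t.comparator}, "
            f"{t.event_group}); ROR undefined without continuity correction"
        )
    raise ValueError(f"unknown zero-cell policy {zero_cell!r}")


def ror_estimate(t: ContingencyTable, zero_cell: str = "error") -> float:
    """Point estimate (a*d)/(b*c).

    ``zero_cell`` is ``'error'`` (raise :class:`UndefinedRORError` naming the
    zero cell) or ``'haldane'`` (+0.5 on all four cells).
    """
    a, b, c, d = _corrected_cells(t, zero_cell)
    return (a * d) / (b * c)


def ror_ci(t: ContingencyTable, level: float = 0.95,
           zero_cell: str = "error") -> tuple[float, float]:
    """Woolf log-normal confidence interval at ``level`` (default 95%)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a, b, c, d = _corrected_cells(t, zero_cell)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z_95 if level == 0.95 else float(norm.ppf((1 + level) / 2))
    return (point * math.exp(-z * se), point * math.exp(z * se))


def classify_signal(ror: float, n_cases: int) -> bool:
    """True iff ROR >= 2.0 and the event case count is at least 3."""
    if ror <= 0:
        raise ValueError("ror must be positive")
    return ror >= SIGNAL_ROR_THRESHOLD and n_cases >= SIGNAL_MIN_CASES


def evaluate_table(t: ContingencyTable, level: float = 0.95,
                   zero_cell: str = "error") -> SignalResult:
    """Evaluate one table; undefined RORs yield a flagged, non-raising result."""
    correction = zero_cell == "haldane" and min(t.cells()) == 0
    try:
        point = ror_estimate(t, zero_cell)
        low, high = ror_ci(t, level, zero_cell)
    except UndefinedRORError as err:
        return SignalResult(table=t, ror=math.nan, ci_low=math.nan,
                            ci_high=math.nan, n_cases=t.a, is_signal=False,
                            undefined=True, note=str(err))
    return SignalResult(
        table=t, ror=point, ci_low=low, ci_high=high, n_cases=t.a,
        is_signal=classify_signal(point, t.a),
        correction_applied=correction,
    )


def evaluate_designs(tables: Iterable[ContingencyTable], level: float = 0.95,
                     zero_cell: str = "error") -> list[SignalResult]:
    """Batch-evaluate tables in deterministic (design, comparator, event) order.

    Undefined RORs (zero cell under the ``'error'`` policy) are marked in the
    result rather than aborting the batch.
    """
    ordered = sorted(tables, key=lambda t: (t.design, t.target, t.comparator,
                                            t.event_group))
    return [evaluate_table(t, level, zero_cell) for t in ordered]


def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Forest-plot table: one row per result, ready for CSV/JSON export."""
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "design": t.design, "target": t.target, "comparator": t.comparator,
            "event_group": t.event_group,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "n_cases": r.n_cases, "is_signal": r.is_signal,
            "correction_applied": r.correction_applied,
            "undefined": r.undefined,
        })
    return pd.DataFrame(rows)
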