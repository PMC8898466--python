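"""Synthetic FAERS generator with plantable reporting-odds-ratio effects.

Generates quarterly-ASCII-shaped spontaneous-report data whose statistical
structure mirrors a real pharmacovigilance corpus: a large background of
reports for uninteresting drugs, one arm per drug of interest with
configurable per-event-group reporting probabilities, demographics and
outcome codes drawn from a configurable mix, therapy-start/event-date pairs
whose gap follows a configurable onset distribution, case duplicates (same
caseid, new primaryid, later receipt date — the situation deduplication must
resolve), and month-precision partial dates.

Event-group draws are independent across groups within a report; a group hit
emits one uniformly chosen preferred term from that group's dictionary, on
top of 1–3 background PTs every report carries.  The *umbrella* event-group
probability is therefore implied: 1 - prod(1 - p_g) over all configured
groups.  :func:`true_ror` turns configured probabilities into the ROR a
correct pipeline should recover, which makes parameter-recovery tests exact.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical configs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import EventDictionary, default_event_dictionary
from .faers_io import RawTables, REQUIRED_COLUMNS

BACKGROUND_ARM = "background"
FULL_DATABASE = "full_database"

#: reaction PTs for the non-event background noise (disjoint from the
#: bundled coagulation dictionary)
BACKGROUND_PTS = (
    "Nausea", "Vomiting", "Diarrhoea", "Pyrexia", "Headache", "Rash",
    "Dizziness", "Pruritus", "Abdominal pain", "Fatigue", "Dyspnoea",
    "Hepatic enzyme increased", "Renal impairment", "Hypotension",
    "Anaemia", "Constipation", "Insomnia", "Oedema peripheral",
    "Drug ineffective", "Hypersensitivity", "Tachycardia", "Confusional state",
)

#: invented primary-suspect drug names for background reports
BACKGROUND_DRUGS = tuple(f"BACKGRODINE-{i:02d}" for i in range(1, 21))


class ConfigError(ValueError):
    """Raised when a simulation config is incoherent, before any generation."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetDistribution:
    """Time from therapy start to event, in days.

    ``gamma`` (shape, scale) is the default — right-skewed onset is the
    standard pharmacovigilance assumption; ``lognormal`` (mu, sigma) and
    ``exponential`` (scale,) are available.  Samples are rounded to whole
    days and floored at 0.
    """

    family: str = "gamma"
    params: tuple[float, ...] = (4.78, 2.18)  # median ~10 d, IQR ~6.9-13.1 d

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "gamma":
            shape, scale = self.params
            draws = rng.gamma(shape, scale, size=n)
        elif self.family == "lognormal":
            mu, sigma = self.params
            draws = rng.lognormal(mu, sigma, size=n)
        elif self.family == "exponential":
            (scale,) = self.params
            draws = rng.exponential(scale, size=n)
        else:
            raise ConfigError(f"unknown onset family {self.family!r}")
        return np.maximum(np.rint(draws), 0).astype(int)


@dataclass(frozen=True)
class DemographicMix:
    """Marginal mixes for sex, age, reporter class and outcome codes.

    Fractions within one mix may sum to less than 1; the remainder is the
    missing/unknown category.  Outcome draws are independent per code, so one
    report can carry several outcomes (as in FAERS) or none.
    """

    male_fraction: float = 0.45
    female_fraction: float = 0.40
    age_missing_fraction: float = 0.25
    elderly_fraction: float = 0.35  # of reports with a known age
    healthcare_fraction: float = 0.60
    non_healthcare_fraction: float = 0.36
    outcome_probabilities: Mapping[str, float] = field(default_factory=lambda: {
        "death": 0.22, "life_threatening": 0.06, "disability": 0.012,
        "hospitalization": 0.21, "other_serious": 0.34,
        "required_intervention": 0.004,
    })

    def validate(self) -> None:
        pairs = [("sex", self.male_fraction + self.female_fraction),
                 ("reporter", self.healthcare_fraction
                  + self.non_healthcare_fraction)]
        for name, total in pairs:
            if not 0.0 <= total <= 1.0:
                raise ConfigError(f"{name} fractions sum to {total}, not in [0,1]")
        for name, p in [("age_missing_fraction", self.age_missing_fraction),
                        ("elderly_fraction", self.elderly_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} not in [0,1]")
        for code, p in self.outcome_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"outcome probability {code}={p} not in [0,1]")


@dataclass(frozen=True)
class DoseMix:
    """Dose-regimen mix for an arm that carries dose information.

    A loading report starts with a 200 mg single dose on therapy day 0 and
    continues with the maintenance regimen from day 1; a non-loading report
    runs the maintenance regimen from day 0.  Maintenance is 50 mg twice
    daily (standard, 100 mg/day) or 100 mg twice daily (high, 200 mg/day).
    """

    loading_fraction: float = 0.19   # ~28/149 of classifiable cases
    high_maintenance_fraction: float = 0.23  # ~34/145

    def validate(self) -> None:
        for name, p in [("loading_fraction", self.loading_fraction),
                        ("high_maintenance_fraction",
                         self.high_maintenance_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} not in [0,1]")


@dataclass(frozen=True)
class DrugSpec:
    """One drug-of-interest arm: size, names, and planted event probabilities.

    ``event_group_probabilities`` maps event-dictionary groups to per-report
    reporting probabilities; a key equal to the umbrella group plants
    umbrella-only PTs (coagulation events outside every named subgroup).
    """

    label: str
    name_variants: tuple[str, ...]
    n_reports: int
    event_group_probabilities: Mapping[str, float]
    dose_mix: DoseMix | None = None
    onset: OnsetDistribution = OnsetDistribution()

    def validate(self) -> None:
        if not self.name_variants:
            raise ConfigError(f"{self.label}: no name variants")
        if self.n_reports < 0:
            raise ConfigError(f"{self.label}: negative n_reports")
        for group, p in self.event_group_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"{self.label}: probability {group}={p} not in [0,1]")
        if self.dose_mix is not None:
            self.dose_mix.validate()


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_background_reports: int = 30_000
    drug_specs: tuple[DrugSpec, ...] = ()
    background_event_probabilities: Mapping[str, float] = field(
        default_factory=dict)
    demographics: DemographicMix = DemographicMix()
    date_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2005, 1, 1), datetime.date(2020, 12, 31))
    duplicate_fraction: float = 0.05
    partial_date_fraction: float = 0.10
    background_onset: OnsetDistribution = OnsetDistribution()

    def validate(self) -> None:
        if self.n_background_reports < 0:
            raise ConfigError("negative n_background_reports")
        for name, p in [("duplicate_fraction", self.duplicate_fraction),
                        ("partial_date_fraction", self.partial_date_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} not in [0,1]")
        for group, p in self.background_event_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"background probability {group}={p} "
                                  "not in [0,1]")
        start, end = self.date_window
        if end <= start:
            raise ConfigError("empty date window")
        if (end - start).days < 180:
            raise ConfigError("date window shorter than 180 days")
        labels = [s.label for s in self.drug_specs]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate drug labels")
        if BACKGROUND_ARM in labels:
            raise ConfigError(f"{BACKGROUND_ARM!r} is a reserved arm label")
        for spec in self.drug_specs:
            spec.validate()
        self.demographics.validate()

    def arm_probabilities(self, arm: str) -> Mapping[str, float]:
        if arm == BACKGROUND_ARM:
            return self.background_event_probabilities
        for spec in self.drug_specs:
            if spec.label == arm:
                return spec.event_group_probabilities
        raise KeyError(f"unknown arm {arm!r}")

    def arm_size(self, arm: str) -> int:
        if arm == BACKGROUND_ARM:
            return self.n_background_reports
        for spec in self.drug_specs:
            if spec.label == arm:
                return spec.n_reports
        raise KeyError(f"unknown arm {arm!r}")

    @property
    def arms(self) -> list[str]:
        return [BACKGROUND_ARM] + [s.label for s in self.drug_specs]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def umbrella_probability(probs: Mapping[str, float]) -> float:
    """Implied any-group probability: 1 - prod(1 - p_g) (independent draws)."""
    prod = 1.0
    for p in probs.values():
        prod *= 1.0 - p
    return 1.0 - prod


def _odds(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ConfigError(f"probability {p} yields undefined odds")
    return p / (1.0 - p)


def group_probability(config: SimulationConfig, arm: str, event_group: str,
                      umbrella: str = "coagulation_dysfunction") -> float:
    """Configured (or, for the umbrella group, implied) event probability."""
    probs = config.arm_probabilities(arm)
    if event_group == umbrella:
        return umbrella_probability(probs)
    return float(probs.get(event_group, 0.0))


def true_ror(config: SimulationConfig, drug: str, event_group: str,
             comparator: str = BACKGROUND_ARM,
             umbrella: str = "coagulation_dysfunction") -> float:
    """The planted ROR: odds(p_drug) / odds(p_comparator).

    ``comparator`` is an arm label, ``'background'``, or ``'full_database'``
    (the report-count-weighted mixture of every arm except ``drug``, which is
    what the pipeline's full-database comparator sees in expectation).
    """
    p_d = group_probability(config, drug, event_group, umbrella)
    if comparator == FULL_DATABASE:
        num = 0.0
        den = 0
        for arm in config.arms:
            if arm == drug:
                continue
            n = config.arm_size(arm)
            num += n * group_probability(config, arm, event_group, umbrella)
            den += n
        if den == 0:
            raise ConfigError("full-database comparator is empty")
        p_c = num / den
    else:
        p_c = group_probability(config, comparator, event_group, umbrella)
    return _odds(p_d) / _odds(p_c)


@dataclass
class GroundTruth:
    """Generator bookkeeping: planted probabilities plus realized counts.

    ``arm_cases`` is the number of distinct cases per arm (duplicates add
    report versions, never cases); ``event_cases[arm][group]`` counts the
    cases whose report realized at least one PT of the group (umbrella
    included), i.e. exactly what a correct pipeline should count after
    deduplication.
    """

    config: SimulationConfig
    arm_cases: dict[str, int]
    event_cases: dict[str, dict[str, int]]

    def true_ror(self, drug: str, event_group: str,
                 comparator: str = BACKGROUND_ARM) -> float:
        return true_ror(self.config, drug, event_group, comparator)

    @property
    def n_cases_total(self) -> int:
        return sum(self.arm_cases.values())


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, options: Sequence[str], n: int) -> np.ndarray:
    idx = rng.integers(0, len(options), size=n)
    return np.asarray(options, dtype=object)[idx]


def _sample_sex(rng, mix: DemographicMix, n: int) -> np.ndarray:
    u = rng.random(n)
    out = np.full(n, "", dtype=object)
    out[u < mix.male_fraction] = "M"
    mask_f = (u >= mix.male_fraction) & (
        u < mix.male_fraction + mix.female_fraction)
    out[mask_f] = "F"
    return out


def _sample_reporter(rng, mix: DemographicMix, n: int) -> np.ndarray:
    u = rng.random(n)
    out = np.full(n, "", dtype=object)
    hc = u < mix.healthcare_fraction
    nh = (~hc) & (u < mix.healthcare_fraction + mix.non_healthcare_fraction)
    out[hc] = _choice(rng, ("MD", "PH", "HP", "OT"), int(hc.sum()))
    out[nh] = _choice(rng, ("CN", "LW"), int(nh.sum()))
    return out


def _sample_age(rng, mix: DemographicMix, n: int) -> np.ndarray:
    known = rng.random(n) >= mix.age_missing_fraction
    elderly = rng.random(n) < mix.elderly_fraction
    ages = np.where(elderly, rng.integers(65, 95, size=n),
                    rng.integers(18, 65, size=n))
    out = np.full(n, "", dtype=object)
    out[known] = ages[known].astype(str)
    return out


@dataclass
class _ArmPlan:
    label: str
    n: int
    names: tuple[str, ...]
    probs: Mapping[str, float]
    dose_mix: DoseMix | None
    onset: OnsetDistribution


def simulate(config: SimulationConfig,
             event_dict: EventDictionary | None = None,
             ) -> tuple[RawTables, GroundTruth]:
    """Generate one FAERS-shaped dataset.

    Deterministic given the config (the seed lives inside it).  Returns the
    five raw tables plus :class:`GroundTruth` bookkeeping for
    parameter-recovery and counting oracles.
    """
    config.validate()
    if event_dict is None:
        event_dict = default_event_dictionary()
    umbrella = event_dict.umbrella
    known_groups = set(event_dict.groups)
    for arm in config.arms:
        unknown = set(config.arm_probabilities(arm)) - known_groups
        if unknown:
            raise ConfigError(f"{arm}: probabilities for unknown event "
                              f"group(s) {sorted(unknown)}")

    # PT pools per configurable group; the umbrella key plants umbrella-only PTs
    pt_pool: dict[str, tuple[str, ...]] = {
        g: tuple(event_dict.terms[g]) for g in event_dict.subgroups}
    extras = tuple(event_dict.umbrella_only_terms())
    if extras:
        pt_pool[umbrella] = extras

    rng = np.random.default_rng(config.seed)
    mix = config.demographics
    window_start, window_end = config.date_window
    start_lo = window_start.toordinal()
    start_hi = window_end.toordinal() - 120  # leave room for onset + receipt lag

    plans = [_ArmPlan(BACKGROUND_ARM, config.n_background_reports,
                      BACKGROUND_DRUGS, config.background_event_probabilities,
                      None, config.background_onset)]
    plans += [_ArmPlan(s.label, s.n_reports, s.name_variants,
                       s.event_group_probabilities, s.dose_mix, s.onset)
              for s in config.drug_specs]

    demo_rows: list[list[str]] = []
    drug_rows: list[list[str]] = []
    reac_rows: list[list[str]] = []
    ther_rows: list[list[str]] = []
    outc_rows: list[list[str]] = []
    # rows per primaryid for duplicate emission
    payload: dict[str, dict[str, list[list[str]]]] = {}

    arm_cases: dict[str, int] = {}
    event_cases: dict[str, dict[str, int]] = {}
    all_pids: list[str] = []
    receipt_ord_by_pid: dict[str, int] = {}
    caseid_by_pid: dict[str, str] = {}
    demo_row_by_pid: dict[str, list[str]] = {}

    next_case = 30_000_001
    outcome_codes = {"death": "DE", "life_threatening": "LT",
                     "disability": "DS", "hospitalization": "HO",
                     "required_intervention": "RI", "other_serious": "OT"}

    for plan in plans:
        n = plan.n
        arm_cases[plan.label] = n
        counts = {g: 0 for g in event_dict.groups}
        if n == 0:
            event_cases[plan.label] = counts
            continue
        caseids = [str(next_case + i) for i in range(n)]
        next_case += n

        sex = _sample_sex(rng, mix, n)
        age = _sample_age(rng, mix, n)
        occp = _sample_reporter(rng, mix, n)
        starts = rng.integers(start_lo, start_hi + 1, size=n)
        onsets = plan.onset.sample(rng, n)
        event_ord = starts + onsets
        receipt_ord = event_ord + rng.integers(1, 61, size=n)
        partial = rng.random(n) < config.partial_date_fraction

        names = _choice(rng, plan.names, n)
        # event-group hits: independent Bernoulli per configured group
        hits: dict[str, np.ndarray] = {}
        for group, p in plan.probs.items():
            if group not in pt_pool:
                raise ConfigError(
                    f"{plan.label}: group {group!r} has no plantable PTs")
            hits[group] = rng.random(n) < p
        n_bg_pts = rng.integers(1, 4, size=n)
        outcome_draws = {code: rng.random(n) < p for code, p in
                         ((outcome_codes[k], v) for k, v in
                          mix.outcome_probabilities.items())}
        if plan.dose_mix is not None:
            loading = rng.random(n) < plan.dose_mix.loading_fraction
            high = rng.random(n) < plan.dose_mix.high_maintenance_fraction
        else:
            loading = high = np.zeros(n, dtype=bool)

        for i in range(n):
            cid = caseids[i]
            pid = cid + "1"
            all_pids.append(pid)
            caseid_by_pid[pid] = cid
            receipt_ord_by_pid[pid] = int(receipt_ord[i])
            event_date = datetime.date.fromordinal(int(event_ord[i]))
            event_dt = (f"{event_date.year:04d}{event_date.month:02d}"
                        if partial[i] else event_date.strftime("%Y%m%d"))
            fda_dt = datetime.date.fromordinal(
                int(receipt_ord[i])).strftime("%Y%m%d")
            d_rows: list[list[str]] = []
            t_rows: list[list[str]] = []
            start_date = datetime.date.fromordinal(int(starts[i]))
            start_dt = start_date.strftime("%Y%m%d")
            if plan.dose_mix is not None:
                maint_amt = "100" if high[i] else "50"  # BID -> 200 / 100 mg/day
                seq = 1
                if loading[i]:
                    d_rows.append([pid, cid, str(seq), "PS", names[i], "",
                                   "200", "MG", "QD"])
                    t_rows.append([pid, cid, str(seq), start_dt])
                    seq += 1
                    maint_start = (start_date
                                   + datetime.timedelta(days=1)).strftime("%Y%m%d")
                else:
                    maint_start = start_dt
                d_rows.append([pid, cid, str(seq), "PS", names[i], "",
                               maint_amt, "MG", "BID"])
                t_rows.append([pid, cid, str(seq), maint_start])
            else:
                d_rows.append([pid, cid, "1", "PS", names[i], "", "", "", ""])
                t_rows.append([pid, cid, "1", start_dt])
            # occasional concomitant drug, no therapy row
            if rng.random() < 0.3:
                conc = BACKGROUND_DRUGS[int(rng.integers(len(BACKGROUND_DRUGS)))]
                d_rows.append([pid, cid, str(len(d_rows) + 1), "C", conc,
                               "", "", "", ""])

            r_rows: list[list[str]] = []
            any_hit = False
            for group, mask in hits.items():
                if mask[i]:
                    counts[group] += 1
                    any_hit = True
                    pool = pt_pool[group]
                    r_rows.append([pid, cid,
                                   pool[int(rng.integers(len(pool)))]])
            if any_hit:
                counts[umbrella] += 1
            for _ in range(int(n_bg_pts[i])):
                r_rows.append([pid, cid, BACKGROUND_PTS[
                    int(rng.integers(len(BACKGROUND_PTS)))]])

            o_rows = [[pid, cid, code] for code, mask in outcome_draws.items()
                      if mask[i]]

            demo_row = [pid, cid, event_dt, str(sex[i]), str(age[i]),
                        "YR" if age[i] else "", str(occp[i]), fda_dt]
            demo_rows.append(demo_row)
            demo_row_by_pid[pid] = demo_row
            drug_rows.extend(d_rows)
            reac_rows.extend(r_rows)
            ther_rows.extend(t_rows)
            outc_rows.extend(o_rows)
            payload[pid] = {"drug": d_rows, "reac": r_rows, "ther": t_rows,
                            "outc": o_rows}
        event_cases[plan.label] = counts

    # duplicates: re-emit the payload under a new primaryid, strictly later
    # receipt date, identical everything else
    if config.duplicate_fraction > 0 and all_pids:
        dup_mask = rng.random(len(all_pids)) < config.duplicate_fraction
        lags = rng.integers(1, 31, size=len(all_pids))
        for j, pid in enumerate(all_pids):
            if not dup_mask[j]:
                continue
            cid = caseid_by_pid[pid]
            new_pid = cid + "2"
            new_receipt = datetime.date.fromordinal(
                receipt_ord_by_pid[pid] + int(lags[j])).strftime("%Y%m%d")
            row = list(demo_row_by_pid[pid])
            row[0] = new_pid
            row[7] = new_receipt
            demo_rows.append(row)
            for table, rows in payload[pid].items():
                dest = {"drug": drug_rows, "reac": reac_rows,
                        "ther": ther_rows, "outc": outc_rows}[table]
                for r in rows:
                    dest.append([new_pid] + r[1:])

    def frame(name: str, rows: list[list[str]]) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[name]),
                            dtype=str)

    tables = RawTables(
        demo=frame("demo", demo_rows), drug=frame("drug", drug_rows),
        reac=frame("reac", reac_rows), ther=frame("ther", ther_rows),
        outc=frame("outc", outc_rows),
    )
    truth = GroundTruth(config=config, arm_cases=arm_cases,
                        event_cases=event_cases)
    return tables, truth


# ---------------------------------------------------------------------------
# Default configurations
# ---------------------------------------------------------------------------

def scale_group_probabilities(base: Mapping[str, float],
                              target_umbrella: float) -> dict[str, float]:
    """Rescale per-group probabilities so the implied umbrella probability
    equals ``target_umbrella`` (solves for the common scale factor)."""
    if not 0.0 < target_umbrella < 1.0:
        raise ConfigError("target umbrella probability must be in (0,1)")

    def gap(s: float) -> float:
        return umbrella_probability({g: min(s * p, 1.0)
                                     for g, p in base.items()}) - target_umbrella

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ConfigError("cannot reach requested umbrella probability")
    s = brentq(gap, 0.0, hi)
    return {g: min(s * p, 1.0) for g, p in base.items()}


# Target-arm per-group reporting probabilities.  The umbrella total is 0.147
# (the observed 223/1517 event fraction); the split across subgroups is
# thrombocytopenia-dominant with a thin tail, plus a sliver of umbrella-only
# coagulation PTs.
_TARGET_PROBS = {
    "thrombocytopenia": 0.068,
    "hypofibrinogenaemia": 0.033,
    "coagulopathy": 0.024,
    "aptt_prolonged": 0.011,
    "inr_increased": 0.0075,
    "pt_prolonged": 0.011,
    "coagulation_dysfunction": 0.00105,  # umbrella-only extras
}

#: planted full-database RORs per subgroup and overall (the signal strengths
#: the pipeline should recover)
_PLANTED_FULLDB_ROR = {
    "thrombocytopenia": 8.21,
    "hypofibrinogenaemia": 705.41,
    "coagulopathy": 30.67,
    "aptt_prolonged": 42.98,
    "inr_increased": 4.67,
    "pt_prolonged": 27.99,
}
_PLANTED_FULLDB_ROR_OVERALL = 3.55

#: planted pairwise (target vs comparator drug) overall RORs
_PLANTED_COMPARATOR_ROR = {
    "vancomycin": 2.74,
    "linezolid": 0.82,
    "daptomycin": 3.08,
    "meropenem": 1.18,
    "imipenem_cilastatin": 1.83,
    "cefoperazone": 0.65,
}

_COMPARATOR_NAMES = {
    "vancomycin": ("VANCOMYCIN", "VANCOCIN", "VANCOMYCIN HCL"),
    "linezolid": ("LINEZOLID", "ZYVOX"),
    "daptomycin": ("DAPTOMYCIN", "CUBICIN"),
    "meropenem": ("MEROPENEM", "MERREM"),
    "imipenem_cilastatin": ("IMIPENEM AND CILASTATIN", "PRIMAXIN"),
    "cefoperazone": ("CEFOPERAZONE", "SULPERAZON"),
}

# comparator arms stay a small fraction of the corpus, as in the real
# database, so the full-database mixture is background-dominated
_COMPARATOR_SIZES = {
    "vancomycin": 1200, "linezolid": 1000, "daptomycin": 600,
    "meropenem": 500, "imipenem_cilastatin": 300, "cefoperazone": 200,
}
_N_BACKGROUND = 50_000
_N_TARGET = 1517


def _inverse_odds(odds: float) -> float:
    return odds / (1.0 + odds)


def _calibrate_background(umbrella: str = "coagulation_dysfunction",
                          ) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Solve background and comparator probabilities so every planted ROR
    holds against the quantity the pipeline actually measures.

    Pairwise comparator RORs fix each comparator arm's umbrella probability
    directly (target odds / planted ROR); within an arm the umbrella is
    reached by raising thrombocytopenia — the class effect of these
    antibiotics — above the background base.  Full-database RORs are enforced
    against the report-weighted mixture of background + comparator arms, so
    the background per-group probabilities are the solution of a small fixed
    point (comparator compositions depend on the background base and vice
    versa); a handful of iterations converges to machine precision.
    """
    subgroups = list(_PLANTED_FULLDB_ROR)
    odds_t = {g: _odds(_TARGET_PROBS[g]) for g in subgroups}
    u_target = umbrella_probability(_TARGET_PROBS)
    # what the full-database mixture must equal, per group and overall
    m_needed = {g: _inverse_odds(odds_t[g] / _PLANTED_FULLDB_ROR[g])
                for g in subgroups}
    m_umbrella = _inverse_odds(_odds(u_target) / _PLANTED_FULLDB_ROR_OVERALL)
    u_comp = {label: _inverse_odds(_odds(u_target) / ror)
              for label, ror in _PLANTED_COMPARATOR_ROR.items()}

    n_mix = _N_BACKGROUND + sum(_COMPARATOR_SIZES.values())
    bg = dict(m_needed)  # starting point: mixture == background
    comp: dict[str, dict[str, float]] = {}
    for _ in range(20):
        base_other = {g: bg[g] for g in subgroups if g != "thrombocytopenia"}
        prod_other = 1.0
        for p in base_other.values():
            prod_other *= 1.0 - p
        comp = {}
        for label, u in u_comp.items():
            p_thromb = 1.0 - (1.0 - u) / prod_other
            if p_thromb <= 0:
                raise ConfigError(f"{label}: umbrella target {u} below the "
                                  "background base rate")
            comp[label] = {**base_other, "thrombocytopenia": p_thromb}
        new_bg = {}
        for g in subgroups:
            comp_events = sum(_COMPARATOR_SIZES[l] * comp[l][g] for l in comp)
            p = (n_mix * m_needed[g] - comp_events) / _N_BACKGROUND
            if p <= 0:
                raise ConfigError(f"planted full-database ROR for {g} is "
                                  "infeasible at these arm sizes")
            new_bg[g] = p
        # umbrella-only sliver so the mixture umbrella also lands on target
        comp_u = sum(_COMPARATOR_SIZES[l] * umbrella_probability(comp[l])
                     for l in comp)
        u_bg = (n_mix * m_umbrella - comp_u) / _N_BACKGROUND
        prod_six = 1.0
        for p in new_bg.values():
            prod_six *= 1.0 - p
        extra = 1.0 - (1.0 - u_bg) / prod_six
        if extra < 0:
            raise ConfigError("planted overall full-database ROR infeasible")
        new_bg[umbrella] = extra
        if max(abs(new_bg[g] - bg.get(g, 0.0)) for g in new_bg) < 1e-12:
            bg = new_bg
            break
        bg = new_bg
    return bg, comp


def default_config(seed: int, scale: float = 1.0) -> SimulationConfig:
    """The study-condition corpus: one tigecycline arm of 1517 reports with a
    planted overall coagulation-dysfunction ROR of 3.55 against the full
    database (background 50,000 reports plus six small comparator-antibiotic
    arms), per-subgroup full-database RORs of 8.21/705.41/30.67/42.98/4.67/
    27.99, pairwise comparator RORs of 2.74/0.82/3.08/1.18/1.83/0.65, 5%
    case duplicates and 10% month-precision event dates over a 2005-2020
    window.

    ``scale`` multiplies every arm size (for smaller smoke-test corpora);
    planted RORs are scale-invariant.
    """
    bg_probs, comp_probs = _calibrate_background()
    specs = [DrugSpec(
        label="tigecycline",
        name_variants=("TIGECYCLINE", "TYGACIL", "TIGECYCLINE 50MG VIAL"),
        n_reports=max(2, round(_N_TARGET * scale)),
        event_group_probabilities=_TARGET_PROBS,
        dose_mix=DoseMix(),
    )]
    for label, probs in comp_probs.items():
        specs.append(DrugSpec(
            label=label,
            name_variants=_COMPARATOR_NAMES[label],
            n_reports=max(2, round(_COMPARATOR_SIZES[label] * scale)),
            event_group_probabilities=probs,
        ))
    return SimulationConfig(
        seed=seed,
        n_background_reports=max(10, round(_N_BACKGROUND * scale)),
        drug_specs=tuple(specs),
        background_event_probabilities=bg_probs,
    )


def calibration_config(seed: int, n_per_arm: int = 5000,
                       planted_ror: float = 3.5,
                       p_background: float = 0.05) -> SimulationConfig:
    """Minimal two-arm corpus for parameter-recovery checks.

    One drug arm vs background only, a single event group, no duplicates and
    no partial dates; the drug-arm probability is set so the planted ROR is
    exactly ``planted_ror``.
    """
    odds_d = _odds(p_background) * planted_ror
    p_drug = odds_d / (1.0 + odds_d)
    spec = DrugSpec(
        label="drug_a", name_variants=("DRUG-A",), n_reports=n_per_arm,
        event_group_probabilities={"thrombocytopenia": p_drug},
    )
    return SimulationConfig(
        seed=seed, n_background_reports=n_per_arm, drug_specs=(spec,),
        background_event_probabilities={"thrombocytopenia": p_background},
        duplicate_fraction=0.0, partial_date_fraction=0.0,
    )


# ---------------------------------------------------------------------------
# Declarative config (YAML/dict) support
# ---------------------------------------------------------------------------

def config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (YAML-friendly).

    Recognised keys mirror the dataclass fields; ``drug_specs`` is a list of
    mappings, ``date_window`` a pair of ISO dates, ``onset`` / dose mixes
    nested mappings.  Unknown keys raise :class:`ConfigError`.
    """
    def build(cls, payload: Mapping, converters: Mapping = {}):
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - names
        if unknown:
            raise ConfigError(f"{cls.__name__}: unknown key(s) {sorted(unknown)}")
        kwargs = {}
        for key, value in payload.items():
            conv = converters.get(key)
            kwargs[key] = conv(value) if conv else value
        try:
            return cls(**kwargs)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    def onset_conv(v):
        return build(OnsetDistribution,
                     {**v, "params": tuple(v.get("params", (4.78, 2.18)))})

    def spec_conv(v):
        return build(DrugSpec, v, {
            "name_variants": tuple, "onset": onset_conv,
            "dose_mix": lambda d: build(DoseMix, d) if d else None,
        })

    return build(SimulationConfig, data, {
        "drug_specs": lambda specs: tuple(spec_conv(s) for s in specs),
        "demographics": lambda d: build(DemographicMix, d),
        "date_window": lambda w: tuple(datetime.date.fromisoformat(x)
                                       for x in w),
        "background_onset": onset_conv,
    })
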