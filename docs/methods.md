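# Methods

## Scope and data model

`faerspv` implements case/non-case disproportionality analysis on
FAERS-format spontaneous reports.  Only the modern quarterly-ASCII dialect
(post-2012Q4, `primaryid`/`caseid` keys) is supported: one consistent data
model keeps every stage testable, and the synthetic generator emits the same
layout.  Field values are carried verbatim as text at the I/O layer; all
decoding (outcome codes, reporter classes, age units, dates) happens during
report assembly, where unknown codes are logged and skipped rather than
fatal — spontaneous-report data are dirty and a single malformed row must
not abort a quarter.  Because FAERS itself does not escape its `'$'`
delimiter, writing a value containing `'$'` is rejected outright; this is
what makes `read ∘ write` bit-exact.

Dates keep an explicit precision flag (day / month / year, from
YYYYMMDD/YYYYMM/YYYY digit strings).  Day-level arithmetic — time to onset —
uses day-precision dates only; month- or year-precision dates are excluded
and tallied rather than imputed, avoiding an imputation bias that nothing in
the analysis could correct for.

## Deduplication

A FAERS case accumulates report versions.  For each `caseid` exactly the
version with the latest FDA receipt date survives; ties break to the
greatest `primaryid` (numeric order on digit strings).  The operation is
idempotent, and all downstream counting is at case level: one deduplicated
case contributes at most one count to any contingency cell, however many
matching PTs or drug entries it carries (this matches the "number of cases"
semantics of the signal criterion).

## Drug and event matching

Drugs of interest are matched as **primary suspect** by default.  Name
matching is case-insensitive, whitespace-normalized, word-boundary substring
against both the verbatim drug name and the active-ingredient field: FAERS
free-text names carry dose/form suffixes ("TIGECYCLINE 50MG VIAL"), so exact
matching would silently lose cases, while unanchored substring matching
would cross word boundaries.  Event groups are sets of MedDRA preferred
terms matched case-insensitively and exactly; the umbrella group
(`coagulation_dysfunction`) must contain every subgroup PT, which makes the
umbrella flag monotone in the subgroup flags.  The bundled dictionaries are
best-effort defaults and fully user-replaceable.

## Comparison designs

Four designs are built in: full database; anti-MRSA drugs (vancomycin,
linezolid, daptomycin); anti-ESBL carbapenems (meropenem,
imipenem-cilastatin); and NMTT-side-chain cephalosporins (cefoperazone).
The full-database comparator **excludes** the target drug's own reports —
the conservative case/non-case convention; it is configurable.  A report
qualifying for both the target and a comparator drug is assigned to the
target only, preventing double counting.  Drug-set designs run pooled or
per-drug; per-drug cells sum to the pooled cells when the comparator cohorts
are disjoint.  Comparator drugs with no reports in the corpus are skipped
with a warning rather than producing degenerate tables.

## The ROR and its interval

For a 2×2 table (a, b; c, d), ROR = (a·d)/(b·c) with the Woolf log-normal
interval exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)) — the de-facto standard
interval in ROR-based pharmacovigilance.  The 95% z-quantile is fixed at
1.959964.  A signal is ROR ≥ 2.0 with a ≥ 3 cases (inclusive thresholds).
Zero cells: the default policy reports the table as undefined (batch
evaluation marks and continues); the optional Haldane–Anscombe correction
adds 0.5 to all four cells and flags the result.  No multiple-testing
adjustment is applied across the batch — results are screening statistics,
and this is a deliberate, documented limitation.

## Descriptive analytics

The cohort summary stratifies the target-drug cohort, split on the umbrella
event flag, by sex, age band (<65 / ≥65), reporter class, FDA-receipt-year
bins (2005–2010, 2011–2015, 2016–2020), outcome codes and dose regimen.
Outcome rows are **not** mutually exclusive (a case can carry several
outcome codes); their percentages use the cohort size as denominator.
Chi-square comparisons use Pearson's statistic on 2×2 counts with 1 df and
no continuity correction.  Time to onset is event date minus the *earliest*
target-drug therapy start; negative intervals are excluded as data-entry
noise.  Quantiles (median, IQR) use linear interpolation between order
statistics — the common default in scientific software.

Dose-regimen classification needs an operational rule, since dose text in
FAERS is free-form.  The rule here: *loading* = any target-drug entry with a
single dose ≥ 200 mg on the earliest therapy date; *maintenance* class from
the modal daily dose (dose amount × administrations/day) over the remaining
dosed entries — standard at 100 mg/day, high at ≥ 200 mg/day; unclassifiable
reports count as missing.  The loading and maintenance stratifications
overlap, so the regimen rows form one non-exclusive stratification.

## Synthetic generator

The generator emulates the statistical structure a pharmacovigilance
pipeline must survive: a large background arm of irrelevant drugs, one arm
per drug of interest, independent per-event-group Bernoulli draws (a hit
emits one uniformly chosen PT from the group; every report also carries 1–3
background PTs), demographics and outcome codes from a configurable mix,
therapy-start/event-date pairs with a configurable onset distribution,
case duplicates (same payload, new `primaryid`, strictly later receipt
date), and month-truncated partial event dates.  All randomness flows from
one seed; identical configs give byte-identical tables.

Because group draws are independent, the umbrella event probability is
implied: u = 1 − ∏(1 − p_g).  `true_ror` converts configured probabilities
into the planted ROR (odds ratio of the two arms' probabilities; for the
full-database comparator, of the report-count-weighted mixture of all other
arms), which is what makes parameter-recovery tests exact rather than
approximate.

**Default corpus calibration.**  The default corpus plants the reference
signal strengths of the tigecycline case study: a 1517-report target arm
with umbrella probability 0.147 (the observed 223/1517 event fraction),
overall full-database ROR 3.55, per-subgroup full-database RORs
8.21 / 705.41 / 30.67 / 42.98 / 4.67 / 27.99 (thrombocytopenia,
hypofibrinogenaemia, coagulopathy, aPTT/INR/PT groups), and pairwise
comparator RORs 2.74 / 0.82 / 3.08 / 1.18 / 1.83 / 0.65.  The subgroup split
of the target's umbrella probability is not determined by those totals; it
is fixed once as a thrombocytopenia-dominant split with a thin tail.
Comparator arms reach their umbrella probability by raising
thrombocytopenia above the background base — the actual class effect of
these antibiotics (e.g. linezolid-induced thrombocytopenia) — and stay a
small fraction of the corpus (3,800 of ~54,000 non-target reports), as in
the real database; background per-group probabilities are then solved by a
small fixed-point iteration so that every planted full-database ROR holds
against the mixture the pipeline actually measures.  Comparator arm sizes
(1200/1000/600/500/300/200) are desk-scale choices; their pairwise ROR
estimates consequently carry wide confidence intervals, and single-run
estimates scatter accordingly — the planted values are recovered in
expectation, which is what the recovery experiment measures.

**Onset distribution.**  Default gamma(shape 4.78, scale 2.18), fitted by
least squares to quartiles (6.75, 10, 13) days; right-skewed onset is the
standard pharmacovigilance assumption.  The fitted quartiles are
(6.9, 9.7, 13.1) and P(onset ≤ 14.5 d) ≈ 0.82, so the generated corpora
reproduce a 10-day median, an IQR of roughly 7–13 days and ~80% of onsets
within two weeks.  Lognormal and exponential families are available.

**Demographic defaults** (sex 45/40/15 M/F/missing, 35% elderly among known
ages, 25% missing age, reporters 60/36/4, outcome probabilities led by
other-serious 0.34 and death 0.22) are single realistic choices for a
seriously-ill inpatient population; the generator emulates marginal mixes
only, not covariance between demographics and events, and one mix is shared
by event and non-event reports.

## What passing tests do and do not show

The generator reproduces FAERS *structure* (tables, versioning, partial
dates, role codes, PT coding) and planted *marginal* reporting rates.  It
does not model reporting biases (stimulated reporting, the Weber effect),
drug–drug interactions, correlated events, real-world name misspellings, or
confounding by indication — so green tests demonstrate that the pipeline
counts, deduplicates and estimates correctly, not that a real-data signal
implies causation.  Disproportionality statistics on spontaneous reports
never estimate incidence; they flag reporting asymmetries.

## Numerical choices

- z = 1.959964 for 95% intervals; other levels use the exact normal
  quantile.
- Reciprocity (ROR(a,b,c,d)·ROR(c,d,a,b) = 1) and comparator scaling
  invariance hold exactly in floating point and are property-tested.
- Quantiles: numpy linear interpolation (type-7).
- Ages outside [0, 150] years after unit conversion are treated as missing.
- Receipt-date ties in deduplication break to the larger primaryid; the
  comparison key is (length, string), which equals numeric order on digit
  strings and stays deterministic otherwise.

## Experiment sizes

The bundled experiments use 600 sampled tables for interval coverage
(planted ROR ∈ {1, 2, 3.5}, 500 or 5,000 reports per arm) and 200 generator
replicates at 5,000 reports per arm for planted-effect recovery; at these
sizes the coverage estimate has a standard error of ~0.9 percentage points
and the recovery mean a standard error of ~0.5%, comfortably inside the
asserted bands ([92%, 98%] coverage; mean within 10% of the planted 3.5).

## Known limitations

- Legacy AERS (pre-2012Q4, ISR-keyed) files, the XML dialect, INDI/RPSR
  tables and openFDA JSON access are out of scope.
- No PRR/IC/EBGM estimators, no Bayesian shrinkage, no duplicate-aware
  variance correction, no multiple-testing adjustment.
- MedDRA hierarchy traversal and fuzzy name matching are not implemented;
  dictionary quality bounds case ascertainment.
- Survival-style time-to-onset modelling (censoring) is not attempted; the
  cumulative curve describes reported onsets only.
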