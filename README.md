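# faerspv

Pharmacovigilance disproportionality analysis for FAERS spontaneous reports,
built around the motivating case of tigecycline-associated coagulation
dysfunction (thrombocytopenia, hypofibrinogenaemia, coagulopathy, and
prolonged aPTT/INR/PT).

The FDA Adverse Event Reporting System (FAERS) distributes each quarter as
'$'-delimited ASCII tables (DEMO, DRUG, REAC, THER, OUTC) keyed by
`primaryid` (report version) and `caseid` (case).  `faerspv` turns those
tables into signal statistics:

1. **Ingestion** — parse the five tables verbatim, join them into per-report
   records (decoded outcomes, reporter class, ages in years, therapy dates
   with explicit day/month/year precision).
2. **Cohorts** — keep the latest version of each case, match drugs of
   interest as *primary suspect* via a generic+brand-name dictionary, map
   reaction preferred terms (PTs) to event groups, and build the 2×2 tables
   for each comparison design (full database, or named comparator drug sets,
   pooled or per drug).
3. **Disproportionality** — for each table with cells *a* (target reports
   with the event), *b*, *c*, *d*, the reporting odds ratio

   ROR = (a·d)/(b·c),  95% CI = exp(ln ROR ± 1.959964·√(1/a+1/b+1/c+1/d))

   with a signal flagged when ROR ≥ 2.0 and a ≥ 3.  Zero cells are reported
   as undefined or handled by the optional Haldane–Anscombe +0.5 correction.
4. **Descriptives** — a Table-1 style summary (sex, age, reporter, year,
   outcomes, dose regimen; event cohort vs other-AE cohort), Pearson
   chi-square subgroup comparisons (no continuity correction), case-fatality
   rate, and time-to-onset (days from earliest target-drug therapy start to
   event) with median/IQR and the cumulative-onset curve.
5. **Synthetic FAERS** — a generator that emits FAERS-shaped corpora with
   *planted* RORs, duplicates, partial dates and realistic demographics, so
   the entire pipeline is testable end to end without downloads.

## Worked example

Generate the default synthetic corpus (a 1517-report tigecycline arm with a
planted overall coagulation-dysfunction ROR of 3.55 against a 50,000-report
background plus six comparator-antibiotic arms) and run signal detection:

```sh
faerspv simulate --seed 7 --out quarter/
# wrote 55317 cases (58025 report versions) to quarter

faerspv signal --in quarter/ --out signals/
# INFO faerspv: raw_reports: 58025
# INFO faerspv: deduplicated_cases: 55317
# INFO faerspv: target_cases: 1517
# INFO faerspv: flagged_target_cases: 208
# evaluated 49 comparison tables -> signals/signals.csv
```

`signals/signals.csv` holds one forest-plot row per (design, comparator,
event group).  The full-database row for the umbrella group in the run
above:

```
design         comparator     a    b     c     d      ror    ci_low  ci_high  is_signal
full_database  full_database  208  1309  2506  51294  3.252  2.795   3.785    True
```

i.e. 208 of the 1517 deduplicated tigecycline cases list a coagulation PT,
against 2506/53800 in the rest of the database; the estimated ROR 3.25
(95% CI 2.79–3.79) recovers the planted 3.55 within sampling error and is
flagged as a signal.  Descriptives for the same corpus:

```sh
faerspv describe --in quarter/ --out desc/
```

`desc/summary.json` reports `median_onset_days: 10.0`, IQR 7–13 and
`pct_within_14_days: 84.66` — recovering the generator's gamma onset
distribution (median 10 d) — plus the case-fatality rate and the Table-1
style stratification in `desc/table1.csv`.

Every run writes a `manifest.json` (config hash, input checksums, stage
counts, seed); identical seeds give byte-identical outputs.

## Library use

```python
import faerspv as fp

tables = fp.read_quarter("quarter/")
reports = fp.deduplicate(fp.assemble_reports(tables))
dd, ed = fp.default_drug_dictionary(), fp.default_event_dictionary()
tabs = fp.build_design_tables(reports, dd, ed,
                              fp.default_designs("tigecycline")[0])
for r in fp.evaluate_designs(tabs):
    print(r.table.event_group, round(r.ror, 2), r.is_signal)
```

Dictionaries are plain text (`[label]` blocks, one pattern/PT per line) and
user-replaceable via `--drug-dict` / `--event-dict`; the bundled defaults
cover tigecycline, the comparator antibiotics (vancomycin, linezolid,
daptomycin, meropenem, imipenem-cilastatin, cefoperazone) and six
coagulation event groups plus an umbrella list.

See `docs/methods.md` for the statistical model, generator calibration and
known limitations.
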