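"""Deduplication, drug/event matching, comparison designs, dose regimens."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from faerspv import (ComparisonDesign, DrugDictionary, EventDictionary,
                     DrugEntry, PartialDate, assemble_reports,
                     build_design_tables, calibration_config,
                     classify_dose_regimen, deduplicate, default_designs,
                     default_drug_dictionary, default_event_dictionary,
                     flag_events, match_drug, simulate)
from faerspv.cohort import DictionaryError, EmptyCohortError

from conftest import make_report


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_later_receipt_survives():
    early = make_report(caseid="7", primaryid="71", receipt="20190101")
    late = make_report(caseid="7", primaryid="72", receipt="20190301")
    assert deduplicate([early, late]) == [late]
    assert deduplicate([late, early]) == [late]


def test_receipt_tie_broken_by_greatest_primaryid():
    a = make_report(caseid="7", primaryid="9", receipt="20190101")
    b = make_report(caseid="7", primaryid="10", receipt="20190101")
    # numeric order: 10 > 9 despite lexicographic '10' < '9'
    assert deduplicate([a, b]) == [b]


def test_unique_caseids_pass_through():
    reports = [make_report(caseid=str(i)) for i in range(5)]
    assert deduplicate(reports) == reports


@given(st.lists(st.tuples(st.integers(0, 4), st.integers(1, 99),
                          st.integers(0, 9999)), min_size=1, max_size=30))
def test_deduplicate_is_idempotent_and_one_per_case(entries):
    reports = [make_report(caseid=str(cid), primaryid=str(pid),
                           receipt=f"2019{1 + d % 12:02d}{1 + d % 28:02d}")
               for cid, pid, d in entries]
    once = deduplicate(reports)
    assert deduplicate(once) == once
    assert len({r.caseid for r in once}) == len(once) == \
        len({r.caseid for r in reports})


def test_duplicate_injection_resolves_to_configured_case_count():
    config = dataclasses.replace(calibration_config(5, n_per_arm=400),
                                 duplicate_fraction=0.4)
    tables, truth = simulate(config)
    assert len(tables.demo) > truth.n_cases_total
    deduped = deduplicate(assemble_reports(tables))
    assert len(deduped) == truth.n_cases_total == 800


# ---------------------------------------------------------------------------
# drug matching
# ---------------------------------------------------------------------------

@pytest.fixture
def drug_dict():
    return DrugDictionary({"tigecycline": ["tigecycline", "tygacil"]})


@pytest.mark.parametrize("name,role,expected", [
    ("TYGACIL", "primary_suspect", True),
    ("tigecycline", "concomitant", False),  # role filter
    ("TIGECYCLINE 50MG VIAL", "primary_suspect", True),  # word boundary
    ("XTIGECYCLINEX", "primary_suspect", False),  # glued substring
    ("PARACETAMOL", "primary_suspect", False),
])
def test_match_drug(drug_dict, name, role, expected):
    report = make_report(drugs=[DrugEntry(name_raw=name,
                                          active_ingredient_raw="", role=role)])
    assert match_drug(report, drug_dict, "tigecycline") is expected


def test_match_via_active_ingredient(drug_dict):
    report = make_report(drugs=[DrugEntry(
        name_raw="SOMEBRAND", active_ingredient_raw="TIGECYCLINE",
        role="primary_suspect")])
    assert match_drug(report, drug_dict, "tigecycline")


def test_unknown_label_raises(drug_dict):
    with pytest.raises(KeyError):
        match_drug(make_report(), drug_dict, "nosuchdrug")


# ---------------------------------------------------------------------------
# event flagging
# ---------------------------------------------------------------------------

def test_flag_events_matches_groups_and_umbrella():
    ed = default_event_dictionary()
    flags = flag_events(make_report(reactions=["Hypofibrinogenaemia",
                                               "Nausea"]), ed)
    assert flags["hypofibrinogenaemia"]
    assert flags["coagulation_dysfunction"]
    assert not flags["thrombocytopenia"]
    assert not any(flag_events(make_report(reactions=["Nausea"]), ed).values())


def test_flag_events_is_case_insensitive_exact():
    ed = default_event_dictionary()
    assert flag_events(make_report(reactions=["THROMBOCYTOPENIA "]),
                       ed)["thrombocytopenia"]
    assert not flag_events(make_report(reactions=["Thrombocytopenia severe"]),
                           ed)["thrombocytopenia"]


def test_flag_events_monotone_under_pt_set_growth():
    small = EventDictionary({"g": ["Nausea"],
                             "coagulation_dysfunction": ["Nausea"]})
    big = EventDictionary({"g": ["Nausea", "Rash"],
                           "coagulation_dysfunction": ["Nausea", "Rash"]})
    for reactions in (["Nausea"], ["Rash"], ["Vomiting"], ["Nausea", "Rash"]):
        report = make_report(reactions=reactions)
        for group in ("g", "coagulation_dysfunction"):
            if flag_events(report, small)[group]:
                assert flag_events(report, big)[group]


# ---------------------------------------------------------------------------
# dictionaries
# ---------------------------------------------------------------------------

def test_umbrella_must_cover_subgroups():
    with pytest.raises(DictionaryError, match="umbrella"):
        EventDictionary({"thrombocytopenia": ["Thrombocytopenia"],
                         "coagulation_dysfunction": ["Coagulopathy"]})


def test_dictionary_text_parsing_errors():
    with pytest.raises(DictionaryError, match="before any"):
        DrugDictionary.from_text("tigecycline\n")
    with pytest.raises(DictionaryError, match="no entries"):
        DrugDictionary.from_text("[empty]\n")


def test_default_dictionaries_load():
    dd = default_drug_dictionary()
    ed = default_event_dictionary()
    assert "tigecycline" in dd.labels
    assert set(ed.subgroups) >= {"thrombocytopenia", "hypofibrinogenaemia",
                                 "coagulopathy", "aptt_prolonged",
                                 "inr_increased", "pt_prolonged"}
    assert ed.umbrella_only_terms()  # umbrella is strictly larger


# ---------------------------------------------------------------------------
# design tables
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def synthetic_cohort():
    config = calibration_config(11, n_per_arm=1500)
    tables, truth = simulate(config)
    reports = deduplicate(assemble_reports(tables))
    dd = DrugDictionary({"drug_a": ["drug-a"], "other": ["backgrodine"]})
    ed = default_event_dictionary()
    return reports, truth, dd, ed


def test_cell_counts_equal_generator_bookkeeping(synthetic_cohort):
    reports, truth, dd, ed = synthetic_cohort
    design = ComparisonDesign("full_db", "drug_a", "full_database")
    tables = build_design_tables(reports, dd, ed, design)
    by_group = {t.event_group: t for t in tables}
    t = by_group["thrombocytopenia"]
    assert t.a == truth.event_cases["drug_a"]["thrombocytopenia"]
    assert t.c == truth.event_cases["background"]["thrombocytopenia"]
    assert t.a + t.b == truth.arm_cases["drug_a"]
    assert t.a + t.b + t.c + t.d == truth.n_cases_total  # partition identity


def test_target_margin_constant_across_event_groups(synthetic_cohort):
    reports, truth, dd, ed = synthetic_cohort
    design = ComparisonDesign("full_db", "drug_a", "full_database")
    margins = {t.a + t.b for t in build_design_tables(reports, dd, ed, design)}
    assert margins == {truth.arm_cases["drug_a"]}


def test_per_drug_cells_sum_to_pooled(synthetic_cohort):
    reports, truth, dd, ed = synthetic_cohort
    per = build_design_tables(reports, dd, ed, ComparisonDesign(
        "x", "drug_a", ("other",), "per_drug"))
    pooled = build_design_tables(reports, dd, ed, ComparisonDesign(
        "x", "drug_a", ("other",), "pooled"))
    for group in ed.groups:
        pc = sum(t.c for t in per if t.event_group == group)
        pd_ = sum(t.d for t in per if t.event_group == group)
        (pool,) = [t for t in pooled if t.event_group == group]
        assert (pc, pd_) == (pool.c, pool.d)


def test_empty_target_cohort_raises(synthetic_cohort):
    reports, _, _, ed = synthetic_cohort
    dd = DrugDictionary({"ghost": ["nonexistentdrugname"]})
    with pytest.raises(EmptyCohortError):
        build_design_tables(reports, dd, ed,
                            ComparisonDesign("x", "ghost", "full_database"))


def test_default_designs_cover_the_four_comparisons():
    designs = default_designs()
    assert [d.label for d in designs] == [
        "full_database", "anti_mrsa", "anti_esbl", "nmtt_cephalosporin"]
    assert all(d.target == "tigecycline" for d in designs)


# ---------------------------------------------------------------------------
# dose regimen
# ---------------------------------------------------------------------------

def _dosed_report(entries):
    drugs = [DrugEntry(name_raw="TIGECYCLINE", active_ingredient_raw="",
                       role="primary_suspect", dose_amount=amt, dose_unit="MG",
                       dose_freq=freq, therapy_start=PartialDate.parse(start))
             for amt, freq, start in entries]
    return make_report(drugs=drugs)


@pytest.fixture
def tige_dict():
    return DrugDictionary({"tigecycline": ["tigecycline"]})


@pytest.mark.parametrize("entries,expected", [
    # 200 mg on the earliest day, then 50 mg BID -> loading + standard
    ([(200, "QD", "20190201"), (50, "BID", "20190202")], (True, "standard")),
    # 100 mg BID from day 0 -> non-loading, high maintenance
    ([(100, "BID", "20190201")], (False, "high")),
    # 50 mg BID from day 0 -> non-loading, standard
    ([(50, "BID", "20190201")], (False, "standard")),
    # loading then 100 mg BID -> loading + high
    ([(200, "QD", "20190201"), (100, "BID", "20190202")], (True, "high")),
])
def test_dose_regimen_classification(tige_dict, entries, expected):
    assert classify_dose_regimen(_dosed_report(entries), tige_dict,
                                 "tigecycline") == expected


def test_dose_regimen_missing_when_no_dose_info(tige_dict):
    report = make_report()
    assert classify_dose_regimen(report, tige_dict, "tigecycline") == \
        (None, None)
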