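"""Clinical-characteristics table, chi-square comparisons, time-to-onset."""

import numpy as np
import pytest
from scipy.stats import chi2

from faerspv import (DrugDictionary, DrugEntry, PartialDate, case_fatality,
                     chisq_2x2, default_event_dictionary, summarize,
                     time_to_event)
from faerspv.descriptive import EmptyCohortError

from conftest import make_report

TIGE = DrugDictionary({"tigecycline": ["tigecycline"]})
COAG_PT = "Hypofibrinogenaemia"


def _cohort(n_event, n_other, **event_kw):
    """n_event coagulation cases (with event_kw overrides) + n_other others."""
    reports = [make_report(caseid=f"e{i}", reactions=[COAG_PT], **event_kw)
               for i in range(n_event)]
    reports += [make_report(caseid=f"o{i}") for i in range(n_other)]
    return reports


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------

def test_stratum_percentages_use_cohort_size():
    # 125 of 223 event-cohort males -> 56.05%, as in a 223-case event cohort
    reports = [make_report(caseid=f"m{i}", sex="M", reactions=[COAG_PT])
               for i in range(125)]
    reports += [make_report(caseid=f"f{i}", sex="F", reactions=[COAG_PT])
                for i in range(98)]
    summary = summarize(reports, TIGE, default_event_dictionary(),
                        "tigecycline")
    sex = summary.strata["sex"][0]
    assert sex.counts["M"] == 125
    assert sex.pct("M") == pytest.approx(56.05, abs=0.005)


def test_elderly_fraction():
    # 98 of 223 aged >= 65 -> 43.95%
    reports = [make_report(caseid=f"a{i}", age=70.0, reactions=[COAG_PT])
               for i in range(98)]
    reports += [make_report(caseid=f"b{i}", age=40.0, reactions=[COAG_PT])
                for i in range(125)]
    summary = summarize(reports, TIGE, default_event_dictionary(),
                        "tigecycline")
    age = summary.strata["age"][0]
    assert age.counts[">=65"] == 98
    assert age.pct(">=65") == pytest.approx(43.95, abs=0.005)


def test_exclusive_stratifications_sum_to_cohort_size():
    reports = _cohort(40, 160)
    summary = summarize(reports, TIGE, default_event_dictionary(),
                        "tigecycline")
    for name, (ev, ot) in summary.strata.items():
        if not ev.exclusive:
            continue
        assert sum(ev.counts.values()) == summary.n_event
        assert sum(ot.counts.values()) == summary.n_other
        assert sum(ev.pct(s) for s in ev.counts) == pytest.approx(100, abs=0.05)


def test_all_missing_sex_degenerates_gracefully():
    reports = [make_report(caseid=str(i), sex="missing",
                           reactions=[COAG_PT]) for i in range(5)]
    sex = summarize(reports, TIGE, default_event_dictionary(),
                    "tigecycline").strata["sex"][0]
    assert sex.counts == {"M": 0, "F": 0, "missing": 5}


def test_outcomes_are_not_mutually_exclusive():
    reports = _cohort(3, 0, outcomes=("death", "hospitalization"))
    out = summarize(reports, TIGE, default_event_dictionary(),
                    "tigecycline").strata["outcome"][0]
    assert out.counts["death"] == out.counts["hospitalization"] == 3


def test_case_fatality_rate():
    # 45 deaths in a 223-case event cohort -> 20.18%
    reports = [make_report(caseid=f"d{i}", outcomes=("death",),
                           reactions=[COAG_PT]) for i in range(45)]
    reports += [make_report(caseid=f"s{i}", reactions=[COAG_PT])
                for i in range(178)]
    summary = summarize(reports, TIGE, default_event_dictionary(),
                        "tigecycline")
    assert case_fatality(summary) == pytest.approx(20.18, abs=0.005)


def test_empty_cohort_raises():
    with pytest.raises(EmptyCohortError):
        summarize([], TIGE, default_event_dictionary(), "tigecycline")


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table,p_expected", [
    # loading vs non-loading dose, event vs other AEs
    (((28, 86), (121, 305)), 0.41),
    # standard vs high maintenance dose
    (((111, 481), (34, 124)), 0.43),
])
def test_pearson_without_correction_reproduces_reference_p(table, p_expected):
    _, p = chisq_2x2(table)
    assert p == pytest.approx(p_expected, abs=0.005)


def test_sex_comparison_is_significant():
    stat, p = chisq_2x2(((125, 520), (69, 501)))
    assert stat == pytest.approx(11.93, abs=0.005)
    assert p < 0.05


def test_chisq_agrees_with_expected_count_bruteforce():
    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
        stat, p = chisq_2x2(((a, b), (c, d)))
        n = a + b + c + d
        exp = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
               [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
        ref = sum((obs - e) ** 2 / e for obs, e in
                  zip((a, b, c, d), (exp[0][0], exp[0][1], exp[1][0],
                                     exp[1][1])))
        assert stat == pytest.approx(ref, rel=1e-10)
        assert p == pytest.approx(float(chi2.sf(ref, 1)), rel=1e-10)


def test_chisq_rejects_degenerate_tables():
    with pytest.raises(ValueError, match="marginal"):
        chisq_2x2(((0, 0), (5, 5)))


# ---------------------------------------------------------------------------
# time to onset
# ---------------------------------------------------------------------------

def _onset_cohort(onsets, start="20190201"):
    reports = []
    for i, days in enumerate(onsets):
        event = PartialDate.parse(start).to_date()
        event = event.fromordinal(event.toordinal() + days)
        reports.append(make_report(
            caseid=str(i), event=event.strftime("%Y%m%d"),
            reactions=[COAG_PT],
            drugs=[DrugEntry(name_raw="TIGECYCLINE", active_ingredient_raw="",
                             role="primary_suspect",
                             therapy_start=PartialDate.parse(start))]))
    return reports


def test_median_of_odd_length_onsets():
    tte = time_to_event(_onset_cohort([6, 8, 10, 12, 14]), TIGE, "tigecycline")
    assert tte.median == 10
    assert tte.fraction_within(14) == 100.0


def test_linear_interpolation_quantiles():
    # order statistics of [4..18 step 2]: median (10+12)/2, Q1 at position
    # 1.75 -> 7.5, Q3 at position 5.25 -> 14.5
    tte = time_to_event(_onset_cohort([4, 6, 8, 10, 12, 14, 16, 18]),
                        TIGE, "tigecycline")
    assert tte.median == 11.0
    assert tte.iqr == (7.5, 14.5)


def test_earliest_therapy_start_is_used():
    report = make_report(
        caseid="x", event="20190210", reactions=[COAG_PT],
        drugs=[
            DrugEntry("TIGECYCLINE", "", "primary_suspect",
                      therapy_start=PartialDate.parse("20190205")),
            DrugEntry("TIGECYCLINE", "", "primary_suspect",
                      therapy_start=PartialDate.parse("20190201")),
        ])
    tte = time_to_event([report], TIGE, "tigecycline")
    assert tte.records[0].onset_days == 9


def test_exclusions_are_tallied_and_curve_monotone():
    reports = _onset_cohort([3, 7, 12])
    reports.append(make_report(caseid="neg", event="20190101",
                               reactions=[COAG_PT]))  # before therapy start
    reports.append(make_report(caseid="partial", event="201902",
                               reactions=[COAG_PT]))
    tte = time_to_event(reports, TIGE, "tigecycline")
    assert len(tte.records) == 3
    assert tte.excluded["negative_interval"] == 1
    assert tte.excluded["partial_event_date"] == 1
    curve = tte.curve()["cumulative_pct"].to_numpy()
    assert (np.diff(curve) >= 0).all()
    assert curve[-1] == 100.0


def test_no_eligible_records_raises_with_reasons():
    reports = [make_report(caseid="1", event="201902", reactions=[COAG_PT])]
    with pytest.raises(EmptyCohortError, match="partial_event_date"):
        time_to_event(reports, TIGE, "tigecycline")
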