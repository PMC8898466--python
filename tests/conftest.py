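import hypothesis
import pandas as pd
import pytest

from faerspv import CaseReport, DrugEntry, PartialDate, RawTables
from faerspv.faers_io import REQUIRED_COLUMNS

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=30,
    deadline=None)
hypothesis.settings.load_profile("deterministic")


def make_tables(demo=(), drug=(), reac=(), ther=(), outc=()) -> RawTables:
    """Build RawTables from partial row dicts; unset columns become ''."""
    frames = {}
    for name, rows in (("demo", demo), ("drug", drug), ("reac", reac),
                       ("ther", ther), ("outc", outc)):
        cols = list(REQUIRED_COLUMNS[name])
        data = [[str(row.get(c, "")) for c in cols] for row in rows]
        frames[name] = pd.DataFrame(data, columns=cols, dtype=str)
    return RawTables(**frames)


def make_report(caseid="1", primaryid=None, receipt="20190301",
                event="20190215", sex="M", age=50.0, reporter="healthcare",
                outcomes=(), drugs=None, reactions=("Nausea",)) -> CaseReport:
    receipt_pd = PartialDate.parse(receipt)
    if drugs is None:
        drugs = [DrugEntry(name_raw="TIGECYCLINE", active_ingredient_raw="",
                           role="primary_suspect",
                           therapy_start=PartialDate.parse("20190201"))]
    return CaseReport(
        caseid=caseid, primaryid=primaryid or caseid + "1",
        receipt_date=receipt_pd, event_date=PartialDate.parse(event),
        sex=sex, age_years=age, reporter_class=reporter,
        year=receipt_pd.year if receipt_pd else None,
        outcomes=frozenset(outcomes), drugs=list(drugs),
        reactions=list(reactions),
    )


@pytest.fixture
def small_quarter() -> RawTables:
    """Two complete reports: one tigecycline coagulation case, one background."""
    return make_tables(
        demo=[
            dict(primaryid="101", caseid="10", event_dt="20180610", sex="M",
                 age="62", age_cod="YR", occp_cod="MD", fda_dt="20180701"),
            dict(primaryid="201", caseid="20", event_dt="20180305", sex="F",
                 age="730", age_cod="DY", occp_cod="CN", fda_dt="20180401"),
        ],
        drug=[
            dict(primaryid="101", caseid="10", drug_seq="1", role_cod="PS",
                 drugname="TYGACIL", prod_ai="TIGECYCLINE", dose_amt="50",
                 dose_unit="MG", dose_freq="BID"),
            dict(primaryid="201", caseid="20", drug_seq="1", role_cod="PS",
                 drugname="OTHERMYCIN", prod_ai=""),
        ],
        reac=[
            dict(primaryid="101", caseid="10", pt="Hypofibrinogenaemia"),
            dict(primaryid="101", caseid="10", pt="Nausea"),
            dict(primaryid="201", caseid="20", pt="Rash"),
        ],
        ther=[
            dict(primaryid="101", caseid="10", dsg_drug_seq="1",
                 start_dt="20180601"),
            dict(primaryid="201", caseid="20", dsg_drug_seq="1",
                 start_dt="20180301"),
        ],
        outc=[
            dict(primaryid="101", caseid="10", outc_cod="DE"),
            dict(primaryid="101", caseid="10", outc_cod="HO"),
        ],
    )
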