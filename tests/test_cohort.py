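import math

import numpy as np
import pandas as pd
import pytest

from faerspv.cohort import (
    CohortConfig,
    build_cohort,
    build_reports,
    match_target_drug,
    normalize_age,
    quartiles,
    summarize_cohort,
)


@pytest.mark.parametrize(
    "value,unit,expected",
    [
        ("120", "MON", 10.0),
        ("1.2", "DEC", 12.0),
        ("10", "YR", 10.0),
        ("365.25", "DY", 1.0),
        ("52.1775", "WK", 1.0),
        ("8766", "HR", 1.0),
    ],
)
def test_normalize_age_units(value, unit, expected):
    assert normalize_age(value, unit) == pytest.approx(expected)


@pytest.mark.parametrize("value,unit", [("", ""), ("abc", "YR"), ("-5", "YR"), ("3", "XX")])
def test_normalize_age_missing_or_invalid(value, unit):
    assert math.isnan(normalize_age(value, unit))


@pytest.mark.parametrize(
    "names,expected",
    [
        (["KYMRIAH"], True),
        (["kymriah 1 infusion"], True),
        (["CTL019"], True),
        (["RITUXIMAB"], False),
        ([], False),
    ],
)
def test_match_target_drug(names, expected):
    assert match_target_drug(names) is expected


def test_classification_rules(fixture_analysis):
    data = fixture_analysis["data"]
    cohort = fixture_analysis["cohort"].reports
    reacs = data.reacs

    # any report whose PTs include Hypotension must be CVAE
    hypo_ids = set(reacs.loc[reacs["pt"] == "Hypotension", "primaryid"])
    assert cohort.loc[cohort["primaryid"].isin(hypo_ids), "is_cvae"].all()

    # CRS is PT-exact; tachycardia reports in the fixture co-report CRS
    # only where the CRS PT row exists
    crs_ids = set(reacs.loc[reacs["pt"] == "Cytokine release syndrome", "primaryid"])
    assert set(cohort.loc[cohort["has_crs"], "primaryid"]) == crs_ids & set(
        cohort["primaryid"]
    )

    # fatal requires outcome DE
    de_ids = set(
        data.outcomes.loc[data.outcomes["outc_cod"] == "DE", "primaryid"]
    )
    assert set(cohort.loc[cohort["is_fatal"], "primaryid"]) == de_ids & set(
        cohort["primaryid"]
    )


def test_partition_and_percentage_invariants(fixture_analysis):
    cohort = fixture_analysis["cohort"]
    df = cohort.reports
    s = cohort.summary
    assert s["n_cvae"] + s["n_non_cvae"] == s["n"]
    n_fatal = int((df["is_cvae"] & df["is_fatal"]).sum())
    assert n_fatal == s["n_fatal_cvae"]
    for block in ("sex", "reporter"):
        assert s[block]["pct"].sum() == pytest.approx(100.0)
    assert s["country"]["pct"].sum() == pytest.approx(100.0)


def test_missing_age_excluded_from_cohort(small_synthetic):
    """Pediatric filter is strict age < 18 with missing ages excluded."""
    cohort = small_synthetic["cohort"].reports
    assert (cohort["age_years"] < 18).all()
    assert cohort["age_years"].notna().all()
    assert cohort["is_target"].all()


def test_shrinking_synonyms_never_grows_cohort(small_synthetic):
    data = small_synthetic["data"]
    ptmap, atcmap = {}, {}
    full = build_cohort(data, ptmap, atcmap, CohortConfig())
    brand_only = build_cohort(
        data, ptmap, atcmap, CohortConfig(synonyms=("KYMRIAH",))
    )
    assert set(brand_only.reports["primaryid"]).issubset(set(full.reports["primaryid"]))


def test_single_report_summary_is_degenerate():
    df = pd.DataFrame(
        {
            "primaryid": ["1"],
            "caseid": ["1"],
            "age_years": [10.0],
            "sex": ["M"],
            "country": ["US"],
            "reporter": ["physician"],
            "event_dt": ["20200101"],
            "fda_dt": [20200301],
            "is_cvae": [True],
            "is_fatal": [False],
        }
    )
    s = summarize_cohort(df)
    for block in ("sex", "reporter"):
        assert set(s[block]["pct"]) <= {0.0, 100.0}
    assert s["age_q1"] == s["age_median"] == s["age_q3"] == 10.0


def test_quartiles_type7():
    assert quartiles([1, 2, 3, 4]) == pytest.approx((1.75, 2.5, 3.25))
    assert quartiles([7]) == (7.0, 7.0, 7.0)
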