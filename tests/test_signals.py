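import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.signals import ContingencyTable, contingency, ror, screen_signals

cells = st.integers(1, 500)


def _reacs(pairs):
    return pd.DataFrame(pairs, columns=["primaryid", "pt"])


def test_contingency_direct_count():
    cohort = {"1", "2", "3", "4", "5"}
    comparator = {str(i) for i in range(10, 20)}
    reacs = _reacs(
        [("1", "Hypotension"), ("2", "Hypotension"), ("10", "Hypotension"), ("3", "Nausea")]
    )
    t = contingency(cohort, comparator, reacs, "Hypotension")
    assert (t.a, t.b, t.c, t.d) == (2, 3, 1, 9)


def test_contingency_absent_pt():
    t = contingency({"1"}, {"2"}, _reacs([("1", "Nausea")]), "Shock")
    assert t.a == 0 and t.c == 0


def test_contingency_empty_pt_rejected():
    with pytest.raises(ValueError):
        contingency({"1"}, {"2"}, _reacs([]), "")


def test_repeated_pt_in_one_report_counts_once():
    reacs = _reacs([("1", "Shock"), ("1", "shock")])
    t = contingency({"1", "2"}, {"3"}, reacs, "Shock")
    assert t.a == 1


def test_ror_symmetric_table_is_unity():
    r = ror(ContingencyTable(10, 10, 10, 10))
    assert r.ror == pytest.approx(1.0)
    assert r.ci_low < 1.0 < r.ci_high
    assert not r.is_signal


def test_ror_closed_form():
    r = ror(ContingencyTable(10, 90, 100, 9900))
    assert r.ror == pytest.approx(11.0)
    # se = sqrt(1/10 + 1/90 + 1/100 + 1/9900) = 0.3481552
    assert r.ci_low == pytest.approx(math.exp(math.log(11) - 1.96 * 0.3481552), abs=1e-4)
    assert r.ci_high == pytest.approx(math.exp(math.log(11) + 1.96 * 0.3481552), abs=1e-3)
    assert r.is_signal


def test_zero_cell_undefined_without_correction():
    r = ror(ContingencyTable(0, 5, 3, 100))
    assert math.isnan(r.ror) and not r.is_signal and not r.corrected


def test_zero_cell_haldane_anscombe():
    r = ror(ContingencyTable(0, 5, 3, 100), zero_correction=True)
    expected = (0.5 * 100.5) / (5.5 * 3.5)
    assert r.ror == pytest.approx(expected)
    assert r.corrected


def test_signal_requires_three_reports():
    # strong disproportionality but only 2 target reports -> no signal
    r = ror(ContingencyTable(2, 10, 1, 1000))
    assert r.ci_low > 1 and not r.is_signal


@given(a=cells, b=cells, c=cells, d=cells)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_ror_properties(a, b, c, d):
    r = ror(ContingencyTable(a, b, c, d))
    swapped = ror(ContingencyTable(b, a, d, c))
    assert r.ror * swapped.ror == pytest.approx(1.0)
    assert r.ci_low <= r.ror <= r.ci_high
    bigger = ror(ContingencyTable(a + 1, b, c, d))
    assert bigger.ror > r.ror


def test_screen_matches_brute_force_recount(small_synthetic):
    data = small_synthetic["data"]
    cohort = small_synthetic["cohort"]
    cohort_ids = set(cohort.reports["primaryid"])
    comp_ids = cohort.comparator_ids
    results = screen_signals(cohort_ids, comp_ids, data.reacs, pts=["Hypotension", "Pyrexia"])
    by_pt = {r.pt: r for r in results}
    for pt in ("Hypotension", "Pyrexia"):
        with_pt = {
            pid
            for pid, p in zip(data.reacs["primaryid"], data.reacs["pt"])
            if p.casefold() == pt.casefold()
        }
        assert by_pt[pt].n_reports == len(cohort_ids & with_pt)


def test_screen_ordering_signals_first_descending(fixture_analysis):
    data = fixture_analysis["data"]
    cohort = fixture_analysis["cohort"]
    results = screen_signals(
        set(cohort.reports["primaryid"]),
        cohort.comparator_ids,
        data.reacs,
        ptmap=fixture_analysis["ptmap"],
    )
    sig = [r for r in results if r.is_signal]
    assert sig == results[: len(sig)]
    rors = [r.ror for r in sig]
    assert rors == sorted(rors, reverse=True)


def test_screen_empty_when_no_pts():
    assert screen_signals({"1"}, {"2"}, _reacs([]), pts=None) == []
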