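import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.dedup import apply_deletions, deduplicate, refine


def _demo(rows):
    return pd.DataFrame(
        [{"primaryid": str(p), "caseid": str(c), "fda_dt": str(f)} for c, f, p in rows],
        dtype=str,
    )


def brute_force_dedup(rows):
    """Independent reference: group by caseid, keep max (fda_dt, primaryid)."""
    best = {}
    for c, f, p in rows:
        if c not in best or (f, p) > best[c]:
            best[c] = (f, p)
    return {(c, f, p) for c, (f, p) in best.items()}


def test_highest_fda_dt_retained():
    out, _ = deduplicate(_demo([(7, 20220101, 1), (7, 20220301, 2)]))
    assert list(out["primaryid"]) == ["2"]


def test_fda_dt_tie_broken_by_highest_primaryid():
    out, _ = deduplicate(_demo([(7, 20220301, 5), (7, 20220301, 9)]))
    assert list(out["primaryid"]) == ["9"]


def test_distinct_caseids_pass_through():
    demo = _demo([(1, 20220101, 11), (2, 20220102, 12), (3, 20220103, 13)])
    out, stats = deduplicate(demo)
    assert len(out) == 3 and stats.invalid_rows == 0
    pd.testing.assert_frame_equal(out, demo)


def test_invalid_keys_excluded_and_counted():
    demo = pd.DataFrame(
        {
            "primaryid": ["1", "x", "3"],
            "caseid": ["10", "20", ""],
            "fda_dt": ["20220101", "20220102", "20220103"],
        }
    )
    out, stats = deduplicate(demo)
    assert len(out) == 1 and stats.invalid_rows == 2


def test_missing_fda_dt_loses_ties():
    out, _ = deduplicate(_demo([(5, "", 99), (5, 20200101, 1)]))
    assert list(out["primaryid"]) == ["1"]


@given(
    st.lists(
        st.tuples(
            st.integers(1, 8),  # caseid from a small pool -> duplicates likely
            st.integers(20200101, 20200131),
            st.integers(1, 10_000),
        ),
        min_size=1,
        max_size=60,
    )
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_matches_brute_force_and_is_idempotent(rows):
    demo = _demo(rows)
    out, _ = deduplicate(demo)
    got = {
        (int(c), int(f), int(p))
        for c, f, p in zip(out["caseid"], out["fda_dt"], out["primaryid"])
    }
    assert got == brute_force_dedup(rows)
    again, _ = deduplicate(out)
    pd.testing.assert_frame_equal(again, out)


@given(st.randoms(use_true_random=False))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_permutation_invariance(rnd):
    rows = [(i % 5 + 1, 20200101 + i % 7, i + 1) for i in range(30)]
    base, _ = deduplicate(_demo(rows))
    shuffled = rows[:]
    rnd.shuffle(shuffled)
    out, _ = deduplicate(_demo(shuffled))
    pd.testing.assert_frame_equal(out, base)


@pytest.mark.parametrize(
    "deleted,expected",
    [({2}, ["1", "3"]), (set(), ["1", "2", "3"]), ({99}, ["1", "2", "3"])],
)
def test_apply_deletions(deleted, expected):
    demo = _demo([(1, 20220101, 11), (2, 20220102, 12), (3, 20220103, 13)])
    out, n = apply_deletions(demo, deleted)
    assert list(out["caseid"]) == expected
    assert n == 3 - len(expected)


def test_generator_duplicates_exactly_removed(small_synthetic):
    """Ground-truth bookkeeping: dedup drops exactly the superseded versions."""
    bundle = small_synthetic["bundle"]
    truth = small_synthetic["truth"]
    out, _ = deduplicate(bundle.demo)
    survivors = set(out["primaryid"].astype(int))
    all_ids = set(bundle.demo["primaryid"].astype(int))
    assert all_ids - survivors == set(truth.removed_primaryids)


def test_refine_cardinality(small_synthetic):
    """|output| = distinct valid caseids minus deleted ones."""
    bundle = small_synthetic["bundle"]
    refined = small_synthetic["refined"]
    caseids = set(bundle.demo["caseid"].astype(int))
    expected = len(caseids - bundle.deleted_caseids)
    assert len(refined.demo) == expected
    surviving = set(refined.demo["primaryid"])
    for child in (refined.drug, refined.reac, refined.outc, refined.ther):
        assert set(child["primaryid"]).issubset(surviving)
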