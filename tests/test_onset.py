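import itertools

import numpy as np
import pandas as pd
import pytest

from faerspv.cohort import DEFAULT_SYNONYMS, ReportData
from faerspv.onset import compute_tto, summarize, wilcoxon_two_sample


def _data(event_dt, start_dt):
    demo = pd.DataFrame(
        {
            "primaryid": ["1"],
            "caseid": ["1"],
            "age_years": [10.0],
            "sex": ["M"],
            "country": ["US"],
            "reporter": ["physician"],
            "event_dt": [event_dt],
            "fda_dt": [20230101],
        }
    )
    drugs = pd.DataFrame(
        {
            "primaryid": ["1"],
            "caseid": ["1"],
            "drug_seq": ["1"],
            "role_cod": ["PS"],
            "drugname": ["KYMRIAH"],
            "prod_ai": ["TISAGENLECLEUCEL"],
        }
    )
    ther = pd.DataFrame(
        {"primaryid": ["1"], "caseid": ["1"], "dsg_drug_seq": ["1"], "start_dt": [start_dt]}
    )
    empty = pd.DataFrame({"primaryid": [], "caseid": [], "pt": [], "outc_cod": []})
    return ReportData(demo=demo, drugs=drugs, reacs=empty, outcomes=empty, ther=ther)


@pytest.mark.parametrize(
    "event,start,expected_days",
    [("20220104", "20220101", 3), ("20220101", "20220101", 0)],
)
def test_compute_tto_date_arithmetic(event, start, expected_days):
    frame, _ = compute_tto(_data(event, start), {"1"}, DEFAULT_SYNONYMS)
    assert list(frame["days"]) == [expected_days]


def test_partial_event_date_excluded():
    frame, excl = compute_tto(_data("202201", "20220101"), {"1"}, DEFAULT_SYNONYMS)
    assert len(frame) == 0 and excl.partial_or_missing_event == 1


def test_event_before_start_excluded():
    frame, excl = compute_tto(_data("20211231", "20220101"), {"1"}, DEFAULT_SYNONYMS)
    assert len(frame) == 0 and excl.negative == 1


def test_missing_start_excluded():
    frame, excl = compute_tto(_data("20220104", ""), {"1"}, DEFAULT_SYNONYMS)
    assert len(frame) == 0 and excl.missing_start == 1


@pytest.mark.parametrize(
    "values,expected",
    [
        ([1, 2, 3, 4, 5], (5, 3.0, 2.0, 4.0)),
        ([1, 2, 3, 4], (4, 2.5, 1.75, 3.25)),
        ([7], (1, 7.0, 7.0, 7.0)),
    ],
)
def test_summarize_quantiles(values, expected):
    s = summarize(values)
    assert (s.n, s.median, s.q1, s.q3) == pytest.approx(expected)


def test_summarize_empty_rejected():
    with pytest.raises(ValueError):
        summarize([])


def test_summarize_permutation_and_shift_invariance():
    vals = [3, 1, 4, 1, 5, 9, 2, 6]
    s1 = summarize(vals)
    s2 = summarize(list(reversed(vals)))
    assert (s1.median, s1.q1, s1.q3) == (s2.median, s2.q1, s2.q3)
    s3 = summarize([v + 10 for v in vals])
    assert s3.median == s1.median + 10


def test_wilcoxon_exact_small_sample():
    w, p = wilcoxon_two_sample([1, 2], [3, 4])
    assert w == 3.0
    assert p == pytest.approx(1 / 3)


def test_wilcoxon_identical_samples():
    _, p = wilcoxon_two_sample([5, 5, 5], [5, 5])
    assert p == 1.0
    _, p2 = wilcoxon_two_sample([1, 2, 3], [1, 2, 3])
    assert p2 > 0.9


def test_wilcoxon_detects_large_shift():
    rng = np.random.default_rng(11)
    x = rng.lognormal(np.log(3), 0.8, 150)
    y = rng.lognormal(np.log(30), 0.8, 150)
    _, p = wilcoxon_two_sample(x, y)
    assert p < 0.001


def test_exact_and_normal_approx_agree_on_tiefree_samples():
    """Sweep of tie-free problems, sizes 8-10: |p_exact - p_normal| < 0.02."""
    from scipy import stats

    rng = np.random.default_rng(2)
    for nx, ny in [(8, 8), (8, 10), (9, 9), (9, 10), (10, 10)]:
        for _ in range(30):
            vals = rng.permutation(np.arange(1, nx + ny + 1) * 1.0)
            x, y = vals[:nx], vals[nx:]
            _, p_exact = wilcoxon_two_sample(x, y)
            p_norm = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - min(p_norm, 1.0)) < 0.02


def test_tto_medians_recovered_from_generator(small_synthetic):
    """CVAE onset is generated faster than non-CVAE onset; the computed
    medians must preserve that ordering."""
    data = small_synthetic["data"]
    cohort = small_synthetic["cohort"].reports
    ids = set(cohort["primaryid"])
    frame, _ = compute_tto(data, ids, DEFAULT_SYNONYMS)
    cvae_ids = set(cohort.loc[cohort["is_cvae"], "primaryid"])
    days_cvae = frame.loc[frame["primaryid"].isin(cvae_ids), "days"]
    days_non = frame.loc[~frame["primaryid"].isin(cvae_ids), "days"]
    assert len(days_cvae) > 20 and len(days_non) > 20
    assert summarize(days_cvae).median < summarize(days_non).median
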