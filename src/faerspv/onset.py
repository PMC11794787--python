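"""Time-to-onset (TTO) analysis.

TTO is the number of days from the earliest target-drug therapy start
(THER.start_dt joined to the target DRUG row via dsg_drug_seq) to the
event date (DEMO.event_dt).  Both dates must be full YYYYMMDD values;
partial or missing dates and negative differences are excluded rather
than imputed, so day-scale medians are never fabricated.  Group
contrasts use the Wilcoxon two-sample (rank-sum) test, exact when both
samples are small and tie-free, otherwise a tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ReportData, quartiles

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTOSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass
class TTOExclusions:
    missing_start: int = 0
    partial_or_missing_event: int = 0
    negative: int = 0


def _full_date(series: pd.Series) -> pd.Series:
    """Parse YYYYMMDD strings; anything shorter/invalid becomes NaT."""
    s = series.astype(str).str.strip()
    ok = s.str.fullmatch(r"\d{8}")
    return pd.to_datetime(s.where(ok), format="%Y%m%d", errors="coerce")


def compute_tto(
    data: ReportData,
    target_ids: set[str],
    synonyms: Sequence[str],
) -> tuple[pd.DataFrame, TTOExclusions]:
    """Days from earliest target-drug start to event, per report.

    Returns a frame with columns ``primaryid``, ``days`` containing only
    reports with a defined TTO, plus the exclusion tally.
    """
    excl = TTOExclusions()
    drugs = data.drugs[data.drugs["primaryid"].isin(target_ids)]
    pattern = "|".join(s.upper() for s in synonyms)
    is_target_row = drugs["drugname"].str.upper().str.contains(pattern) | drugs[
        "prod_ai"
    ].str.upper().str.contains(pattern)
    target_rows = drugs[is_target_row.fillna(False)][["primaryid", "drug_seq"]]

    ther = data.ther.merge(
        target_rows,
        left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"],
    )
    ther = ther.assign(start=_full_date(ther["start_dt"]))
    starts = ther.dropna(subset=["start"]).groupby("primaryid")["start"].min()

    demo = data.demo[data.demo["primaryid"].isin(target_ids)]
    event = _full_date(demo["event_dt"])
    frame = pd.DataFrame(
        {"primaryid": demo["primaryid"].to_numpy(), "event": event.to_numpy()}
    )
    frame["start"] = frame["primaryid"].map(starts)

    excl.missing_start = int(frame["start"].isna().sum())
    excl.partial_or_missing_event = int(frame["event"].isna().sum())
    frame = frame.dropna(subset=["start", "event"])
    days = (frame["event"] - frame["start"]).dt.days
    negative = days < 0
    excl.negative = int(negative.sum())
    if excl.negative:
        log.info("compute_tto: excluded %d report(s) with event before start", excl.negative)
    out = pd.DataFrame(
        {"primaryid": frame.loc[~negative, "primaryid"], "days": days[~negative]}
    ).reset_index(drop=True)
    return out, excl


def summarize(days: Sequence[float]) -> TTOSummary:
    """Median and IQR by linear-interpolation quantiles."""
    arr = np.asarray(days, dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires a nonempty sample")
    q1, med, q3 = quartiles(arr)
    return TTOSummary(n=arr.size, median=med, q1=q1, q3=q3)


def wilcoxon_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-sum statistic W (midranks) for x, with a two-sided p-value.

    Exact p by enumeration of rank assignments when n_x + n_y <= 20 and
    there are no ties; otherwise the normal approximation with
    tie-corrected variance and 0.5 continuity correction.  Degenerate
    samples (all values identical across both groups) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[: x.size].sum())
    if np.unique(combined).size == 1:
        return w, 1.0
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return w, float(min(res.pvalue, 1.0))


def compare_groups(
    tto: pd.DataFrame, group_ids: dict[str, set[str]]
) -> dict:
    """Summaries per group plus the pairwise Wilcoxon contrast.

    ``group_ids`` maps two group names (e.g. CVAE / non-CVAE) to report
    id sets; reports without a defined TTO simply do not contribute.
    """
    if len(group_ids) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    (name_a, ids_a), (name_b, ids_b) = group_ids.items()
    days_a = tto.loc[tto["primaryid"].isin(ids_a), "days"].to_numpy()
    days_b = tto.loc[tto["primaryid"].isin(ids_b), "days"].to_numpy()
    out: dict = {"groups": {}}
    for name, days in ((name_a, days_a), (name_b, days_b)):
        if days.size:
            s = summarize(days)
            out["groups"][name] = {"n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3}
        else:
            out["groups"][name] = {"n": 0}
    if days_a.size and days_b.size:
        w, p = wilcoxon_two_sample(days_a, days_b)
        method = (
            "exact"
            if days_a.size + days_b.size <= 20
            and np.unique(np.concatenate([days_a, days_b])).size
            == days_a.size + days_b.size
            else "normal_approx"
        )
        out["test"] = {"W": w, "p": p, "method": f"wilcoxon_{method}"}
    return out
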