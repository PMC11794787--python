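"""Per-PT CRS co-reporting and mortality, plus categorical group tests.

For each cardiovascular PT the cohort reports mentioning it are tallied:
how many also report cytokine release syndrome (CRS) and how many were
fatal.  Group comparisons dispatch between Fisher's exact test (any
expected cell below 5) and the Pearson chi-square test (all expected
cells at least 5), the standard small-sample rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapRow:
    pt: str
    n_pt: int
    n_crs_overlap: int
    overlap_rate: float
    n_fatal: int
    mortality_rate: float


def overlap_table(
    cohort: pd.DataFrame, reacs: pd.DataFrame, pts: Sequence[str]
) -> list[OverlapRow]:
    """One row per PT restricted to cohort reports containing that PT.

    ``cohort`` must carry ``primaryid``, ``has_crs`` and ``is_fatal``
    labels.  PTs with no cohort reports are omitted.
    """
    crs_ids = set(cohort.loc[cohort["has_crs"], "primaryid"])
    fatal_ids = set(cohort.loc[cohort["is_fatal"], "primaryid"])
    cohort_ids = set(cohort["primaryid"])
    pairs = reacs.drop_duplicates(["primaryid", "pt"])
    key = pairs["pt"].str.casefold()

    rows = []
    for pt in pts:
        with_pt = set(pairs.loc[key == pt.casefold(), "primaryid"]) & cohort_ids
        n = len(with_pt)
        if n == 0:
            continue
        n_crs = len(with_pt & crs_ids)
        n_fatal = len(with_pt & fatal_ids)
        rows.append(
            OverlapRow(pt, n, n_crs, n_crs / n, n_fatal, n_fatal / n)
        )
    rows.sort(key=lambda r: -r.n_pt)
    return rows


def overlap_frame(rows: Sequence[OverlapRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pt": r.pt,
                "n": r.n_pt,
                "n_crs_overlap": r.n_crs_overlap,
                "overlap_rate": r.overlap_rate,
                "n_fatal": r.n_fatal,
                "mortality_rate": r.mortality_rate,
            }
            for r in rows
        ]
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (zero margins give 1)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("fisher_exact needs a nonnegative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def chi_square(
    table: Sequence[Sequence[int]], yates: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction by default).

    Returns (statistic, p, dof).  Degenerate margins raise.
    """
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi_square: degenerate margins")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p), int(dof)


def expected_counts(table: Sequence[Sequence[int]]) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def association_test(table: Sequence[Sequence[int]], yates: bool = False) -> dict:
    """Dispatch per the small-sample rule: any expected cell < 5 -> Fisher.

    2x2 only for the Fisher branch; larger tables always use chi-square.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape == (2, 2) and (
        arr.sum() == 0 or (expected_counts(arr) < 5).any()
    ):
        return {"method": "fisher_exact", "p": fisher_exact(arr)}
    stat, p, dof = chi_square(arr, yates=yates)
    return {"method": "chi_square", "statistic": stat, "p": p, "dof": dof}
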