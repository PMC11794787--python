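"""Reporting odds ratio (ROR) disproportionality analysis.

For each preferred term the case/non-case 2x2 table is

                event    no event
    target        a         b
    comparator    c         d

and ROR = (a*d)/(b*c) with 95% CI exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).
A PT is flagged as a signal when it has at least three target-drug
reports (a >= 3) and the lower 95% bound exceeds 1.  Event presence is
binary per report: repeated identical PTs within one report count once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

Z95 = 1.96  # 95% CI (the convention the signal criteria are stated in)

#: Minimum number of target-drug reports for a signal.
MIN_REPORTS = 3


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target drug, event
    b: int  # target drug, no event
    c: int  # comparator, event
    d: int  # comparator, no event

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")


@dataclass(frozen=True)
class SignalResult:
    pt: str
    n_reports: int  # = a
    ror: float  # NaN when undefined
    ci_low: float
    ci_high: float
    is_signal: bool
    corrected: bool = False


def contingency(
    cohort_ids: set[str],
    comparator_ids: set[str],
    reacs: pd.DataFrame,
    pt: str,
) -> ContingencyTable:
    """Count the 2x2 table for one PT over disjoint report sets."""
    if not pt:
        raise ValueError("pt must be non-empty")
    key = pt.casefold()
    with_pt = set(reacs.loc[reacs["pt"].str.casefold() == key, "primaryid"])
    a = len(cohort_ids & with_pt)
    c = len(comparator_ids & with_pt)
    return ContingencyTable(a, len(cohort_ids) - a, c, len(comparator_ids) - c)


def ror(table: ContingencyTable, zero_correction: bool = False, pt: str = "") -> SignalResult:
    """Point estimate, Wald CI and signal flag for one 2x2 table.

    A zero cell leaves the ROR undefined (NaN) unless ``zero_correction``
    applies the Haldane–Anscombe +0.5 to all four cells, in which case
    the result is flagged ``corrected``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        if not zero_correction:
            return SignalResult(pt, table.a, float("nan"), float("nan"), float("nan"), False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - Z95 * se)
    hi = math.exp(math.log(est) + Z95 * se)
    is_signal = table.a >= MIN_REPORTS and lo > 1.0
    return SignalResult(pt, table.a, est, lo, hi, is_signal, corrected)


def screen_signals(
    cohort_ids: set[str],
    comparator_ids: set[str],
    reacs: pd.DataFrame,
    pts: Sequence[str] | None = None,
    ptmap: dict[str, str] | None = None,
    zero_correction: bool = False,
) -> list[SignalResult]:
    """Per-PT ROR screen over a list of PTs.

    With ``pts=None`` the screen covers every PT observed in the cohort
    that maps to a cardiovascular SOC under ``ptmap`` (or, if no map is
    given, every PT observed in the cohort).  Results are ordered
    signals first by descending ROR, then remaining PTs by descending
    report count.
    """
    pairs = reacs.drop_duplicates(["primaryid", "pt"])
    key = pairs["pt"].str.casefold()
    in_cohort = pairs["primaryid"].isin(cohort_ids)
    in_comp = pairs["primaryid"].isin(comparator_ids)

    if pts is None:
        observed = pairs.loc[in_cohort, "pt"]
        if ptmap is not None:
            from .mappings import CARDIOVASCULAR_SOCS

            observed = observed[
                observed.str.casefold().map(ptmap).isin(CARDIOVASCULAR_SOCS)
            ]
        # preserve first-seen capitalisation, one entry per casefolded PT
        seen: dict[str, str] = {}
        for p in observed:
            seen.setdefault(p.casefold(), p)
        pts = list(seen.values())
    if not pts:
        return []

    a_counts = key[in_cohort].value_counts()
    c_counts = key[in_comp].value_counts()
    n_cohort, n_comp = len(cohort_ids), len(comparator_ids)

    results = []
    for p in pts:
        k = p.casefold()
        a = int(a_counts.get(k, 0))
        c = int(c_counts.get(k, 0))
        table = ContingencyTable(a, n_cohort - a, c, n_comp - c)
        results.append(ror(table, zero_correction=zero_correction, pt=p))
    results.sort(
        key=lambda r: (
            not r.is_signal,
            -(r.ror if r.is_signal and not math.isnan(r.ror) else -math.inf),
            -r.n_reports,
        )
    )
    return results


def signals_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Tabulate screen results for CSV output."""
    return pd.DataFrame(
        [
            {
                "pt": r.pt,
                "n": r.n_reports,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "is_signal": r.is_signal,
                "corrected": r.corrected,
            }
            for r in results
        ]
    )
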