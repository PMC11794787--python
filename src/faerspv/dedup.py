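"""Deduplication of spontaneous reports and deletion-list handling.

FAERS distributes successive versions of the same safety report under one
CASEID with distinct PRIMARYIDs.  Following the FDA-endorsed refinement,
one row is retained per CASEID: the row with the highest FDA_DT (latest
receipt), ties broken by the highest PRIMARYID.  After deduplication the
quarterly deletion logs are applied by CASEID.  Child tables are then
filtered to the surviving PRIMARYIDs so reports stay coherent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import QuarterBundle

log = logging.getLogger(__name__)


@dataclass
class DedupStats:
    input_rows: int = 0
    invalid_rows: int = 0
    unique_cases: int = 0
    deleted: int = 0
    output_rows: int = 0
    dropped_child_rows: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, DedupStats]:
    """Keep one DEMO row per CASEID: max FDA_DT, ties to max PRIMARYID.

    Rows whose CASEID or PRIMARYID do not parse as positive integers are
    excluded and counted.  Missing or unparseable FDA_DT is treated as 0
    so that row always loses ties to any dated version.  Output is sorted
    by CASEID, making the result independent of input row order.
    """
    stats = DedupStats(input_rows=len(demo))
    if len(demo) == 0:
        return demo.copy(), stats

    caseid = pd.to_numeric(demo["caseid"], errors="coerce")
    primaryid = pd.to_numeric(demo["primaryid"], errors="coerce")
    fda_dt = pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(0)

    valid = caseid.notna() & (caseid > 0) & primaryid.notna() & (primaryid > 0)
    stats.invalid_rows = int((~valid).sum())
    if stats.invalid_rows:
        log.warning("deduplicate: excluded %d row(s) with invalid keys", stats.invalid_rows)

    keyed = demo.assign(_caseid=caseid, _primaryid=primaryid, _fda_dt=fda_dt)[valid]
    keyed = keyed.sort_values(
        ["_caseid", "_fda_dt", "_primaryid"], kind="mergesort"
    )
    kept = keyed.groupby("_caseid", sort=True).tail(1)
    kept = kept.sort_values("_caseid", kind="mergesort")
    result = kept.drop(columns=["_caseid", "_primaryid", "_fda_dt"]).reset_index(drop=True)
    stats.unique_cases = len(result)
    stats.output_rows = len(result)
    return result, stats


def apply_deletions(
    demo: pd.DataFrame, deleted: set[int]
) -> tuple[pd.DataFrame, int]:
    """Remove rows whose CASEID appears in the deletion set."""
    if len(demo) == 0 or not deleted:
        return demo.reset_index(drop=True), 0
    caseid = pd.to_numeric(demo["caseid"], errors="coerce")
    drop = caseid.isin(list(deleted))
    n_removed = int(drop.sum())
    return demo[~drop].reset_index(drop=True), n_removed


def filter_children(child: pd.DataFrame, surviving_primaryids: set[str]) -> pd.DataFrame:
    """Restrict a child table to rows of surviving reports."""
    if len(child) == 0:
        return child.reset_index(drop=True)
    return child[child["primaryid"].isin(surviving_primaryids)].reset_index(drop=True)


def refine(bundle: QuarterBundle) -> tuple[QuarterBundle, DedupStats]:
    """Deduplicate then apply deletions, propagating to child tables.

    The composed operation the pipeline runs once over all quarters.
    """
    demo, stats = deduplicate(bundle.demo)
    demo, stats.deleted = apply_deletions(demo, bundle.deleted_caseids)
    stats.output_rows = len(demo)
    surviving = set(demo["primaryid"])
    refined = QuarterBundle(
        demo=demo,
        drug=filter_children(bundle.drug, surviving),
        reac=filter_children(bundle.reac, surviving),
        outc=filter_children(bundle.outc, surviving),
        ther=filter_children(bundle.ther, surviving),
        deleted_caseids=set(bundle.deleted_caseids),
    )
    stats.dropped_child_rows = sum(
        len(t) for t in bundle.tables().values()
    ) - len(bundle.demo) - sum(
        len(t) for n, t in refined.tables().items() if n != "DEMO"
    )
    return refined, stats
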