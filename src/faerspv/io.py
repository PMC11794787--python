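"""Reading and writing FAERS QDE-style ASCII tables and deletion lists.

Files are plain text: a header line naming the columns followed by
"$"-delimited data lines, one file per table per quarter with the naming
pattern ``<TABLE><yy>Q<q>.txt`` (e.g. ``DEMO23Q1.txt``).  Deletion lists
are one CASEID per line.  Malformed data lines never raise; they are
counted, logged and skipped.
"""

from __future__ import annotations

import glob
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

from .schemas import DELIMITER, schema_for

log = logging.getLogger(__name__)

_QUARTER_FILE_RE = re.compile(r"^(DEMO|DRUG|REAC|OUTC|THER)(\d{2}Q[1-4])\.txt$", re.I)


@dataclass
class QuarterBundle:
    """One quarter's worth of raw tables plus its deletion list.

    Child-table rows whose PRIMARYID does not appear in DEMO have already
    been dropped (``n_dropped_children`` counts them); this is logged, not
    fatal, mirroring the referential noise of real extracts.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    deleted_caseids: set[int] = field(default_factory=set)
    n_dropped_children: int = 0

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "DEMO": self.demo,
            "DRUG": self.drug,
            "REAC": self.reac,
            "OUTC": self.outc,
            "THER": self.ther,
        }


def _empty_table(table_name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in schema_for(table_name)})


def read_table(
    stream: TextIO, table_name: str, delimiter: str = DELIMITER
) -> pd.DataFrame:
    """Parse one FAERS-style ASCII table into a string DataFrame.

    The first line must be a header naming the columns.  Columns absent
    from the declared schema are ignored by name; schema columns absent
    from the file come back as empty strings.  Data lines whose field
    count does not match the header are skipped and counted.
    """
    columns = schema_for(table_name)
    header_line = stream.readline()
    if header_line == "":
        return _empty_table(table_name)
    header = [h.strip().lower() for h in header_line.rstrip("\r\n").split(delimiter)]
    n_fields = len(header)
    pos = {name: i for i, name in enumerate(header)}

    records: list[list[str]] = []
    n_skipped = 0
    for line in stream:
        line = line.rstrip("\r\n")
        if line == "":
            continue
        parts = line.split(delimiter)
        if len(parts) != n_fields:
            n_skipped += 1
            continue
        records.append([parts[pos[c]] if c in pos else "" for c in columns])
    if n_skipped:
        log.warning(
            "%s: skipped %d malformed line(s) (field count != %d)",
            table_name,
            n_skipped,
            n_fields,
        )
    if not records:
        return _empty_table(table_name)
    return pd.DataFrame(records, columns=columns, dtype=str)


def write_table(
    df: pd.DataFrame, stream: TextIO, table_name: str, delimiter: str = DELIMITER
) -> None:
    """Write a table in the same dialect ``read_table`` consumes."""
    columns = schema_for(table_name)
    stream.write(delimiter.join(columns) + "\n")
    if len(df) == 0:
        return
    body = df.reindex(columns=columns).fillna("").astype(str)
    for row in body.itertuples(index=False):
        stream.write(delimiter.join(row) + "\n")


def read_deletion_list(stream: TextIO) -> set[int]:
    """Parse a deletion report log: one CASEID per line, blanks ignored."""
    deleted: set[int] = set()
    n_bad = 0
    for line in stream:
        token = line.strip()
        if not token:
            continue
        try:
            deleted.add(int(token))
        except ValueError:
            n_bad += 1
    if n_bad:
        log.warning("deletion list: skipped %d non-numeric line(s)", n_bad)
    return deleted


def assemble_quarter(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    outc: pd.DataFrame,
    ther: pd.DataFrame,
    deletions: Iterable[int] = (),
) -> QuarterBundle:
    """Bundle per-table rows, dropping child rows orphaned from DEMO."""
    demo_ids = set(demo["primaryid"]) if len(demo) else set()
    dropped = 0
    children = {}
    for name, table in (("drug", drug), ("reac", reac), ("outc", outc), ("ther", ther)):
        if len(table):
            keep = table["primaryid"].isin(demo_ids)
            dropped += int((~keep).sum())
            table = table[keep].reset_index(drop=True)
        children[name] = table
    if dropped:
        log.warning("assemble_quarter: dropped %d orphaned child row(s)", dropped)
    return QuarterBundle(
        demo=demo.reset_index(drop=True),
        deleted_caseids=set(deletions),
        n_dropped_children=dropped,
        **children,
    )


def read_quarter_dir(directory: str, delimiter: str = DELIMITER) -> QuarterBundle:
    """Read every ``<TABLE><yy>Q<q>.txt`` under ``directory`` into one bundle.

    Multiple quarters are concatenated; deletion lists are any
    ``DELETED*.txt`` files found alongside.
    """
    parts: dict[str, list[pd.DataFrame]] = {t: [] for t in ("DEMO", "DRUG", "REAC", "OUTC", "THER")}
    for path in sorted(glob.glob(os.path.join(directory, "*.txt"))):
        m = _QUARTER_FILE_RE.match(os.path.basename(path))
        if not m:
            continue
        table_name = m.group(1).upper()
        with open(path, encoding="utf-8") as fh:
            parts[table_name].append(read_table(fh, table_name, delimiter))
    deletions: set[int] = set()
    for path in sorted(glob.glob(os.path.join(directory, "DELETED*.txt"))):
        with open(path, encoding="utf-8") as fh:
            deletions |= read_deletion_list(fh)

    def _concat(table_name: str) -> pd.DataFrame:
        frames = parts[table_name]
        if not frames:
            return _empty_table(table_name)
        return pd.concat(frames, ignore_index=True)

    return assemble_quarter(
        _concat("DEMO"), _concat("DRUG"), _concat("REAC"), _concat("OUTC"),
        _concat("THER"), deletions,
    )


def write_quarter_dir(
    bundle: QuarterBundle,
    directory: str,
    quarter_tag: str = "23Q1",
    delimiter: str = DELIMITER,
) -> None:
    """Write a bundle back out as one file per table plus a deletion list."""
    os.makedirs(directory, exist_ok=True)
    for table_name, table in bundle.tables().items():
        path = os.path.join(directory, f"{table_name}{quarter_tag}.txt")
        with open(path, "w", encoding="utf-8") as fh:
            write_table(table, fh, table_name, delimiter)
    with open(os.path.join(directory, f"DELETED{quarter_tag}.txt"), "w", encoding="utf-8") as fh:
        for caseid in sorted(bundle.deleted_caseids):
            fh.write(f"{caseid}\n")
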