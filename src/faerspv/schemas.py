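"""Column schemas for FAERS Quarterly-Data-Extract-style ASCII tables.

Only the minimal field set the downstream analysis touches is declared;
extra columns present in real extracts are ignored by name at read time.
All values stay strings at the I/O layer because FAERS dates and ages are
dirty; typing happens downstream.
"""

from __future__ import annotations

#: Default FAERS QDE field delimiter.
DELIMITER = "$"

#: Declared column set per table, in canonical order.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occr_country",
        "occp_cod",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
}

TABLE_NAMES = tuple(TABLE_SCHEMAS)

#: FAERS outcome codes; DE (death) defines fatal reports.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


def schema_for(table_name: str) -> list[str]:
    """Return the declared column list for ``table_name``.

    Raises ``KeyError`` with the known table names for unknown tables.
    """
    try:
        return TABLE_SCHEMAS[table_name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown table {table_name!r}; expected one of {TABLE_NAMES}"
        ) from None
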