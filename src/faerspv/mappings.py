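"""User-supplied terminology mappings.

The licensed MedDRA dictionary cannot be redistributed, so the pipeline
takes a PT->SOC mapping as a plain TSV (columns ``pt``, ``soc``); any
table with those columns works, including the surrogate the synthetic
generator emits.  Concomitant drugs are grouped by ATC anatomical main
group (level 1, single letter) via a TSV with columns ``drugname``,
``atc1``.
"""

from __future__ import annotations

from typing import TextIO

import pandas as pd

#: SOCs whose PTs define a cardiovascular adverse event (CVAE).
CARDIOVASCULAR_SOCS = frozenset({"Cardiac disorders", "Vascular disorders"})

#: The CRS preferred term (matched case-insensitively, PT-exact).
CRS_PT = "Cytokine release syndrome"

#: Human-readable names for ATC level-1 codes used in report tables.
ATC1_LABELS = {
    "A": "Digestive and metabolic system drugs",
    "B": "Blood and hematopoietic organs medication",
    "C": "Cardiovascular system medications",
    "D": "Dermatological medications",
    "G": "Genitourinary system and sexual hormones",
    "H": "Systemic corticosteroids, excluding sexual hormones and insulin",
    "J": "Systemic anti-infective agents",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculoskeletal system medications",
    "N": "Nervous system medication",
    "P": "Antiparasitic, insecticidal, and anthelmintic drugs",
    "R": "Respiratory system medications",
    "S": "Sensory organ system medications",
    "V": "Other miscellaneous drugs",
}


def load_pt_map(stream: TextIO) -> dict[str, str]:
    """Load a PT->SOC TSV; the mapping must be a function (one SOC per PT)."""
    df = pd.read_csv(stream, sep="\t", dtype=str).fillna("")
    if not {"pt", "soc"}.issubset(df.columns):
        raise ValueError("PT map must have columns 'pt' and 'soc'")
    dup = df["pt"].str.casefold().duplicated()
    if dup.any():
        raise ValueError(f"PT map is not a function: duplicated PTs {sorted(df['pt'][dup])}")
    return {pt.strip().casefold(): soc.strip() for pt, soc in zip(df["pt"], df["soc"])}


def load_atc_map(stream: TextIO) -> dict[str, str]:
    """Load a drugname->ATC-level-1 TSV (letter codes A..V)."""
    df = pd.read_csv(stream, sep="\t", dtype=str).fillna("")
    if not {"drugname", "atc1"}.issubset(df.columns):
        raise ValueError("ATC map must have columns 'drugname' and 'atc1'")
    return {
        name.strip().upper(): code.strip().upper()
        for name, code in zip(df["drugname"], df["atc1"])
        if name.strip()
    }


def cardiovascular_pts(ptmap: dict[str, str]) -> list[str]:
    """PT keys (casefolded) mapping to a cardiovascular SOC."""
    return [pt for pt, soc in ptmap.items() if soc in CARDIOVASCULAR_SOCS]
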