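"""Cohort construction: demographics normalisation and report labelling.

The case/non-case design needs each deduplicated report classified along
several axes: does it mention the target drug, is the patient pediatric
(< 18 years), does any reaction map to a cardiovascular SOC (CVAE), was
the outcome fatal (outcome code DE), was cytokine release syndrome (CRS)
co-reported, and which ATC level-1 classes the concomitant medication
belongs to.  The counting unit throughout is the deduplicated report,
used as a patient proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import QuarterBundle
from .mappings import ATC1_LABELS, CARDIOVASCULAR_SOCS, CRS_PT

log = logging.getLogger(__name__)

#: Target-drug synonyms: INN, brand name and development code.
DEFAULT_SYNONYMS = ("TISAGENLECLEUCEL", "KYMRIAH", "CTL019", "CTL-019")

#: Conversion of FAERS age units to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_REPORTER_MAP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health professional",
    "HP": "other health professional",
    "RN": "other health professional",
    "CN": "consumer",
}


@dataclass
class CohortConfig:
    """Knobs for cohort identification.

    ``roles=None`` counts every DRUG role code (PS/SS/C/I) toward target
    identification; set ``roles=("PS", "SS")`` to restrict to suspect
    drugs.  ``comparator`` selects whether the non-case background is
    other-drug reports of any age ("all") or only pediatric ones
    ("pediatric").
    """

    synonyms: tuple[str, ...] = DEFAULT_SYNONYMS
    age_limit: float = 18.0
    roles: tuple[str, ...] | None = None
    comparator: str = "all"  # "all" | "pediatric"


def normalize_age(value: str, unit_code: str) -> float:
    """Convert a FAERS age value/unit pair to years; NaN when unusable."""
    try:
        v = float(str(value).strip())
    except (TypeError, ValueError):
        return float("nan")
    if v < 0:
        log.debug("negative age %r discarded", value)
        return float("nan")
    factor = AGE_UNIT_TO_YEARS.get(str(unit_code).strip().upper())
    if factor is None:
        return float("nan")
    return v * factor


def match_target_drug(names: Iterable[str], synonyms: Sequence[str] = DEFAULT_SYNONYMS) -> bool:
    """True iff any drug name/ingredient contains a synonym (case-insensitive)."""
    syn = [s.upper() for s in synonyms]
    for name in names:
        u = str(name).strip().upper()
        if any(s in u for s in syn):
            return True
    return False


@dataclass
class ReportData:
    """Typed per-report demographics plus raw child tables, post-dedup."""

    demo: pd.DataFrame  # primaryid, caseid, age_years, sex, country, reporter, event_dt, fda_dt
    drugs: pd.DataFrame
    reacs: pd.DataFrame  # primaryid, pt (deduplicated pairs)
    outcomes: pd.DataFrame
    ther: pd.DataFrame


def build_reports(bundle: QuarterBundle) -> ReportData:
    """Normalise a refined (deduplicated) bundle into the analysis model."""
    demo = bundle.demo
    age_years = np.array(
        [normalize_age(v, u) for v, u in zip(demo["age"], demo["age_cod"])]
    )
    sex = demo["sex"].str.strip().str.upper()
    sex = sex.where(sex.isin(["M", "F"]), "missing")
    reporter = (
        demo["occp_cod"].str.strip().str.upper().map(_REPORTER_MAP).fillna("missing")
    )
    typed = pd.DataFrame(
        {
            "primaryid": demo["primaryid"],
            "caseid": demo["caseid"],
            "age_years": age_years,
            "sex": sex.to_numpy(),
            "country": demo["occr_country"].str.strip().to_numpy(),
            "reporter": reporter.to_numpy(),
            "event_dt": demo["event_dt"].str.strip().to_numpy(),
            "fda_dt": pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(0).astype(int).to_numpy(),
        }
    )
    reacs = bundle.reac.assign(pt=bundle.reac["pt"].str.strip())
    reacs = reacs[reacs["pt"] != ""].drop_duplicates(["primaryid", "pt"])
    return ReportData(
        demo=typed.reset_index(drop=True),
        drugs=bundle.drug,
        reacs=reacs.reset_index(drop=True),
        outcomes=bundle.outc,
        ther=bundle.ther,
    )


def _target_ids(drugs: pd.DataFrame, config: CohortConfig) -> set[str]:
    if len(drugs) == 0:
        return set()
    rows = drugs
    if config.roles is not None:
        rows = rows[rows["role_cod"].str.strip().str.upper().isin(config.roles)]
    pattern = "|".join(s.upper() for s in config.synonyms)
    hit = rows["drugname"].str.upper().str.contains(pattern, regex=True) | rows[
        "prod_ai"
    ].str.upper().str.contains(pattern, regex=True)
    return set(rows.loc[hit.fillna(False), "primaryid"])


def classify(
    data: ReportData,
    ptmap: dict[str, str],
    atcmap: dict[str, str],
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Label every report; returns one row per primaryid.

    Columns: is_target, is_pediatric, is_cvae, is_fatal, has_crs and one
    boolean ``atc_<X>`` flag per ATC level-1 class seen in the supplied
    map plus ``atc_other`` for concomitant drugs absent from it.  PTs
    missing from the PT map count as non-CVAE and are tallied in the log.
    """
    config = config or CohortConfig()
    demo = data.demo
    labels = pd.DataFrame({"primaryid": demo["primaryid"]})

    target_ids = _target_ids(data.drugs, config)
    labels["is_target"] = demo["primaryid"].isin(target_ids)
    labels["is_pediatric"] = demo["age_years"].to_numpy() < config.age_limit

    pts = data.reacs["pt"].str.casefold()
    soc = pts.map(ptmap)
    n_unmapped = int(soc.isna().sum())
    if n_unmapped:
        log.info("classify: %d reaction row(s) with unmapped PT treated as non-CVAE", n_unmapped)
    cvae_ids = set(data.reacs.loc[soc.isin(CARDIOVASCULAR_SOCS), "primaryid"])
    crs_ids = set(data.reacs.loc[pts == CRS_PT.casefold(), "primaryid"])
    labels["is_cvae"] = demo["primaryid"].isin(cvae_ids)
    labels["has_crs"] = demo["primaryid"].isin(crs_ids)

    fatal_ids = set(
        data.outcomes.loc[
            data.outcomes["outc_cod"].str.strip().str.upper() == "DE", "primaryid"
        ]
    )
    labels["is_fatal"] = demo["primaryid"].isin(fatal_ids)

    # ATC flags from concomitant (non-target) drugs only: the target drug
    # itself would make its own class flag constant within the cohort.
    drugs = data.drugs
    if len(drugs):
        name_u = drugs["drugname"].str.strip().str.upper()
        ai_u = drugs["prod_ai"].str.strip().str.upper()
        syn = tuple(s.upper() for s in config.synonyms)
        is_target_row = name_u.str.contains("|".join(syn)) | ai_u.str.contains("|".join(syn))
        conc = drugs[~is_target_row.fillna(False)]
        atc1 = conc["drugname"].str.strip().str.upper().map(atcmap)
        atc1 = atc1.fillna(conc["prod_ai"].str.strip().str.upper().map(atcmap))
    else:
        conc = drugs
        atc1 = pd.Series(dtype=str)
    classes = sorted(set(atcmap.values()))
    for code in classes:
        ids = set(conc.loc[atc1 == code, "primaryid"])
        labels[f"atc_{code}"] = demo["primaryid"].isin(ids)
    other_ids = set(conc.loc[atc1.isna(), "primaryid"]) if len(conc) else set()
    labels["atc_other"] = demo["primaryid"].isin(other_ids)
    return labels


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation (quantile type 7)."""
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size == 0:
        return (float("nan"),) * 3
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


@dataclass
class Cohort:
    """Labelled pediatric target-drug cohort plus its comparator."""

    reports: pd.DataFrame  # demo columns + label columns, cohort members only
    comparator_ids: set[str]
    labels: pd.DataFrame  # labels for every deduplicated report
    summary: dict = field(default_factory=dict)


def _count_pct(series: pd.Series, categories: Sequence[str], denom: int) -> pd.DataFrame:
    counts = series.value_counts()
    rows = []
    for cat in categories:
        n = int(counts.get(cat, 0))
        rows.append({"category": cat, "n": n, "pct": 100.0 * n / denom if denom else float("nan")})
    return pd.DataFrame(rows)


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Descriptive summary of a labelled cohort (counts and percentages).

    Percentages are against the full cohort size, missing categories
    included, so each block sums to 100 up to rounding.
    """
    n = len(cohort)
    if n == 0:
        log.warning("summarize_cohort: empty cohort")
        return {"n": 0}
    cvae = cohort[cohort["is_cvae"]]
    fatal = cvae[cvae["is_fatal"]]
    q1, med, q3 = quartiles(cohort["age_years"])
    country_counts = cohort["country"].value_counts()
    summary = {
        "n": n,
        "n_cvae": len(cvae),
        "pct_cvae": 100.0 * len(cvae) / n,
        "n_non_cvae": n - len(cvae),
        "n_fatal_cvae": len(fatal),
        "pct_fatal_cvae": 100.0 * len(fatal) / len(cvae) if len(cvae) else float("nan"),
        "age_q1": q1,
        "age_median": med,
        "age_q3": q3,
        "sex": _count_pct(cohort["sex"], ["M", "F", "missing"], n),
        "reporter": _count_pct(
            cohort["reporter"],
            ["physician", "pharmacist", "other health professional", "consumer", "missing"],
            n,
        ),
        "country": pd.DataFrame(
            {
                "category": country_counts.index,
                "n": country_counts.to_numpy(),
                "pct": 100.0 * country_counts.to_numpy() / n,
            }
        ),
        "year": cohort.assign(year=cohort["fda_dt"] // 10000)["year"]
        .value_counts()
        .sort_index()
        .rename_axis("year")
        .reset_index(name="n"),
    }
    return summary


def build_cohort(
    data: ReportData,
    ptmap: dict[str, str],
    atcmap: dict[str, str],
    config: CohortConfig | None = None,
) -> Cohort:
    """Identify the pediatric target-drug cohort and its comparator.

    Cohort membership requires a target-drug mention and age strictly
    under the pediatric limit; reports with missing age are excluded.
    The comparator holds the non-cases: every deduplicated report of
    *other* drugs (optionally restricted to pediatric reports).  Target
    reports failing the age filter belong to neither group.
    """
    config = config or CohortConfig()
    labels = classify(data, ptmap, atcmap, config)
    merged = data.demo.merge(labels, on="primaryid")
    in_cohort = merged["is_target"] & merged["is_pediatric"].fillna(False)
    cohort_df = merged[in_cohort].reset_index(drop=True)
    comp = merged[~merged["is_target"]]
    if config.comparator == "pediatric":
        comp = comp[comp["is_pediatric"].fillna(False)]
    summary = summarize_cohort(cohort_df)
    return Cohort(
        reports=cohort_df,
        comparator_ids=set(comp["primaryid"]),
        labels=labels,
        summary=summary,
    )
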