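"""Synthetic FAERS-like data with known ground truth.

Two generators live here:

* :func:`generate_population` / :func:`make_bundle` / :func:`generate` —
  a seeded stochastic generator emitting quarterly-extract-shaped tables
  (DEMO/DRUG/REAC/OUTC/THER, "$"-delimited) with the structural dirt the
  pipeline must survive: duplicated CASEIDs across versions, a deletion
  list, ages in mixed units, partial event dates — and with injected,
  recoverable statistical structure: per-PT reporting-odds multipliers
  on target-drug reports, CRS co-reporting with cardiovascular events,
  log-normal time-to-onset per outcome group, and a logistic fatality
  model driven by age and a respiratory co-medication flag.

* :func:`paper_shaped_fixture` — a fully deterministic bundle whose
  cohort marginals equal a published pediatric CAR-T safety table set
  (568 target reports, 187 CVAE of which 57 fatal, country/sex/reporter
  margins), used for worked-example tests.

All randomness flows through one ``numpy.random.default_rng(seed)``;
fixed seed and config give byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import QuarterBundle, write_quarter_dir
from .mappings import CRS_PT

TARGET_NAME = "TISAGENLECLEUCEL"
TARGET_BRAND = "KYMRIAH"

#: (pt, soc, background report rate) — cardiovascular terms first.
DEFAULT_PT_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("Hypotension", "Vascular disorders", 0.008),
    ("Tachycardia", "Cardiac disorders", 0.004),
    ("Hypertension", "Vascular disorders", 0.006),
    ("Shock", "Vascular disorders", 0.0015),
    ("Cardiac arrest", "Cardiac disorders", 0.0015),
    ("Cardiac failure", "Cardiac disorders", 0.002),
    ("Pericardial effusion", "Cardiac disorders", 0.0015),
    ("Capillary leak syndrome", "Vascular disorders", 0.001),
    ("Mitral valve disease", "Cardiac disorders", 0.0008),
    ("Pyrexia", "General disorders and administration site conditions", 0.10),
    ("Nausea", "Gastrointestinal disorders", 0.09),
    ("Headache", "Nervous system disorders", 0.07),
    ("Neutropenia", "Blood and lymphatic system disorders", 0.04),
    ("Vomiting", "Gastrointestinal disorders", 0.05),
)

#: One representative concomitant drug per ATC level-1 class.
DEFAULT_ATC_CATALOG: dict[str, str] = {
    "OMEPRAZOLE": "A",
    "FILGRASTIM": "B",
    "AMLODIPINE": "C",
    "MUPIROCIN": "D",
    "OXYBUTYNIN": "G",
    "DEXAMETHASONE": "H",
    "MEROPENEM": "J",
    "METHOTREXATE": "L",
    "IBUPROFEN": "M",
    "LEVETIRACETAM": "N",
    "MEBENDAZOLE": "P",
    "SALBUTAMOL": "R",
    "TIMOLOL": "S",
}

_CLASS_DRUG = {v: k for k, v in DEFAULT_ATC_CATALOG.items()}

#: Primary suspect drugs for comparator reports (absent from the ATC map).
COMPARATOR_DRUGS = ("RITUXIMAB", "CYCLOPHOSPHAMIDE", "VINCRISTINE", "INFLIXIMAB", "BLINATUMOMAB")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic spontaneous-report database.

    Defaults emulate a pediatric CAR-T pharmacovigilance setting: the
    target drug is overwhelmingly reported in children, cardiovascular
    PTs carry elevated reporting odds on target reports (hypotension 30,
    tachycardia 13, hypertension 4), CRS accompanies 91% of CVAE
    reports, onset is log-normal with medians of 4 / 2 / 7 days for
    fatal-CVAE / non-fatal-CVAE / non-CVAE, and death among CVAE reports
    follows a logistic model with a protective age slope (-0.0909 per
    year) and a respiratory co-medication log-odds of 0.6.
    """

    n_reports: int = 5000
    target_share: float = 0.05
    pediatric_share_target: float = 0.95
    pediatric_share_other: float = 0.15
    pt_catalog: tuple[tuple[str, str, float], ...] = DEFAULT_PT_CATALOG
    injected_ror: dict[str, float] = field(
        default_factory=lambda: {"Hypotension": 30.0, "Tachycardia": 13.0, "Hypertension": 4.0}
    )
    crs_given_cvae: float = 0.91
    crs_given_target_noncvae: float = 0.50
    crs_background: float = 0.01
    # per-class prevalence of concomitant medication flags
    class_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "A": 0.12, "B": 0.06, "C": 0.08, "D": 0.04, "G": 0.03, "H": 0.12,
            "J": 0.15, "L": 0.18, "M": 0.06, "N": 0.15, "P": 0.02, "R": 0.10,
            "S": 0.02,
        }
    )
    other_drug_prevalence: float = 0.10
    # multiplicative covariate effect on cardiovascular PT odds (target reports)
    cvae_covariate_log_or: dict[str, float] = field(default_factory=lambda: {"N": 1.53})
    # fatality model within target CVAE reports
    fatal_intercept: float = -0.85
    fatal_age_slope: float = -0.0909  # per year, centred at age 10
    fatal_log_or: dict[str, float] = field(default_factory=lambda: {"R": 0.60})
    fatal_rate_background: float = 0.08
    tto_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fatal_cvae": (4.0, 1.1),
            "nonfatal_cvae": (2.0, 1.1),
            "non_cvae": (7.0, 1.1),
        }
    )
    duplicate_rate: float = 0.10
    deletion_rate: float = 0.02
    partial_date_rate: float = 0.10
    start_missing_rate: float = 0.05

    def validate(self) -> None:
        rates = [
            self.target_share, self.pediatric_share_target, self.pediatric_share_other,
            self.crs_given_cvae, self.crs_given_target_noncvae, self.crs_background,
            self.duplicate_rate, self.deletion_rate, self.partial_date_rate,
            self.start_missing_rate, self.other_drug_prevalence,
            self.fatal_rate_background,
        ] + list(self.class_prevalence.values())
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates/fractions must lie in [0, 1]")
        catalog = {pt: rate for pt, _, rate in self.pt_catalog}
        for pt, mult in self.injected_ror.items():
            if mult <= 0:
                raise ValueError(f"odds multiplier for {pt!r} must be > 0")
            if catalog.get(pt, 0.0) <= 0.0:
                raise ValueError(
                    f"injected multiplier for {pt!r} needs a positive background rate"
                )
        for pt, _, rate in self.pt_catalog:
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"background rate for {pt!r} out of range")

    def cv_pts(self) -> list[str]:
        return [
            pt for pt, soc, _ in self.pt_catalog
            if soc in ("Cardiac disorders", "Vascular disorders")
        ]


@dataclass
class GroundTruth:
    """What the generator injected, for recovery tests."""

    injected_ror: dict[str, float]
    tto_medians: dict[str, float]
    fatality_log_or: dict[str, float]
    cvae_covariate_or: dict[str, float]
    duplicate_caseids: list[int] = field(default_factory=list)
    removed_primaryids: list[int] = field(default_factory=list)
    deleted_caseids: list[int] = field(default_factory=list)
    n_reports: int = 0
    n_target: int = 0
    n_cohort: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class Population:
    """In-memory per-report truth before file formatting."""

    reports: pd.DataFrame  # caseid, primaryid, is_target, is_pediatric, age_years, ...
    pt_flags: pd.DataFrame  # one boolean column per catalog PT plus CRS
    truth: GroundTruth


def _covariate_strata(config: GeneratorConfig) -> list[tuple[float, float]]:
    """(weight, exp(eta)) over the joint co-medication flag distribution,
    restricted to the classes carrying a CVAE covariate effect."""
    strata = [(1.0, 1.0)]
    for cls, beta in config.cvae_covariate_log_or.items():
        p = config.class_prevalence.get(cls, 0.0)
        strata = [(w * (1.0 - p), m) for w, m in strata] + [
            (w * p, m * float(np.exp(beta))) for w, m in strata
        ]
    return strata


def _calibrate_multiplier(config: GeneratorConfig, base_odds: float, rho: float) -> float:
    """Solve for q so the *marginal* target-vs-background reporting odds
    ratio equals ``rho`` when per-report odds are base_odds*q*exp(eta).

    The OR is non-collapsible over covariate strata: applying ``rho``
    within each stratum leaves the marginal OR below ``rho``, so the
    generator's contract that ``injected_ror`` is the recoverable
    marginal quantity needs this one-dimensional root solve.
    """
    from scipy import optimize

    strata = _covariate_strata(config)
    p_target = base_odds * rho / (1.0 + base_odds * rho)

    def mixture_gap(q: float) -> float:
        p = sum(w * (base_odds * q * m) / (1.0 + base_odds * q * m) for w, m in strata)
        return p - p_target

    return float(optimize.brentq(mixture_gap, rho * 1e-4, rho * 1e4, xtol=1e-12))


def generate_population(config: GeneratorConfig, seed: int) -> Population:
    """Draw the per-report truth table (vectorised; no file formatting)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_reports

    caseid = 10_000_001 + np.arange(n)
    primaryid = caseid * 10 + 1
    is_target = rng.random(n) < config.target_share
    ped_prob = np.where(is_target, config.pediatric_share_target, config.pediatric_share_other)
    is_pediatric = rng.random(n) < ped_prob
    age_years = np.where(
        is_pediatric,
        np.round(rng.uniform(0.3, 17.9, n), 1),
        np.round(rng.uniform(18.0, 80.0, n), 1),
    )

    # concomitant medication class flags
    classes = sorted(config.class_prevalence)
    flags = {c: rng.random(n) < config.class_prevalence[c] for c in classes}
    other_flag = rng.random(n) < config.other_drug_prevalence

    # covariate effect on cardiovascular PT odds, normalised
    eta = np.zeros(n)
    for cls, beta in config.cvae_covariate_log_or.items():
        eta += beta * flags.get(cls, np.zeros(n, dtype=bool))
    cov_mult = np.exp(eta)

    cv_set = set(config.cv_pts())
    pt_cols: dict[str, np.ndarray] = {}
    for pt, soc, rate in config.pt_catalog:
        odds = rate / (1.0 - rate)
        mult = np.ones(n)
        if pt in cv_set:
            rho = config.injected_ror.get(pt, 1.0)
            q = _calibrate_multiplier(config, odds, rho)
            mult = np.where(is_target, q * cov_mult, 1.0)
        p = odds * mult / (1.0 + odds * mult)
        pt_cols[pt] = rng.random(n) < p

    is_cvae = np.zeros(n, dtype=bool)
    for pt in cv_set:
        is_cvae |= pt_cols[pt]

    # every analyzable report carries at least one reaction
    any_pt = np.zeros(n, dtype=bool)
    for col in pt_cols.values():
        any_pt |= col
    pt_cols["Pyrexia"] = pt_cols["Pyrexia"] | ~any_pt

    crs_p = np.where(
        is_target & is_cvae,
        config.crs_given_cvae,
        np.where(is_target, config.crs_given_target_noncvae, config.crs_background),
    )
    has_crs = rng.random(n) < crs_p
    pt_cols[CRS_PT] = has_crs

    # fatality: logistic model on target CVAE reports, background elsewhere
    lin = (
        config.fatal_intercept
        + config.fatal_age_slope * (age_years - 10.0)
    )
    for cls, beta in config.fatal_log_or.items():
        lin = lin + beta * flags.get(cls, np.zeros(n, dtype=bool))
    p_fatal = np.where(
        is_target & is_cvae,
        1.0 / (1.0 + np.exp(-lin)),
        config.fatal_rate_background,
    )
    is_fatal = rng.random(n) < p_fatal

    # time to onset by outcome group
    group = np.where(~is_cvae, "non_cvae", np.where(is_fatal, "fatal_cvae", "nonfatal_cvae"))
    days = np.zeros(n)
    for g, (median, sigma) in config.tto_lognormal.items():
        mask = group == g
        days[mask] = rng.lognormal(np.log(median), sigma, mask.sum())
    days = np.maximum(np.round(days), 0).astype(int)

    start_ord = rng.integers(
        np.datetime64("2018-01-01").astype(int),
        np.datetime64("2023-06-30").astype(int),
        n,
    )
    start = start_ord.astype("datetime64[D]")
    event = start + days.astype("timedelta64[D]")
    fda = event + rng.integers(10, 120, n).astype("timedelta64[D]")

    sex = rng.choice(["M", "F", ""], size=n, p=[0.59, 0.375, 0.035])
    country = rng.choice(
        ["US", "JP", "CA", "ES", "AU", "GB", "FR", "DE"],
        size=n,
        p=[0.62, 0.08, 0.06, 0.05, 0.04, 0.05, 0.05, 0.05],
    )
    occp = rng.choice(["MD", "PH", "OT", "CN", ""], size=n, p=[0.546, 0.241, 0.097, 0.109, 0.007])

    partial_event = rng.random(n) < config.partial_date_rate
    missing_start = rng.random(n) < config.start_missing_rate

    reports = pd.DataFrame(
        {
            "caseid": caseid,
            "primaryid": primaryid,
            "is_target": is_target,
            "is_pediatric": is_pediatric,
            "age_years": age_years,
            "sex": sex,
            "country": country,
            "occp": occp,
            "is_cvae": is_cvae,
            "has_crs": has_crs,
            "is_fatal": is_fatal,
            "tto_days": days,
            "start": start,
            "event": event,
            "fda": fda,
            "partial_event": partial_event,
            "missing_start": missing_start,
            "other_drug": other_flag,
            **{f"atc_{c}": flags[c] for c in classes},
        }
    )
    truth = GroundTruth(
        injected_ror=dict(config.injected_ror),
        tto_medians={g: m for g, (m, _) in config.tto_lognormal.items()},
        fatality_log_or={"age": config.fatal_age_slope, **config.fatal_log_or},
        cvae_covariate_or={c: float(np.exp(b)) for c, b in config.cvae_covariate_log_or.items()},
        n_reports=n,
        n_target=int(is_target.sum()),
        n_cohort=int((is_target & is_pediatric).sum()),
    )
    return Population(reports=reports, pt_flags=pd.DataFrame(pt_cols), truth=truth)


def population_reacs(pop: Population) -> pd.DataFrame:
    """Long (primaryid, pt) pairs from the boolean PT flags."""
    pid = pop.reports["primaryid"].astype(str).to_numpy()
    frames = []
    for pt in pop.pt_flags.columns:
        mask = pop.pt_flags[pt].to_numpy()
        if mask.any():
            frames.append(pd.DataFrame({"primaryid": pid[mask], "pt": pt}))
    if not frames:
        return pd.DataFrame({"primaryid": pd.Series(dtype=str), "pt": pd.Series(dtype=str)})
    return pd.concat(frames, ignore_index=True)


def cohort_comparator_ids(pop: Population) -> tuple[set[str], set[str]]:
    """Target-pediatric cohort ids vs everything else (as strings)."""
    r = pop.reports
    in_cohort = (r["is_target"] & r["is_pediatric"]).to_numpy()
    pid = r["primaryid"].astype(str).to_numpy()
    return set(pid[in_cohort]), set(pid[~in_cohort])


def _dates_to_str(values: np.ndarray, partial: np.ndarray | None = None) -> np.ndarray:
    s = np.char.replace(
        np.datetime_as_string(values.astype("datetime64[D]"), unit="D"), "-", ""
    )
    if partial is not None:
        # truncate to YYYYMM precision where the date is only partial
        s = np.where(partial, np.array([d[:6] for d in s]), s)
    return s


def _format_age(age_years: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Emit ages in mixed units (YR/MON/DY/DEC) as real extracts do."""
    n = age_years.size
    unit = rng.choice(["YR", "MON", "DY", "DEC"], size=n, p=[0.7, 0.15, 0.1, 0.05])
    # months/days only plausible for young patients
    unit = np.where((unit == "MON") & (age_years >= 5), "YR", unit)
    unit = np.where((unit == "DY") & (age_years >= 2), "YR", unit)
    value = np.empty(n, dtype=object)
    for u, factor in (("YR", 1.0), ("MON", 12.0), ("DY", 365.25), ("DEC", 0.1)):
        mask = unit == u
        value[mask] = np.char.mod("%g", np.round(age_years[mask] * factor, 2))
    return value.astype(str), unit


def population_to_bundle(
    pop: Population, config: GeneratorConfig, seed: int
) -> tuple[QuarterBundle, GroundTruth]:
    """Format a population as raw string tables, injecting duplicates and
    a deletion list, and finish the ground-truth bookkeeping."""
    rng = np.random.default_rng(seed + 1_000_003)
    r = pop.reports
    n = len(r)
    truth = pop.truth

    age_value, age_cod = _format_age(r["age_years"].to_numpy(), rng)
    event_str = _dates_to_str(r["event"].to_numpy(), r["partial_event"].to_numpy())
    fda_str = _dates_to_str(r["fda"].to_numpy())
    pid_str = r["primaryid"].astype(str).to_numpy()
    cid_str = r["caseid"].astype(str).to_numpy()

    demo = pd.DataFrame(
        {
            "primaryid": pid_str,
            "caseid": cid_str,
            "fda_dt": fda_str,
            "event_dt": event_str,
            "age": age_value,
            "age_cod": age_cod,
            "sex": r["sex"].to_numpy(),
            "occr_country": r["country"].to_numpy(),
            "occp_cod": r["occp"].to_numpy(),
        }
    )

    # DRUG: one primary-suspect row per report plus concomitant class drugs
    is_target = r["is_target"].to_numpy()
    primary_name = np.where(
        is_target,
        np.where(rng.random(n) < 0.5, TARGET_NAME, TARGET_BRAND),
        rng.choice(COMPARATOR_DRUGS, size=n),
    )
    primary_ai = np.where(is_target, TARGET_NAME, primary_name)
    drug_parts = [
        pd.DataFrame(
            {
                "primaryid": pid_str,
                "caseid": cid_str,
                "drug_seq": "1",
                "role_cod": "PS",
                "drugname": primary_name,
                "prod_ai": primary_ai,
            }
        )
    ]
    seq = np.full(n, 2)
    for cls in sorted(config.class_prevalence):
        mask = r[f"atc_{cls}"].to_numpy()
        if mask.any():
            drug_parts.append(
                pd.DataFrame(
                    {
                        "primaryid": pid_str[mask],
                        "caseid": cid_str[mask],
                        "drug_seq": seq[mask].astype(str),
                        "role_cod": "C",
                        "drugname": _CLASS_DRUG[cls],
                        "prod_ai": _CLASS_DRUG[cls],
                    }
                )
            )
            seq = seq + mask
    other_mask = r["other_drug"].to_numpy()
    if other_mask.any():
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid_str[other_mask],
                    "caseid": cid_str[other_mask],
                    "drug_seq": seq[other_mask].astype(str),
                    "role_cod": "C",
                    "drugname": "HERBAL PREPARATION",
                    "prod_ai": "",
                }
            )
        )
    drug = pd.concat(drug_parts, ignore_index=True)

    reac = population_reacs(pop).copy()
    reac.insert(1, "caseid", reac["primaryid"].map(dict(zip(pid_str, cid_str))))

    is_fatal = r["is_fatal"].to_numpy()
    outc_cod = np.where(is_fatal, "DE", np.where(rng.random(n) < 0.3, "HO", "OT"))
    outc = pd.DataFrame({"primaryid": pid_str, "caseid": cid_str, "outc_cod": outc_cod})

    start_str = _dates_to_str(r["start"].to_numpy())
    has_start = ~r["missing_start"].to_numpy()
    ther = pd.DataFrame(
        {
            "primaryid": pid_str[has_start],
            "caseid": cid_str[has_start],
            "dsg_drug_seq": "1",
            "start_dt": start_str[has_start],
        }
    )

    # duplicate versions: same CASEID, later FDA_DT, higher PRIMARYID;
    # dedup must drop the originals, which GroundTruth records.
    k_dup = int(round(config.duplicate_rate * n))
    dup_idx = np.sort(rng.choice(n, size=k_dup, replace=False)) if k_dup else np.array([], dtype=int)
    if k_dup:
        new_pid = (r["caseid"].to_numpy()[dup_idx] * 10 + 2).astype(str)
        old_pid = pid_str[dup_idx]
        remap = dict(zip(old_pid, new_pid))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["primaryid"] = new_pid
        dup_demo["fda_dt"] = _dates_to_str(
            (r["fda"].to_numpy()[dup_idx] + np.timedelta64(30, "D"))
        )
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        def _duplicate_children(table: pd.DataFrame) -> pd.DataFrame:
            sel = table[table["primaryid"].isin(remap)].copy()
            sel["primaryid"] = sel["primaryid"].map(remap)
            return pd.concat([table, sel], ignore_index=True)

        drug = _duplicate_children(drug)
        reac = _duplicate_children(reac)
        outc = _duplicate_children(outc)
        ther = _duplicate_children(ther)
        truth.duplicate_caseids = [int(c) for c in cid_str[dup_idx]]
        truth.removed_primaryids = [int(p) for p in old_pid]

    k_del = int(round(config.deletion_rate * n))
    del_idx = rng.choice(n, size=k_del, replace=False) if k_del else np.array([], dtype=int)
    deleted = {int(c) for c in cid_str[del_idx]}
    truth.deleted_caseids = sorted(deleted)

    bundle = QuarterBundle(
        demo=demo, drug=drug, reac=reac[["primaryid", "caseid", "pt"]],
        outc=outc, ther=ther, deleted_caseids=deleted,
    )
    return bundle, truth


def pt_map_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = [{"pt": pt, "soc": soc} for pt, soc, _ in config.pt_catalog]
    rows.append({"pt": CRS_PT, "soc": "Immune system disorders"})
    return pd.DataFrame(rows)


def atc_map_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [{"drugname": d, "atc1": c} for d, c in sorted(DEFAULT_ATC_CATALOG.items())]
    )


def make_bundle(config: GeneratorConfig, seed: int) -> tuple[QuarterBundle, GroundTruth]:
    """Generate an in-memory bundle (no disk I/O)."""
    pop = generate_population(config, seed)
    return population_to_bundle(pop, config, seed)


def generate(config: GeneratorConfig, out_dir: str, seed: int) -> GroundTruth:
    """Generate and write a full synthetic quarter to ``out_dir``.

    Emits the five ASCII tables, a deletion list, the PT->SOC and
    drug->ATC mapping TSVs, and ``ground_truth.json``.
    """
    bundle, truth = make_bundle(config, seed)
    os.makedirs(out_dir, exist_ok=True)
    write_quarter_dir(bundle, out_dir, quarter_tag="23Q1")
    pt_map_frame(config).to_csv(os.path.join(out_dir, "ptmap.tsv"), sep="\t", index=False)
    atc_map_frame().to_csv(os.path.join(out_dir, "atcmap.tsv"), sep="\t", index=False)
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    return truth


def simulate_logistic(
    n: int,
    log_ors: Sequence[float],
    seed: int,
    prevalence: float = 0.3,
    intercept: float = -1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary covariates with known log-odds effects and logistic outcome.

    Returns (X with intercept column, y); the true coefficient vector is
    ``[intercept, *log_ors]``.
    """
    rng = np.random.default_rng(seed)
    Xc = (rng.random((n, len(log_ors))) < prevalence).astype(float)
    eta = intercept + Xc @ np.asarray(log_ors, dtype=float)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return np.column_stack([np.ones(n), Xc]), y


# ---------------------------------------------------------------------------
# Deterministic worked-example fixture
# ---------------------------------------------------------------------------


def _fill(pairs: Sequence[tuple[object, int]]) -> np.ndarray:
    out: list[object] = []
    for value, count in pairs:
        out.extend([value] * count)
    return np.asarray(out, dtype=object)


def _ramp(n: int, anchors: Sequence[tuple[float, float]]) -> np.ndarray:
    """Deterministic sorted values whose type-7 quantiles sit near anchors."""
    xs = [a for a, _ in anchors]
    ys = [b for _, b in anchors]
    pos = np.linspace(0, 1, n)
    return np.interp(pos, xs, ys)


def paper_shaped_fixture() -> tuple[QuarterBundle, pd.DataFrame, pd.DataFrame]:
    """A deterministic bundle reproducing the published cohort marginals.

    568 pediatric target-drug reports — 187 CVAE (57 fatal, 130
    non-fatal) and 381 non-CVAE — with country, sex, receipt-year and
    reporter margins matching the published demographic tables, per-PT
    CRS-overlap and mortality counts consistent with the published
    rates (e.g. cardiac arrest 1/6 fatal, shock 6/9, hypotension
    118/131 CRS), plus 1,500 comparator reports so disproportionality
    is computable.  Returns (bundle, pt_map_frame, atc_map_frame).
    """
    n_cohort = 568
    # cohort layout: [0,57) fatal CVAE, [57,187) non-fatal CVAE, [187,568) non-CVAE
    fatal = np.zeros(n_cohort, dtype=bool)
    fatal[0:57] = True
    cvae = np.zeros(n_cohort, dtype=bool)
    cvae[0:187] = True

    sex = np.concatenate(
        [
            _fill([("M", 39), ("F", 16), ("", 2)]),
            _fill([("M", 77), ("F", 48), ("", 5)]),
            _fill([("M", 219), ("F", 149), ("", 13)]),
        ]
    )
    country = np.concatenate(
        [
            _fill([("US", 45), ("CA", 4), ("GB", 2), ("AU", 2), ("JP", 1), ("FR", 1), ("DE", 1), ("IT", 1)]),
            _fill([("US", 111), ("ES", 5), ("CA", 1), ("GB", 2), ("AU", 1), ("JP", 2), ("FR", 3), ("DE", 3), ("IT", 2)]),
            _fill([("US", 278), ("JP", 19), ("CA", 15), ("ES", 12), ("AU", 9), ("FR", 16), ("DE", 16), ("IT", 16)]),
        ]
    )
    year = np.concatenate(
        [
            _fill([(2018, 7), (2019, 8), (2020, 13), (2021, 6), (2022, 17), (2023, 6)]),
            _fill([(2018, 15), (2019, 15), (2020, 30), (2021, 26), (2022, 32), (2023, 12)]),
            _fill([(2017, 5), (2018, 27), (2019, 62), (2020, 117), (2021, 49), (2022, 74), (2023, 47)]),
        ]
    ).astype(int)
    occp = np.concatenate(
        [
            _fill([("MD", 19), ("OT", 10), ("CN", 6), ("PH", 21), ("", 1)]),
            _fill([("MD", 65), ("OT", 11), ("CN", 10), ("PH", 43), ("", 1)]),
            _fill([("MD", 226), ("OT", 34), ("CN", 46), ("PH", 73), ("", 2)]),
        ]
    )
    age = np.concatenate(
        [
            np.round(_ramp(57, [(0, 1), (0.25, 4), (0.5, 7), (0.75, 14), (1, 17)])),
            np.round(_ramp(130, [(0, 1), (0.25, 8), (0.5, 11), (0.75, 14), (1, 17)])),
            np.round(_ramp(381, [(0, 1), (0.25, 6), (0.5, 11), (0.75, 14), (1, 17)])),
        ]
    ).astype(int)

    # per-PT assignment inside the CVAE block (local indices 0..186);
    # CRS is true for CVAE indices < 170 (170/187 co-reporting)
    crs = np.zeros(n_cohort, dtype=bool)
    crs[0:170] = True
    crs[187 : 187 + 150] = True  # CRS also occurs without CVAE
    pt_assign: dict[str, list[int]] = {
        "Hypotension": list(range(0, 38)) + list(range(57, 137)) + list(range(170, 183)),
        "Tachycardia": list(range(19, 50)) + list(range(137, 166)) + list(range(179, 187)),
        "Shock": list(range(50, 56)) + list(range(166, 169)),
        "Cardiac arrest": [56] + list(range(165, 170)),
        "Cardiac failure": list(range(0, 3)) + list(range(57, 62)),
        "Pericardial effusion": list(range(3, 6)) + list(range(62, 64)),
        "Hypertension": list(range(6, 8)) + list(range(64, 76)),
        "Capillary leak syndrome": list(range(8, 12)) + list(range(76, 82)) + list(range(170, 172)),
        "Mitral valve disease": list(range(12, 14)) + list(range(82, 85)) + list(range(172, 174)),
    }
    non_cv_cycle = ("Pyrexia", "Nausea", "Headache", "Neutropenia", "Vomiting")
    for i in range(187, n_cohort):
        pt_assign.setdefault(non_cv_cycle[i % 5], []).append(i)
    fatal_non_cvae = list(range(187, 225))  # 38 fatal non-CVAE reports
    fatal[fatal_non_cvae] = True

    def _spread(start: int, stop: int, count: int, phase: int) -> list[int]:
        """Evenly spaced distinct indices in [start, stop); deterministic.

        Spreading (rather than contiguous blocks) keeps co-medication
        flags close to independent of each other within outcome groups,
        so the fixture's multivariate fit is well conditioned while the
        group-wise marginal counts stay exact.
        """
        size = stop - start
        base = np.floor(np.arange(count) * size / count).astype(int)
        return sorted(start + (base + phase) % size)

    # per class: (count in fatal CVAE, non-fatal CVAE, non-CVAE)
    comed_counts = {
        "LEVETIRACETAM": (18, 42, 35),   # nervous system, enriched in CVAE
        "SALBUTAMOL": (20, 15, 30),      # respiratory, enriched in fatal
        "OMEPRAZOLE": (20, 30, 50),
        "DEXAMETHASONE": (30, 40, 70),
        "MEROPENEM": (20, 40, 70),
        "FILGRASTIM": (10, 20, 30),
    }
    comeds: dict[str, list[int]] = {}
    for phase, (drugname, (k_f, k_nf, k_nc)) in enumerate(sorted(comed_counts.items())):
        comeds[drugname] = (
            _spread(0, 57, k_f, 5 * phase)
            + _spread(57, 187, k_nf, 11 * phase)
            + _spread(187, 568, k_nc, 29 * phase)
        )

    tto_days = np.concatenate(
        [
            np.round(_ramp(57, [(0, 1), (0.25, 1), (0.5, 4), (0.75, 12.5), (1, 60)])),
            np.round(_ramp(130, [(0, 0), (0.25, 1), (0.5, 2), (0.75, 4), (1, 10)])),
            np.round(_ramp(381, [(0, 0), (0.25, 2), (0.5, 7), (0.75, 54), (1, 200)])),
        ]
    ).astype(int)

    caseid = 20_000_001 + np.arange(n_cohort)
    primaryid = caseid * 10 + 1
    start = np.array([np.datetime64(f"{y}-01-10") for y in year])
    event = start + tto_days.astype("timedelta64[D]")
    fda = event + np.timedelta64(30, "D")

    def ds(values):
        return np.char.replace(np.datetime_as_string(values.astype("datetime64[D]"), unit="D"), "-", "")

    pid = primaryid.astype(str)
    cid = caseid.astype(str)
    demo_rows = pd.DataFrame(
        {
            "primaryid": pid,
            "caseid": cid,
            "fda_dt": ds(fda),
            "event_dt": ds(event),
            "age": age.astype(str),
            "age_cod": "YR",
            "sex": sex.astype(str),
            "occr_country": country.astype(str),
            "occp_cod": occp.astype(str),
        }
    )

    drug_parts = [
        pd.DataFrame(
            {
                "primaryid": pid,
                "caseid": cid,
                "drug_seq": "1",
                "role_cod": "PS",
                "drugname": TARGET_NAME,
                "prod_ai": TARGET_NAME,
            }
        )
    ]
    for seq, (drugname, idx) in enumerate(sorted(comeds.items()), start=2):
        idx = sorted(set(idx))
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid[idx],
                    "caseid": cid[idx],
                    "drug_seq": str(seq),
                    "role_cod": "C",
                    "drugname": drugname,
                    "prod_ai": drugname,
                }
            )
        )

    reac_parts = []
    for pt, idx in sorted(pt_assign.items()):
        idx = sorted(set(idx))
        reac_parts.append(pd.DataFrame({"primaryid": pid[idx], "caseid": cid[idx], "pt": pt}))
    crs_idx = np.flatnonzero(crs)
    reac_parts.append(pd.DataFrame({"primaryid": pid[crs_idx], "caseid": cid[crs_idx], "pt": CRS_PT}))

    outc_rows = pd.DataFrame(
        {"primaryid": pid, "caseid": cid, "outc_cod": np.where(fatal, "DE", "OT")}
    )
    ther_rows = pd.DataFrame(
        {"primaryid": pid, "caseid": cid, "dsg_drug_seq": "1", "start_dt": ds(start)}
    )

    # comparator block: 1,500 reports on other drugs, mostly adult
    n_comp = 1500
    c_caseid = 21_000_001 + np.arange(n_comp)
    c_pid = (c_caseid * 10 + 1).astype(str)
    c_cid = c_caseid.astype(str)
    comp_cv = {
        "Hypotension": range(0, 15),
        "Tachycardia": range(15, 27),
        "Hypertension": range(27, 36),
        "Shock": range(36, 38),
        "Cardiac arrest": range(38, 40),
        "Cardiac failure": range(40, 43),
        "Pericardial effusion": range(43, 45),
        "Capillary leak syndrome": range(45, 46),
        "Mitral valve disease": range(46, 47),
    }
    comp_age = np.where(np.arange(n_comp) % 7 == 0, 10, 35)
    comp_demo = pd.DataFrame(
        {
            "primaryid": c_pid,
            "caseid": c_cid,
            "fda_dt": "20210615",
            "event_dt": "20210501",
            "age": comp_age.astype(str),
            "age_cod": "YR",
            "sex": np.where(np.arange(n_comp) % 2 == 0, "M", "F"),
            "occr_country": "US",
            "occp_cod": "MD",
        }
    )
    comp_drug = pd.DataFrame(
        {
            "primaryid": c_pid,
            "caseid": c_cid,
            "drug_seq": "1",
            "role_cod": "PS",
            "drugname": [COMPARATOR_DRUGS[i % len(COMPARATOR_DRUGS)] for i in range(n_comp)],
            "prod_ai": "",
        }
    )
    comp_reac_parts = []
    for pt, rng_ in sorted(comp_cv.items()):
        idx = list(rng_)
        comp_reac_parts.append(pd.DataFrame({"primaryid": c_pid[idx], "caseid": c_cid[idx], "pt": pt}))
    comp_other = [non_cv_cycle[i % 5] for i in range(n_comp)]
    comp_reac_parts.append(pd.DataFrame({"primaryid": c_pid, "caseid": c_cid, "pt": comp_other}))
    crs_comp = list(range(0, 10))
    comp_reac_parts.append(
        pd.DataFrame({"primaryid": c_pid[crs_comp], "caseid": c_cid[crs_comp], "pt": CRS_PT})
    )
    comp_outc = pd.DataFrame(
        {
            "primaryid": c_pid,
            "caseid": c_cid,
            "outc_cod": np.where(np.arange(n_comp) < 100, "DE", "OT"),
        }
    )

    bundle = QuarterBundle(
        demo=pd.concat([demo_rows, comp_demo], ignore_index=True).astype(str),
        drug=pd.concat(drug_parts + [comp_drug], ignore_index=True).astype(str),
        reac=pd.concat(reac_parts + comp_reac_parts, ignore_index=True).astype(str),
        outc=pd.concat([outc_rows, comp_outc], ignore_index=True).astype(str),
        ther=ther_rows.astype(str),
        deleted_caseids=set(),
    )
    config = GeneratorConfig()
    return bundle, pt_map_frame(config), atc_map_frame()


def write_fixture(out_dir: str) -> None:
    """Write the deterministic fixture bundle and its mapping TSVs."""
    bundle, ptmap, atcmap = paper_shaped_fixture()
    os.makedirs(out_dir, exist_ok=True)
    write_quarter_dir(bundle, out_dir, quarter_tag="23Q1")
    ptmap.to_csv(os.path.join(out_dir, "ptmap.tsv"), sep="\t", index=False)
    atcmap.to_csv(os.path.join(out_dir, "atcmap.tsv"), sep="\t", index=False)
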