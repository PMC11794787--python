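"""End-to-end orchestration: ingest -> dedup -> cohort -> signals -> TTO
-> overlap -> regression, with a machine-readable results bundle.

Stage outputs are plain CSV/JSON so they diff cleanly; floats are
printed at 4 decimals in CSVs and kept at full precision in JSON.  A
MANIFEST file lists completed stages so partial runs are inspectable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    CohortConfig,
    DEFAULT_SYNONYMS,
    ReportData,
    build_cohort,
    build_reports,
)
from .dedup import DedupStats, refine
from .io import read_quarter_dir
from .mappings import cardiovascular_pts, load_atc_map, load_pt_map
from .onset import compare_groups, compute_tto
from .overlap import overlap_frame, overlap_table
from .regression import build_design, results_frame, two_stage
from .signals import screen_signals, signals_frame

log = logging.getLogger(__name__)

FLOAT_FMT = "%.4f"


@dataclass
class RunConfig:
    input_dir: str
    ptmap_path: str
    atcmap_path: str
    out_dir: str
    synonyms: tuple[str, ...] = DEFAULT_SYNONYMS
    comparator: str = "all"
    zero_correction: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synonyms" in raw:
            raw["synonyms"] = tuple(raw["synonyms"])
        return cls(**raw)


@dataclass
class PipelineState:
    """Everything the stages share, for reuse by the CLI subcommands."""

    data: ReportData
    cohort: Cohort
    ptmap: dict[str, str]
    atcmap: dict[str, str]
    dedup_stats: DedupStats
    input_rows: int


def load_and_label(config: RunConfig) -> PipelineState:
    """Ingest quarters, refine (dedup + deletions) and label the cohort."""
    bundle = read_quarter_dir(config.input_dir)
    input_rows = len(bundle.demo)
    refined, stats = refine(bundle)
    data = build_reports(refined)
    with open(config.ptmap_path, encoding="utf-8") as fh:
        ptmap = load_pt_map(fh)
    with open(config.atcmap_path, encoding="utf-8") as fh:
        atcmap = load_atc_map(fh)
    cc = CohortConfig(synonyms=config.synonyms, comparator=config.comparator)
    cohort = build_cohort(data, ptmap, atcmap, cc)
    return PipelineState(
        data=data, cohort=cohort, ptmap=ptmap, atcmap=atcmap,
        dedup_stats=stats, input_rows=input_rows,
    )


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis and write the results bundle to ``out_dir``.

    Returns the summary dict.  On a stage failure the MANIFEST of
    completed stages is still written before the error propagates.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    completed: list[str] = []
    manifest_path = os.path.join(config.out_dir, "MANIFEST")
    summary: dict = {"software": {"name": "faerspv", "version": __version__}}

    def _manifest() -> None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(completed) + ("\n" if completed else ""))

    try:
        state = load_and_label(config)
        completed.append("ingest+dedup+cohort")
        cohort_df = state.cohort.reports
        summary["dedup"] = state.dedup_stats.as_dict()
        summary["input_rows"] = state.input_rows
        s = state.cohort.summary
        summary["cohort"] = {
            k: s.get(k)
            for k in (
                "n", "n_cvae", "pct_cvae", "n_non_cvae", "n_fatal_cvae",
                "pct_fatal_cvae", "age_median", "age_q1", "age_q3",
            )
        }
        _write_csv(cohort_df, os.path.join(config.out_dir, "cohort.csv"))
        for key in ("sex", "reporter", "country", "year"):
            if key in s:
                _write_csv(s[key], os.path.join(config.out_dir, f"summary_{key}.csv"))

        cohort_ids = set(cohort_df["primaryid"])
        results = screen_signals(
            cohort_ids,
            state.cohort.comparator_ids,
            state.data.reacs,
            pts=None,
            ptmap=state.ptmap,
            zero_correction=config.zero_correction,
        )
        _write_csv(signals_frame(results), os.path.join(config.out_dir, "signals.csv"))
        summary["signals"] = {
            "n_screened": len(results),
            "n_signals": sum(r.is_signal for r in results),
        }
        completed.append("signals")

        tto, excl = compute_tto(state.data, cohort_ids, config.synonyms)
        cvae_ids = set(cohort_df.loc[cohort_df["is_cvae"], "primaryid"])
        fatal_ids = set(
            cohort_df.loc[cohort_df["is_cvae"] & cohort_df["is_fatal"], "primaryid"]
        )
        tto_result = {
            "exclusions": dataclasses.asdict(excl),
            "cvae_vs_non_cvae": compare_groups(
                tto, {"CVAE": cvae_ids, "non-CVAE": cohort_ids - cvae_ids}
            ),
            "fatal_vs_nonfatal_cvae": compare_groups(
                tto, {"fatal": fatal_ids, "non-fatal": cvae_ids - fatal_ids}
            ),
        }
        with open(os.path.join(config.out_dir, "tto.json"), "w", encoding="utf-8") as fh:
            json.dump(tto_result, fh, indent=2)
        summary["tto"] = tto_result
        completed.append("tto")

        cv_pts_in_map = set(cardiovascular_pts(state.ptmap))
        observed = state.data.reacs.loc[
            state.data.reacs["primaryid"].isin(cvae_ids), "pt"
        ]
        seen: dict[str, str] = {}
        for p in observed:
            if p.casefold() in cv_pts_in_map:
                seen.setdefault(p.casefold(), p)
        rows = overlap_table(cohort_df, state.data.reacs, sorted(seen.values()))
        _write_csv(overlap_frame(rows), os.path.join(config.out_dir, "overlap.csv"))
        summary["overlap"] = {"n_pts": len(rows)}
        completed.append("overlap")

        for outcome, fname, t_test in (
            ("cvae", "regression_cvae.csv", False),
            ("fatal_within_cvae", "regression_fatal.csv", True),
        ):
            try:
                design, y = build_design(cohort_df, outcome=outcome)
                uni, multi = two_stage(design, y, age_t_test=t_test)
                _write_csv(
                    results_frame(uni + multi), os.path.join(config.out_dir, fname)
                )
                summary[f"regression_{outcome}"] = {
                    "n": int(len(y)),
                    "n_selected": len(
                        {r.variable for r in multi}
                    ),
                }
            except ValueError as exc:
                log.warning("regression %s skipped: %s", outcome, exc)
                summary[f"regression_{outcome}"] = {"skipped": str(exc)}
        completed.append("regression")

        with open(os.path.join(config.out_dir, "summary.json"), "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, default=float)
        completed.append("summary")
        return summary
    finally:
        _manifest()
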