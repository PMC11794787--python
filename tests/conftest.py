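import pandas as pd
import pytest

from faerspv.cohort import build_cohort, build_reports
from faerspv.dedup import refine
from faerspv.simulate import (
    GeneratorConfig,
    atc_map_frame,
    make_bundle,
    paper_shaped_fixture,
    pt_map_frame,
)


def frame_to_ptmap(df: pd.DataFrame) -> dict[str, str]:
    return {r["pt"].casefold(): r["soc"] for _, r in df.iterrows()}


def frame_to_atcmap(df: pd.DataFrame) -> dict[str, str]:
    return {r["drugname"].upper(): r["atc1"] for _, r in df.iterrows()}


@pytest.fixture(scope="session")
def fixture_analysis():
    """The deterministic worked-example bundle, refined and labelled."""
    bundle, ptf, atf = paper_shaped_fixture()
    refined, stats = refine(bundle)
    data = build_reports(refined)
    cohort = build_cohort(data, frame_to_ptmap(ptf), frame_to_atcmap(atf))
    return {
        "bundle": bundle,
        "data": data,
        "cohort": cohort,
        "ptmap": frame_to_ptmap(ptf),
        "atcmap": frame_to_atcmap(atf),
        "dedup_stats": stats,
    }


@pytest.fixture(scope="session")
def small_synthetic():
    """A small generated bundle with default study conditions."""
    config = GeneratorConfig(n_reports=2000)
    bundle, truth = make_bundle(config, seed=7)
    refined, stats = refine(bundle)
    data = build_reports(refined)
    cohort = build_cohort(
        data, frame_to_ptmap(pt_map_frame(config)), frame_to_atcmap(atc_map_frame())
    )
    return {
        "config": config,
        "bundle": bundle,
        "truth": truth,
        "refined": refined,
        "data": data,
        "cohort": cohort,
        "dedup_stats": stats,
    }
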