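"""Curated multiregion gastric adenoma case fixture.

Five cases — three microsatellite-stable (MSS1-3) and two MSI-high
(MSI-H1/2), each with three regional biopsies (T1-T3) — transcribed as the
regional distribution of their driver gene events: coding mutations with
protein changes and consequences, called copy-number segments, a small
hotspot catalog, gene models and chromosome-arm boundaries. The fixture
exercises the evolution stage end to end: biallelic APC inactivation in
every case, convergent ARID2/APC hits, and hotspot mutations of KRAS,
ERBB2 and FBXW7 appearing off the trunk.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .copynumber import call_gain_loss
from .evolution import CaseEvolution, analyze_case, events_from_mutations, events_from_segments
from .variants import HotspotCatalog

REGIONS = ["T1", "T2", "T3"]
CASES = ["MSS1", "MSS2", "MSS3", "MSI-H1", "MSI-H2"]
MSS_CASES = ["MSS1", "MSS2", "MSS3"]


def _data(name: str) -> str:
    return str(resources.files("multiregion.data") / "adenoma_cases" / name)


def load_mutations() -> pd.DataFrame:
    return pd.read_csv(_data("mutations.tsv"), sep="\t")


def load_segments() -> pd.DataFrame:
    return pd.read_csv(_data("segments.tsv"), sep="\t")


def load_gene_models() -> pd.DataFrame:
    return pd.read_csv(
        _data("genes.bed"), sep="\t", names=["chrom", "start", "end", "gene"]
    )


def load_arm_table() -> pd.DataFrame:
    return pd.read_csv(_data("arms.tsv"), sep="\t")


def load_hotspots(hotspot_min_count: int = 5) -> HotspotCatalog:
    return HotspotCatalog.from_tsv(_data("hotspots.tsv"), hotspot_min_count)


def analyze_fixture_case(case: str) -> CaseEvolution:
    """Run the evolution stage on one fixture case."""
    muts = load_mutations()
    segs = load_segments()
    catalog = load_hotspots()
    case_muts = muts[muts["case"] == case]
    if case_muts.empty:
        raise ValueError(f"unknown case {case!r}; known: {CASES}")
    events = events_from_mutations(case_muts, catalog)
    case_segs = segs[segs["case"] == case]
    if not case_segs.empty:
        called = call_gain_loss(case_segs, load_arm_table())
        events += events_from_segments(called, load_gene_models())
    return analyze_case(case, events, REGIONS)


def analyze_all_cases() -> dict[str, CaseEvolution]:
    return {case: analyze_fixture_case(case) for case in CASES}
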