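"""Case-level evolutionary interpretation of multiregion mutation data.

From the regional distribution of functional events this module infers:

* biallelic inactivation of a gene in a region (two distinct
  loss-of-function mutations, or one plus an overlapping copy loss) — the
  Knudson two-hit configuration;
* convergent evolution — independent functional hits on the same gene
  whose region sets are disjoint (regionally exclusive multi-hits);
* the chronology strata: public events belong to the trunk (founding
  clone), shared events to branches, private events to single regions; the
  spatial categories stand in for temporal order (trunk before branch
  before private);
* a laminar region tree built greedily from the observed region subsets in
  decreasing mutation-count order, with non-nesting subsets surfaced as
  incompatibilities rather than resolved.

Phasing is not observable in exome data: two distinct LoF hits in the same
region are assumed to strike both alleles (reported as an assumption).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

EVENT_TYPES = ("LoF_mutation", "hotspot_missense", "missense", "copy_loss", "copy_gain")

#: Event types that count as functional hits for convergence detection.
FUNCTIONAL_HITS = frozenset({"LoF_mutation", "hotspot_missense", "copy_loss"})


@dataclass(frozen=True)
class GeneEvent:
    """One functional event on a gene, with the regions carrying it."""

    gene: str
    event_type: str
    regions: frozenset
    source: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.regions:
            raise ValueError(f"{self.gene} {self.source}: empty region set")


def stratum_of(event: GeneEvent, all_regions: frozenset) -> str:
    if not event.regions <= all_regions:
        raise ValueError(
            f"{event.gene} {self_source(event)}: regions {set(event.regions)} "
            f"outside case regions {set(all_regions)}"
        )
    if event.regions == all_regions:
        return "trunk"
    if len(event.regions) == 1:
        return "private"
    return "branch"


def self_source(event: GeneEvent) -> str:
    return event.source or event.event_type


def detect_biallelic_inactivation(
    gene: str, events: Sequence[GeneEvent], regions: Iterable[str]
) -> dict[str, tuple[bool, tuple[str, str] | None]]:
    """Per-region biallelic flag with the witnessing evidence pair.

    A region is biallelic for ``gene`` when it carries two distinct LoF
    mutations, or one LoF mutation plus a copy loss overlapping the gene.
    """
    gene_events = [e for e in events if e.gene == gene]
    out: dict[str, tuple[bool, tuple[str, str] | None]] = {}
    for region in sorted(regions):
        lof = sorted(
            (e for e in gene_events if e.event_type == "LoF_mutation" and region in e.regions),
            key=self_source,
        )
        loss = sorted(
            (e for e in gene_events if e.event_type == "copy_loss" and region in e.regions),
            key=self_source,
        )
        if len(lof) >= 2:
            out[region] = (True, (self_source(lof[0]), self_source(lof[1])))
        elif lof and loss:
            out[region] = (True, (self_source(lof[0]), self_source(loss[0])))
        else:
            out[region] = (False, None)
    return out


def detect_convergence(
    gene: str, events: Sequence[GeneEvent]
) -> tuple[bool, list[tuple[str, str]]]:
    """Convergent-evolution flag: >= 2 functional hits with disjoint regions.

    Returns the flag and every witnessing (event, event) pair, order
    independent of the input event order.
    """
    hits = sorted(
        (e for e in events if e.gene == gene and e.event_type in FUNCTIONAL_HITS),
        key=self_source,
    )
    witnesses = [
        (self_source(a), self_source(b))
        for i, a in enumerate(hits)
        for b in hits[i + 1 :]
        if not (a.regions & b.regions)
    ]
    return bool(witnesses), witnesses


def order_events(
    events: Sequence[GeneEvent], all_regions: Iterable[str]
) -> dict[str, list[GeneEvent]]:
    """Partition events into chronology strata trunk -> branch -> private.

    Within a stratum no order is asserted. Every event must have a region
    set inside the case's regions.
    """
    all_regions = frozenset(all_regions)
    strata: dict[str, list[GeneEvent]] = {"trunk": [], "branch": [], "private": []}
    for e in events:
        strata[stratum_of(e, all_regions)].append(e)
    for key in strata:
        strata[key].sort(key=lambda e: (e.gene, self_source(e)))
    return strata


def build_region_tree(
    subset_counts: Mapping[frozenset, int] | pd.Series,
) -> tuple[list[frozenset], list[tuple[frozenset, frozenset]]]:
    """Greedy laminar (perfect-phylogeny-like) region tree.

    ``subset_counts`` maps each observed region subset to its mutation
    count. Subsets are accepted in decreasing count order (ties broken by
    lexicographic region-set order) when they nest — are a subset,
    superset, or disjoint — with everything accepted so far; rejected
    subsets are returned flagged with the first accepted subset they
    conflict with.
    """
    items = sorted(
        ((frozenset(k), int(v)) for k, v in dict(subset_counts).items()),
        key=lambda kv: (-kv[1], tuple(sorted(kv[0]))),
    )
    if not items:
        raise ValueError("no region subsets supplied")
    accepted: list[frozenset] = []
    incompatible: list[tuple[frozenset, frozenset]] = []
    for subset, _count in items:
        conflict = next(
            (
                acc
                for acc in accepted
                if (subset & acc) and not (subset <= acc or acc <= subset)
            ),
            None,
        )
        if conflict is None:
            accepted.append(subset)
        else:
            incompatible.append((subset, conflict))
    return accepted, incompatible


def region_tree_from_matrix(pm) -> tuple[list[frozenset], list[tuple[frozenset, frozenset]]]:
    """Region tree from a presence matrix (regions must number >= 2)."""
    if len(pm.regions) < 2:
        raise ValueError("region tree needs at least 2 regions")
    subsets: dict[frozenset, int] = {}
    present = pm.present
    for i in range(pm.n_sites):
        row = present.iloc[i]
        subset = frozenset(r for r in pm.regions if row[r])
        if subset:
            subsets[subset] = subsets.get(subset, 0) + 1
    return build_region_tree(subsets)


@dataclass
class CaseEvolution:
    """Full evolutionary annotation of one case."""

    case: str
    regions: list[str]
    strata: dict[str, list[GeneEvent]]
    biallelic: dict[str, dict[str, tuple[bool, tuple[str, str] | None]]]
    convergent: dict[str, list[tuple[str, str]]]
    tree_accepted: list[frozenset]
    tree_incompatible: list[tuple[frozenset, frozenset]]

    def biallelic_genes(self) -> list[str]:
        """Genes biallelically inactivated in at least one region."""
        return sorted(
            g for g, per_region in self.biallelic.items()
            if any(flag for flag, _ in per_region.values())
        )

    def convergent_genes(self) -> list[str]:
        return sorted(self.convergent)

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "regions": self.regions,
            "strata": {
                s: [
                    {"gene": e.gene, "event_type": e.event_type,
                     "regions": sorted(e.regions), "source": e.source}
                    for e in evs
                ]
                for s, evs in self.strata.items()
            },
            "biallelic": {
                g: {r: {"flag": flag, "evidence": list(ev) if ev else None}
                    for r, (flag, ev) in per_region.items()}
                for g, per_region in self.biallelic.items()
            },
            "convergent": {g: [list(p) for p in pairs] for g, pairs in self.convergent.items()},
            "region_tree": {
                "accepted": [sorted(s) for s in self.tree_accepted],
                "incompatible": [
                    {"subset": sorted(a), "conflicts_with": sorted(b)}
                    for a, b in self.tree_incompatible
                ],
            },
            "assumptions": [
                "two distinct LoF hits in one region are assumed to hit both alleles (phase unknown)"
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def render_text(self) -> str:
        """Schematic text rendering: trunk -> branches -> private leaves."""
        lines = [f"case {self.case} (regions: {', '.join(self.regions)})"]
        for stratum in ("trunk", "branch", "private"):
            events = self.strata.get(stratum, [])
            lines.append(f"  [{stratum}] {len(events)} event(s)")
            for e in events:
                marks = []
                if e.gene in self.biallelic and any(
                    f for f, _ in self.biallelic[e.gene].values()
                ):
                    marks.append("biallelic")
                if e.gene in self.convergent:
                    marks.append("convergent")
                suffix = f"  <{','.join(marks)}>" if marks else ""
                lines.append(
                    f"    {e.gene} {e.event_type} [{';'.join(sorted(e.regions))}]"
                    f" {e.source}{suffix}"
                )
        if self.tree_incompatible:
            lines.append("  incompatible region subsets:")
            for a, b in self.tree_incompatible:
                lines.append(f"    {sorted(a)} conflicts with {sorted(b)}")
        return "\n".join(lines)


def analyze_case(
    case: str,
    events: Sequence[GeneEvent],
    regions: Sequence[str],
    subset_counts: Mapping[frozenset, int] | None = None,
) -> CaseEvolution:
    """Assemble the full CaseEvolution from a case's gene events."""
    regions = list(regions)
    strata = order_events(events, regions)
    genes = sorted({e.gene for e in events})
    biallelic = {g: detect_biallelic_inactivation(g, events, regions) for g in genes}
    convergent = {}
    for g in genes:
        flag, pairs = detect_convergence(g, events)
        if flag:
            convergent[g] = pairs
    if subset_counts is None:
        subset_counts = {}
        for e in events:
            subset_counts[e.regions] = subset_counts.get(e.regions, 0) + 1
    if len(regions) >= 2:
        accepted, incompat = build_region_tree(subset_counts)
    else:
        accepted, incompat = [frozenset(regions)], []
    return CaseEvolution(
        case=case,
        regions=regions,
        strata=strata,
        biallelic=biallelic,
        convergent=convergent,
        tree_accepted=accepted,
        tree_incompatible=incompat,
    )


# ---------------------------------------------------------------------------
# building GeneEvents from pipeline tables
# ---------------------------------------------------------------------------

def events_from_mutations(
    table: pd.DataFrame, catalog=None
) -> list[GeneEvent]:
    """GeneEvents from a categorized mutation table.

    Expects columns gene, consequence, protein_change and regions
    (semicolon-separated region labels). LoF consequences map to
    LoF_mutation; missense maps to hotspot_missense when the catalog says
    so; synonymous/other calls carry no event.
    """
    from .variants import LOF_CONSEQUENCES

    events = []
    for row in table.itertuples():
        regions = frozenset(str(row.regions).split(";"))
        pchange = "" if pd.isna(row.protein_change) else str(row.protein_change)
        source = f"{row.gene}:{pchange or row.consequence}"
        if row.consequence in LOF_CONSEQUENCES:
            etype = "LoF_mutation"
        elif row.consequence == "missense":
            etype = (
                "hotspot_missense"
                if catalog is not None and catalog.is_hotspot(str(row.gene), pchange)
                else "missense"
            )
        else:
            continue
        events.append(GeneEvent(str(row.gene), etype, regions, source))
    return events


def events_from_segments(
    segments: pd.DataFrame, gene_models: pd.DataFrame
) -> list[GeneEvent]:
    """Copy gain/loss GeneEvents from called segments and a gene-model BED.

    ``segments`` needs chrom, start, end, call and regions columns
    (semicolon-separated); ``gene_models`` is BED-like (chrom, start, end,
    gene; 0-based half-open). An event is emitted per (gene, segment) with
    >= 1 bp overlap.
    """
    events = []
    called = segments[segments["call"].isin(["gain", "loss"])]
    for seg in called.itertuples():
        regions = frozenset(str(seg.regions).split(";"))
        overlapping = gene_models[
            (gene_models["chrom"] == seg.chrom)
            & (gene_models["start"] < seg.end)
            & (gene_models["end"] > seg.start)
        ]
        etype = "copy_gain" if seg.call == "gain" else "copy_loss"
        scope = getattr(seg, "scope", "focal")
        for g in overlapping.itertuples():
            source = f"{g.gene}:{scope}_{seg.call}_{seg.chrom}:{seg.start}-{seg.end}"
            events.append(GeneEvent(str(g.gene), etype, regions, source))
    return events
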