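"""Mutation call sets, read evidence and functional classification.

Coordinate conventions: mutation positions are 1-based (VCF dialect);
all interval files (depth bins, gene models, chromosome arms) are
0-based half-open. :func:`to_zero_based` / :func:`to_one_based` are the
single conversion point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Closed consequence vocabulary. Everything downstream (loss-of-function
#: classes, NS/S ratios) is defined over these labels.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "splicing",
        "frameshift_indel",
        "inframe_indel",
        "synonymous",
        "other",
    }
)

#: Consequences counted as loss-of-function: nonsense and canonical-splice
#: point mutations plus out-of-frame (frameshift) indels. In-frame indels
#: are deliberately excluded.
LOF_CONSEQUENCES = frozenset({"nonsense", "splicing", "frameshift_indel"})

MAF_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "consequence",
    "region",
]


def to_zero_based(pos: int) -> int:
    """1-based inclusive coordinate -> 0-based half-open start."""
    return pos - 1


def to_one_based(start: int) -> int:
    """0-based half-open start -> 1-based inclusive coordinate."""
    return start + 1


@dataclass(frozen=True)
class MutationCall:
    """One somatic mutation call in one regional biopsy."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str
    protein_change: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(
                f"position must be >= 1 (got {self.pos} at {self.chrom}:{self.pos})"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos} ({self.ref})")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r} at "
                f"{self.chrom}:{self.pos}; allowed: {sorted(CONSEQUENCES)}"
            )

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES


class HotspotCatalog:
    """Catalog of recurrent (gene, protein change) pairs with occurrence counts.

    A missense call is a hotspot when its catalog count reaches
    ``hotspot_min_count`` (default 5 recurrences).
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], int] | None = None,
        hotspot_min_count: int = 5,
    ) -> None:
        self.entries: dict[tuple[str, str], int] = {}
        for key, count in (entries or {}).items():
            if count < 1:
                raise ValueError(f"occurrence count must be >= 1 for {key}")
            self.entries[key] = int(count)
        self.hotspot_min_count = hotspot_min_count

    @classmethod
    def from_tsv(cls, path: str | Path, hotspot_min_count: int = 5) -> "HotspotCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        entries = {
            (str(r.gene), str(r.protein_change)): int(r.count)
            for r in df.itertuples()
        }
        return cls(entries, hotspot_min_count)

    def count(self, gene: str, protein_change: str) -> int:
        return self.entries.get((gene, protein_change), 0)

    def is_hotspot(self, gene: str, protein_change: str) -> bool:
        return self.count(gene, protein_change) >= self.hotspot_min_count


def classify_consequence(call: MutationCall, catalog: HotspotCatalog | None = None) -> str:
    """Functional class of a call: LoF, hotspot_missense, missense, synonymous, other."""
    if call.consequence in LOF_CONSEQUENCES:
        return "LoF"
    if call.consequence == "missense":
        if catalog is not None and catalog.is_hotspot(call.gene, call.protein_change):
            return "hotspot_missense"
        return "missense"
    if call.consequence == "synonymous":
        return "synonymous"
    return "other"


def _annovar_map() -> dict[str, str]:
    """Translation of common annotator consequence strings to the vocabulary."""
    path = resources.files("multiregion.data") / "consequence_map.tsv"
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["source"], df["consequence"]))


def normalize_consequence(raw: str) -> str:
    """Map an annotator-style consequence string onto the closed vocabulary."""
    raw = raw.strip()
    if raw in CONSEQUENCES:
        return raw
    mapped = _annovar_map().get(raw)
    if mapped is None:
        raise ValueError(
            f"unknown consequence string {raw!r}; allowed: {sorted(CONSEQUENCES)} "
            "or a string listed in data/consequence_map.tsv"
        )
    return mapped


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_region_calls(
    path: str | Path, region: str, dialect: str | None = None
) -> list[MutationCall]:
    """Read one region's call set from VCF or MAF-like TSV.

    ``dialect`` is ``"vcf"`` or ``"tsv"``; inferred from the extension when
    omitted. Malformed records raise with the offending record named.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix == ".vcf" else "tsv"
    if dialect == "vcf":
        return _read_vcf(path, region)
    if dialect == "tsv":
        return _read_maf_tsv(path, region)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'vcf' or 'tsv')")


def _read_vcf(path: Path, region: str) -> list[MutationCall]:
    from cyvcf2 import VCF

    calls: list[MutationCall] = []
    vcf = VCF(str(path))
    try:
        for i, v in enumerate(vcf, start=1):
            try:
                calls.append(
                    MutationCall(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=v.ALT[0],
                        gene=v.INFO.get("GENE", ""),
                        protein_change=v.INFO.get("PCHANGE", "") or "",
                        consequence=normalize_consequence(v.INFO.get("CSQ", "other")),
                        region=region,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} record {i}: {exc}") from exc
    finally:
        vcf.close()
    if not calls:
        log.warning("no mutation records in %s", path)
    return calls


def _read_maf_tsv(path: Path, region: str) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        log.warning("no mutation records in %s", path)
        return []
    missing = set(MAF_COLUMNS) - {"region"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(), start=2):  # 1 header line
        try:
            calls.append(
                MutationCall(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    protein_change="" if pd.isna(row.protein_change) else str(row.protein_change),
                    consequence=normalize_consequence(str(row.consequence)),
                    region=region,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change (HGVS-p)">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_region_vcf(
    calls: Sequence[MutationCall],
    path: str | Path,
    sample: str,
    evidence: Mapping[tuple[str, int, str, str], tuple[int, int]] | None = None,
) -> None:
    """Write a minimal single-sample VCF 4.2 with per-site AD (ref, alt)."""
    chroms = sorted({c.chrom for c in calls}, key=_chrom_sort_key)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for c in sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos)):
            ad = "."
            if evidence is not None and c.site in evidence:
                alt_n, ref_n = evidence[c.site]
                ad = f"{ref_n},{alt_n}"
            info = f"GENE={c.gene};CSQ={c.consequence}"
            if c.protein_change:
                info += f";PCHANGE={c.protein_change}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\tAD\t{ad}\n"
            )


def calls_to_frame(calls: Iterable[MutationCall]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "gene": c.gene,
            "protein_change": c.protein_change,
            "consequence": c.consequence,
            "region": c.region,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=MAF_COLUMNS)


def write_maf_tsv(calls: Sequence[MutationCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def _chrom_sort_key(chrom: str):
    body = chrom.removeprefix("chr")
    return (0, int(body)) if body.isdigit() else (1, body)


def merge_candidate_sites(call_sets: Mapping[str, Sequence[MutationCall]]) -> pd.DataFrame:
    """Union of candidate sites across regions, ordered by (chrom, pos).

    Returns one row per distinct (chrom, pos, ref, alt) with the gene
    annotation and the set of regions that originally called it
    (``called_in``, a frozenset). Conflicting gene annotations at one
    site raise.
    """
    if not call_sets:
        raise ValueError("need at least one region call set")
    sites: dict[tuple, dict] = {}
    for region, calls in call_sets.items():
        for c in calls:
            entry = sites.setdefault(
                c.site,
                {
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "ref": c.ref,
                    "alt": c.alt,
                    "gene": c.gene,
                    "protein_change": c.protein_change,
                    "consequence": c.consequence,
                    "called_in": set(),
                },
            )
            if entry["gene"] != c.gene:
                raise ValueError(
                    f"conflicting gene annotation at {c.chrom}:{c.pos} "
                    f"({entry['gene']!r} vs {c.gene!r})"
                )
            entry["called_in"].add(region)
    rows = sorted(
        sites.values(), key=lambda e: (_chrom_sort_key(e["chrom"]), e["pos"], e["ref"], e["alt"])
    )
    df = pd.DataFrame(rows)
    df["called_in"] = df["called_in"].map(frozenset)
    return df


# ---------------------------------------------------------------------------
# read evidence
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = ["chrom", "pos", "ref", "alt", "region", "alt_count", "ref_count"]


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing evidence columns {sorted(missing)}")
    if (df[["alt_count", "ref_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative read counts")
    return df


def write_evidence_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False)
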