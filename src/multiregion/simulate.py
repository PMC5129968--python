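"""Synthetic multiregion tumor sequencing summaries with known ground truth.

One simulated case mirrors the multiregion study design: a clonal tree
with trunk mutations (in every region), branch mutations (a proper subset
of regions) and region-private mutations; per-region read evidence drawn
binomially at the heterozygous-diploid expectation VAF = purity / 2;
coding-microsatellite repeat-length read histograms with a stutter null
and, at unstable loci, a slippage-shifted mixture; and a binned
tumor/normal depth track with piecewise-constant true copy states and an
optional differential GC bias on the tumor library.

Caller dropout (to exercise the evidence-rescue step downstream) is
discovery-conditioned: each mutation stays called in at least one region
where it is truly present, because a variant called nowhere never enters
any pipeline's candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import (
    MutationCall,
    calls_to_frame,
    write_evidence_tsv,
    write_maf_tsv,
    write_region_vcf,
)

#: Consequence mix for simulated exonic SNVs/indels. Chosen to resemble a
#: somatic exome spectrum (NS/S around 2.3 for SNVs, ~7% indels).
CONSEQUENCE_PROBS = {
    "missense": 0.57,
    "synonymous": 0.28,
    "nonsense": 0.04,
    "splicing": 0.02,
    "frameshift_indel": 0.05,
    "inframe_indel": 0.02,
    "other": 0.02,
}

_BASES = np.array(list("ACGT"))


def triangular_profile(center: int = 10, half_width: int = 2) -> dict[int, float]:
    """Symmetric triangular stutter null over the reference length +/- 2."""
    lengths = range(center - half_width, center + half_width + 1)
    weights = [half_width + 1 - abs(L - center) for L in lengths]
    total = float(sum(weights))
    return {L: w / total for L, w in zip(lengths, weights)}


@dataclass
class SimConfig:
    """Study-design parameters of one simulated multiregion case.

    Defaults follow the emulated design: three regional biopsies, tumor
    purity 0.7 (the study enrolled lesions with purity above 70%), mean
    exome depth 100x, and a 50/20/30 trunk/branch/private split.
    """

    n_regions: int = 3
    n_trunk: int = 500
    n_branch: int = 200
    n_private: int = 300
    purity: float | Sequence[float] = 0.7
    mean_depth: float = 100.0
    seq_error: float = 1e-3
    dropout: float = 0.0
    # microsatellites
    n_microsat: int = 2000
    n_msi_loci: int = 0
    slip_fraction: float = 0.5
    slip_shift: int = -2
    microsat_depth: float = 100.0
    ref_repeat_length: int = 10
    # depth track
    n_bins: int = 300
    bin_size: int = 100_000
    segment_spec: list[tuple[int, int, float]] = field(default_factory=list)
    gc_bias_amp: float = 0.0
    seed: int = 0

    def region_labels(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_regions)]

    def purities(self) -> np.ndarray:
        p = np.asarray(self.purity, dtype=float)
        if p.ndim == 0:
            p = np.repeat(p, self.n_regions)
        if len(p) != self.n_regions:
            raise ValueError("purity must be scalar or one value per region")
        return p

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        if min(self.n_trunk, self.n_branch, self.n_private) < 0:
            raise ValueError("mutation counts must be nonnegative")
        if self.n_regions < 3 and self.n_branch > 0:
            raise ValueError("branch (shared) mutations need at least 3 regions")
        p = self.purities()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("purity must be in [0, 1]")
        if self.mean_depth <= 0 or self.microsat_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0 <= self.seq_error < 1:
            raise ValueError("seq_error must be in [0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_msi_loci > self.n_microsat:
            raise ValueError("n_msi_loci cannot exceed n_microsat")
        if not 0 <= self.slip_fraction <= 1:
            raise ValueError("slip_fraction must be in [0, 1]")
        _check_segment_spec(self.segment_spec, self.n_bins)


def _check_segment_spec(spec: Sequence[tuple[int, int, float]], n_bins: int) -> None:
    prev_end = None
    for start, end, _ in sorted(spec):
        if not 0 <= start < end <= n_bins:
            raise ValueError(f"segment ({start}, {end}) outside [0, {n_bins})")
        if prev_end is not None and start < prev_end:
            raise ValueError("segment_spec ranges overlap")
        prev_end = end


@dataclass
class TruthSet:
    """Ground truth of one simulated case."""

    mutations: pd.DataFrame  # chrom,pos,ref,alt,gene,consequence,category,regions
    msi_locus_ids: list[str]
    breakpoints: list[int]  # bin indices of true copy-state changes

    def true_fractions(self) -> dict[str, float]:
        counts = self.mutations["category"].value_counts()
        n = len(self.mutations)
        return {c: counts.get(c, 0) / n for c in ("public", "shared", "private")}


@dataclass
class SimCase:
    """All tables of one simulated case, plus the truth."""

    config: SimConfig
    calls: dict[str, list[MutationCall]]
    evidence: pd.DataFrame
    microsat: pd.DataFrame
    depth_bins: pd.DataFrame
    truth: TruthSet

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ev_by_site_region = {
            (r.chrom, r.pos, r.ref, r.alt, r.region): (r.alt_count, r.ref_count)
            for r in self.evidence.itertuples()
        }
        for region, calls in self.calls.items():
            ev = {
                c.site: ev_by_site_region[c.site + (region,)]
                for c in calls
                if c.site + (region,) in ev_by_site_region
            }
            write_region_vcf(calls, outdir / f"calls_{region}.vcf", region, ev)
            write_maf_tsv(calls, outdir / f"calls_{region}.tsv")
        write_evidence_tsv(self.evidence, outdir / "evidence.tsv")
        self.microsat.to_csv(outdir / "microsat.tsv", sep="\t", index=False)
        self.depth_bins.to_csv(outdir / "depth_bins.tsv", sep="\t", index=False)
        self.truth.mutations.to_csv(outdir / "truth_mutations.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def simulate_read_counts(
    vaf: float, depth: int, seq_error: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial alt/ref read counts at a site.

    The per-read alt probability folds in sequencing error: a true-variant
    read is misread with probability ``seq_error`` and a reference read is
    misread as this alt with probability ``seq_error / 3``.
    """
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must be in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    p = vaf * (1 - seq_error) + (1 - vaf) * seq_error / 3
    alt = int(rng.binomial(depth, p)) if depth else 0
    return alt, depth - alt


def simulate_microsat_locus(
    null_profile: dict[int, float],
    is_msi: bool,
    slip_fraction: float,
    slip_shift: int,
    n_reads_tumor: int,
    n_reads_normal: int,
    rng: np.random.Generator,
) -> tuple[dict[int, int], dict[int, int]]:
    """Tumor and normal repeat-length histograms for one locus.

    The normal sample is drawn from the stutter null; an unstable tumor is
    drawn from the mixture (1 - slip_fraction) * null + slip_fraction *
    (null shifted by slip_shift repeat units).
    """
    if not null_profile:
        raise ValueError("null_profile is empty")
    total = sum(null_profile.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("null_profile must sum to 1")
    if n_reads_tumor <= 0 or n_reads_normal <= 0:
        raise ValueError("read counts must be positive")
    lengths = np.array(sorted(null_profile))
    probs = np.array([null_profile[int(L)] for L in lengths])

    normal = rng.multinomial(n_reads_normal, probs)
    normal_hist = {int(L): int(c) for L, c in zip(lengths, normal) if c}

    if is_msi and slip_fraction > 0:
        support = np.union1d(lengths, lengths + slip_shift)
        mix = np.zeros(len(support))
        for L, p in zip(lengths, probs):
            mix[np.searchsorted(support, L)] += (1 - slip_fraction) * p
            mix[np.searchsorted(support, L + slip_shift)] += slip_fraction * p
        tumor = rng.multinomial(n_reads_tumor, mix)
        tumor_hist = {int(L): int(c) for L, c in zip(support, tumor) if c}
    else:
        tumor = rng.multinomial(n_reads_tumor, probs)
        tumor_hist = {int(L): int(c) for L, c in zip(lengths, tumor) if c}
    return tumor_hist, normal_hist


def gc_bias_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth multiplicative coverage bias: 2**(amplitude * sin(2 pi gc))."""
    return np.exp2(amplitude * np.sin(2 * np.pi * np.asarray(gc, dtype=float)))


def simulate_depth_profile(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binned tumor/normal depths with GC bias and true copy states.

    The GC bias is differential: it perturbs the tumor library only, which
    is what makes the raw depth ratio GC-dependent and the GC-correction
    step downstream meaningful.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_bins
    gc = rng.uniform(0.3, 0.7, size=n)
    true_log2 = np.zeros(n)
    for start, end, value in config.segment_spec:
        true_log2[start:end] = value
    bias = gc_bias_factor(gc, config.gc_bias_amp)
    normal = rng.poisson(config.mean_depth, size=n)
    tumor = rng.poisson(config.mean_depth * np.exp2(true_log2) * bias)
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(n) * config.bin_size,
            "end": (np.arange(n) + 1) * config.bin_size,
            "gc": gc,
            "tumor_depth": tumor,
            "normal_depth": normal,
            "true_log2": true_log2,
        }
    )


# ---------------------------------------------------------------------------
# full case
# ---------------------------------------------------------------------------

def _draw_alleles(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if consequence in ("frameshift_indel",):
        return (ref + str(rng.choice(_BASES)), ref) if rng.random() < 0.5 else (
            ref,
            ref + str(rng.choice(_BASES)),
        )
    if consequence == "inframe_indel":
        ins = "".join(rng.choice(_BASES, size=3))
        return ref + ins, ref
    alt = str(rng.choice(_BASES[_BASES != ref]))
    return ref, alt


def simulate_case(config: SimConfig) -> SimCase:
    """Simulate all per-case tables plus the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = config.region_labels()
    purities = config.purities()
    R = config.n_regions

    n_total = config.n_trunk + config.n_branch + config.n_private
    categories = (
        ["public"] * config.n_trunk + ["shared"] * config.n_branch + ["private"] * config.n_private
    )
    consequences = rng.choice(
        list(CONSEQUENCE_PROBS), size=n_total, p=list(CONSEQUENCE_PROBS.values())
    )

    # unique positions across a synthetic exome
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n_total)])
    while True:
        positions = rng.integers(1, 200_000_000, size=n_total)
        if pd.DataFrame({"c": chroms, "p": positions}).duplicated().sum() == 0:
            break

    truth_rows = []
    calls: dict[str, list[MutationCall]] = {r: [] for r in regions}
    ev_rows = []
    for idx in range(n_total):
        cat = categories[idx]
        if cat == "public":
            present = list(range(R))
        elif cat == "shared":
            size = int(rng.integers(2, R))  # 2 .. R-1
            present = sorted(rng.choice(R, size=size, replace=False))
        else:
            present = [int(rng.integers(R))]
        # the realized category follows the region assignment (with a single
        # region every mutation is public by construction)
        if len(present) == R:
            cat = "public"
        elif len(present) == 1:
            cat = "private"
        csq = str(consequences[idx])
        ref, alt = _draw_alleles(rng, csq)
        gene = f"G{idx:05d}"
        pchange = ""
        call = MutationCall(
            chrom=str(chroms[idx]),
            pos=int(positions[idx]),
            ref=ref,
            alt=alt,
            gene=gene,
            consequence=csq,
            protein_change=pchange,
        )

        # read evidence in every region
        for r_idx, region in enumerate(regions):
            vaf = purities[r_idx] * 0.5 if r_idx in present else 0.0
            depth = int(rng.poisson(config.mean_depth))
            a, rcount = simulate_read_counts(vaf, depth, config.seq_error, rng)
            ev_rows.append(
                {
                    "chrom": call.chrom,
                    "pos": call.pos,
                    "ref": ref,
                    "alt": alt,
                    "region": region,
                    "alt_count": a,
                    "ref_count": rcount,
                }
            )

        # caller output with discovery-conditioned dropout
        called = [r for r in present if rng.random() >= config.dropout]
        if not called:
            called = [present[int(rng.integers(len(present)))]]
        for r_idx in called:
            region = regions[r_idx]
            calls[region].append(
                MutationCall(
                    chrom=call.chrom, pos=call.pos, ref=ref, alt=alt, gene=gene,
                    consequence=csq, protein_change=pchange, region=region,
                )
            )
        truth_rows.append(
            {
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": csq,
                "category": cat,
                "regions": ";".join(regions[i] for i in present),
            }
        )

    evidence = pd.DataFrame(ev_rows)

    # microsatellites: unstable loci are unstable in every region
    null_profile = triangular_profile(config.ref_repeat_length)
    msi_ids = [f"MS{idx:06d}" for idx in range(config.n_msi_loci)]
    ms_rows = []
    for idx in range(config.n_microsat):
        locus_id = f"MS{idx:06d}"
        is_msi = idx < config.n_msi_loci
        n_norm = max(1, int(rng.poisson(config.microsat_depth)))
        normal_done = False
        for region in regions:
            n_tum = max(1, int(rng.poisson(config.microsat_depth)))
            tumor_hist, normal_hist = simulate_microsat_locus(
                null_profile, is_msi, config.slip_fraction, config.slip_shift,
                n_tum, n_norm, rng,
            )
            for L, cnt in sorted(tumor_hist.items()):
                ms_rows.append(
                    {"locus_id": locus_id, "sample": f"tumor:{region}", "length": L, "read_count": cnt}
                )
            if not normal_done:
                for L, cnt in sorted(normal_hist.items()):
                    ms_rows.append(
                        {"locus_id": locus_id, "sample": "normal", "length": L, "read_count": cnt}
                    )
                normal_done = True
    microsat = pd.DataFrame(ms_rows, columns=["locus_id", "sample", "length", "read_count"])

    depth_bins = simulate_depth_profile(config, rng)
    breakpoints = sorted({s for s, _, _ in config.segment_spec} | {e for _, e, _ in config.segment_spec})
    breakpoints = [b for b in breakpoints if 0 < b < config.n_bins]

    truth = TruthSet(
        mutations=pd.DataFrame(truth_rows),
        msi_locus_ids=msi_ids,
        breakpoints=breakpoints,
    )
    return SimCase(
        config=config,
        calls=calls,
        evidence=evidence,
        microsat=microsat,
        depth_bins=depth_bins,
        truth=truth,
    )
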