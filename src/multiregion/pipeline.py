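"""End-to-end per-case orchestration: calls -> genotyping -> ITH -> MSI -> CNV -> evolution."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .copynumber import (
    call_gain_loss,
    compute_log_ratio,
    detect_oscillation,
    gc_correct,
    segment,
    write_seg,
)
from .evolution import analyze_case, events_from_mutations, events_from_segments
from .genotyper import RescueThresholds, build_presence_matrix
from .ith import categorize_matrix, ith_summary
from .msi import call_msi_events, case_msi_status, classify_msi_status, loci_from_table, read_microsat_tsv
from .variants import HotspotCatalog, merge_candidate_sites, read_evidence_tsv, read_region_calls

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one case. Every threshold is echoed into
    the output metadata verbatim."""

    case: str = "case"
    regions: list[str] = field(default_factory=lambda: ["T1", "T2", "T3"])
    calls: dict[str, str] = field(default_factory=dict)  # region -> path
    evidence: str = ""
    microsat: str = ""
    depth_bins: str = ""
    hotspots: str = ""
    gene_models: str = ""
    arm_table: str = ""
    # thresholds
    min_alt_reads: int = 2
    min_vaf: float = 0.02
    min_depth: int = 10
    fdr_threshold: float = 0.05
    msi_min_reads: int = 20
    msih_min_events: int = 20
    msi_method: str = "asymptotic"
    msi_pooling: str = "pooled"  # pooled | per-region:<rule>
    target_size_mb: float = 50.0
    hotspot_min_count: int = 5
    seg_alpha: float = 0.01
    seg_min_bins: int = 5
    seg_n_perm: int = 1000
    gain_thresh: float = 0.3
    loss_thresh: float = -0.3
    arm_cover: float = 0.8
    min_switches: int = 8
    state_tol: float = 0.15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def thresholds(self) -> dict:
        skip = {"case", "regions", "calls", "evidence", "microsat", "depth_bins",
                "hotspots", "gene_models", "arm_table"}
        return {k: v for k, v in asdict(self).items() if k not in skip}


def run_case(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on one case and write the per-case report.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Stage failures propagate with the stage named.
    """
    if len(config.regions) < 2:
        raise ValueError("multiregion analysis needs at least 2 regions")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "case": config.case,
        "version": __version__,
        "thresholds": config.thresholds(),
    }

    # --- mutations: joint genotyping + ITH -------------------------------
    call_sets = {}
    for region in config.regions:
        path = config.calls.get(region)
        if path is None:
            raise FileNotFoundError(f"[calls] no call file configured for region {region}")
        if not Path(path).exists():
            raise FileNotFoundError(f"[calls] missing input file: {path}")
        call_sets[region] = read_region_calls(path, region)
    try:
        union = merge_candidate_sites(call_sets)
        evidence = read_evidence_tsv(config.evidence)
        thresholds = RescueThresholds(config.min_alt_reads, config.min_vaf, config.min_depth)
        pm = build_presence_matrix(union, evidence, thresholds)
        log.info("genotyping: %s", pm.counts())
        all_calls = [c for calls in call_sets.values() for c in calls]
        summary = ith_summary(pm, all_calls, config.target_size_mb)
        categories = categorize_matrix(pm)
    except Exception as exc:
        raise RuntimeError(f"[genotype/ith] {exc}") from exc
    report["genotyping"] = pm.counts()
    report["ith"] = json.loads(summary.to_json())
    cat_table = union.copy()
    cat_table["category"] = categories.to_numpy()
    cat_table["regions"] = [
        ";".join(r for r in pm.regions if pm.present.iloc[i][r]) for i in range(pm.n_sites)
    ]
    cat_table.drop(columns=["called_in"]).to_csv(outdir / "mutations_categorized.tsv",
                                                 sep="\t", index=False)
    pm.to_frame().to_csv(outdir / "presence_matrix.tsv", sep="\t", index=False)

    # --- MSI --------------------------------------------------------------
    msi_report = None
    if config.microsat:
        try:
            table = read_microsat_tsv(config.microsat)
            tumor_samples = [f"tumor:{r}" for r in config.regions]
            if config.msi_pooling == "pooled":
                loci = loci_from_table(table, tumor_samples)
                res = call_msi_events(
                    loci, config.fdr_threshold, config.msi_min_reads,
                    config.msi_method, seed=config.seed,
                )
                n_events = int(res["is_event"].sum())
                status = classify_msi_status(n_events, config.msih_min_events)
                msi_report = {
                    "pooling": "pooled",
                    "n_events": n_events,
                    "n_testable": int(res["testable"].sum()),
                    "n_untestable": int((~res["testable"]).sum()),
                    "status": status,
                }
                res.to_csv(outdir / "msi_loci.tsv", sep="\t", index=False)
            else:
                rule = config.msi_pooling.split(":", 1)[1] if ":" in config.msi_pooling else "majority"
                statuses, events = {}, {}
                for r, sample in zip(config.regions, tumor_samples):
                    res = call_msi_events(
                        loci_from_table(table, sample), config.fdr_threshold,
                        config.msi_min_reads, config.msi_method, seed=config.seed,
                    )
                    events[r] = int(res["is_event"].sum())
                    statuses[r] = classify_msi_status(events[r], config.msih_min_events)
                msi_report = {
                    "pooling": config.msi_pooling,
                    "per_region_events": events,
                    "per_region_status": statuses,
                    "status": case_msi_status(statuses, rule),
                }
        except Exception as exc:
            raise RuntimeError(f"[msi] {exc}") from exc
    report["msi"] = msi_report

    # --- copy number -------------------------------------------------------
    seg_called = None
    if config.depth_bins:
        try:
            bins = pd.read_csv(config.depth_bins, sep="\t")
            bins = compute_log_ratio(bins, min_normal_depth=config.min_depth)
            bins = gc_correct(bins)
            segs = segment(
                bins, alpha=config.seg_alpha, min_bins=config.seg_min_bins,
                n_perm=config.seg_n_perm, seed=config.seed,
            )
            arm_table = pd.read_csv(config.arm_table, sep="\t") if config.arm_table else None
            seg_called = call_gain_loss(
                segs, arm_table, config.gain_thresh, config.loss_thresh, config.arm_cover
            )
            oscillation = {
                chrom: detect_oscillation(grp, config.min_switches, config.state_tol)
                for chrom, grp in seg_called.groupby("chrom")
            }
            write_seg(seg_called, outdir / "segments.seg", config.case)
            report["copynumber"] = {
                "n_segments": len(seg_called),
                "n_gain": int((seg_called["call"] == "gain").sum()),
                "n_loss": int((seg_called["call"] == "loss").sum()),
                "oscillation": {
                    c: {"flag": bool(f), "run": int(n)} for c, (f, n) in oscillation.items()
                },
            }
        except Exception as exc:
            raise RuntimeError(f"[copynumber] {exc}") from exc

    # --- evolution ----------------------------------------------------------
    try:
        catalog = (
            HotspotCatalog.from_tsv(config.hotspots, config.hotspot_min_count)
            if config.hotspots
            else None
        )
        mut_events_table = cat_table.rename(columns={"regions": "regions"})
        events = events_from_mutations(mut_events_table, catalog)
        if seg_called is not None and config.gene_models:
            gene_models = pd.read_csv(
                config.gene_models, sep="\t", names=["chrom", "start", "end", "gene"]
            )
            segs_regions = seg_called.copy()
            segs_regions["regions"] = ";".join(config.regions)
            events += events_from_segments(segs_regions, gene_models)
        evo = analyze_case(config.case, events, config.regions)
    except Exception as exc:
        raise RuntimeError(f"[evolution] {exc}") from exc
    report["evolution"] = evo.to_dict()

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(render_report(report, evo))
    return report


def render_report(report: dict, evo=None) -> str:
    """Human-readable per-case summary."""
    lines = [f"# case {report['case']}"]
    ith = report.get("ith") or {}
    if ith:
        lines.append(
            "mutations: {n} total | public {p:.1%} shared {s:.1%} private {v:.1%}".format(
                n=ith["n_total"], p=ith["fraction_public"],
                s=ith["fraction_shared"], v=ith["fraction_private"],
            )
        )
        if ith.get("burden_per_mb") is not None:
            lines.append(f"burden: {ith['burden_per_mb']:.2f} mutations/Mb")
        if ith.get("ns_s_ratio") is not None:
            lines.append(f"NS/S ratio: {ith['ns_s_ratio']:.2f}")
    else:
        lines.append("mutations: none")
    msi = report.get("msi")
    if msi:
        lines.append(f"MSI status: {msi['status']} ({msi.get('n_events', 'per-region')} events)")
    cn = report.get("copynumber")
    if cn:
        lines.append(
            f"copy number: {cn['n_segments']} segments "
            f"({cn['n_gain']} gain, {cn['n_loss']} loss)"
        )
        for chrom, osc in cn["oscillation"].items():
            if osc["flag"]:
                lines.append(f"  chromothripsis-like oscillation on {chrom} (run {osc['run']})")
    if evo is not None:
        lines.append("")
        lines.append(evo.render_text())
    return "\n".join(lines) + "\n"
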