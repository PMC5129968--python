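"""Quantify how read-evidence rescue protects ITH estimates from caller dropout.

For each simulated case of the cohort (see 01_simulate_cohort.py) the
public/shared/private composition is computed twice — using the raw caller
output and after joint genotyping with evidence rescue — and compared with
the ground truth; an extra dropout experiment (20% per-region caller
dropout, 100 seeds) measures the error distribution of both estimators.

Writes results/ith_summary.tsv and results/rescue_experiment.tsv.

Run: python analysis/02_ith_rescue.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

from multiregion.genotyper import build_presence_matrix
from multiregion.ith import ith_summary
from multiregion.simulate import SimConfig, simulate_case
from multiregion.variants import merge_candidate_sites


def fractions(case, rescue):
    union = merge_candidate_sites(case.calls)
    pm = build_presence_matrix(union, case.evidence, rescue=rescue)
    s = ith_summary(pm, [c for calls in case.calls.values() for c in calls])
    return s


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # architectures match 01_simulate_cohort.py (duplicated so each driver
    # stands alone; microsatellites are skipped here)
    rows = []
    cohort_specs = {
        "SIM-MSS1": dict(n_trunk=22, n_branch=40, n_private=95),
        "SIM-MSS2": dict(n_trunk=7, n_branch=42, n_private=121),
        "SIM-MSS3": dict(n_trunk=2, n_branch=50, n_private=108),
        "SIM-MSIH1": dict(n_trunk=575, n_branch=345, n_private=230),
        "SIM-MSIH2": dict(n_trunk=5750, n_branch=250, n_private=140),
    }
    for i, (name, kw) in enumerate(cohort_specs.items()):
        case = simulate_case(SimConfig(seed=args.seed + i, n_microsat=0, **kw))
        s = fractions(case, rescue=True)
        truth = case.truth.true_fractions()
        rows.append(
            {"case": name, "n_mutations": s.n_total,
             "true_public": round(truth["public"], 4),
             "public": round(s.fraction_public, 4),
             "shared": round(s.fraction_shared, 4),
             "private": round(s.fraction_private, 4),
             "burden_per_mb": round(s.burden_per_mb, 2),
             "ns_s": round(s.ns_s_ratio, 2) if s.ns_s_ratio else None}
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "ith_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    # dropout experiment
    exp_rows = []
    for run in range(100):
        cfg = SimConfig(n_trunk=500, n_branch=200, n_private=300, n_microsat=0,
                        dropout=0.2, seq_error=0.0, seed=args.seed + 1000 + run)
        case = simulate_case(cfg)
        est_resc = fractions(case, rescue=True).fraction_public
        est_raw = fractions(case, rescue=False).fraction_public
        exp_rows.append({"run": run, "with_rescue": est_resc, "without_rescue": est_raw})
    exp = pd.DataFrame(exp_rows)
    exp.to_csv(outdir / "rescue_experiment.tsv", sep="\t", index=False)
    err_resc = (exp["with_rescue"] - 0.5).abs()
    err_raw = (exp["without_rescue"] - 0.5).abs()
    print(
        f"\ndropout 0.2, truth public=0.50 over {len(exp)} runs: "
        f"mean |error| {err_resc.mean():.4f} with rescue vs {err_raw.mean():.4f} without; "
        f"rescue within 0.03 in {(err_resc < 0.03).sum()} runs"
    )


if __name__ == "__main__":
    main()
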