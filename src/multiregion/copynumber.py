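"""Read-depth copy-number analysis: log-ratio, GC correction, CBS segmentation.

The tumor/normal depth ratio per genomic bin is library-size normalized,
log2-transformed and median-centered; residual GC content bias is removed
by subtracting the median log-ratio of each GC stratum (width 0.02). The
corrected track is segmented with a circular binary segmentation (CBS)
variant: recursively find the arc (i, j] whose mean differs most from its
complement (two-sample t-like statistic), accept the split when a
permutation test rejects at ``alpha``, recurse into the parts, then merge
adjacent segments whose means are within ``merge_tol``.

The permutation test is adaptive: sampling stops early once the p-value is
decided relative to ``alpha`` (early rejection of hopeless splits, early
acceptance of overwhelming ones), with seeded, deterministic draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "gc", "tumor_depth", "normal_depth"]


# ---------------------------------------------------------------------------
# per-bin log ratio
# ---------------------------------------------------------------------------

def compute_log_ratio(bins: pd.DataFrame, min_normal_depth: float = 10) -> pd.DataFrame:
    """Library-size-normalized, median-centered log2 tumor/normal depth ratio.

    Bins with ``normal_depth < min_normal_depth`` are masked (column
    ``masked``); their ratio is NaN.
    """
    out = bins.copy()
    masked = out["normal_depth"] < min_normal_depth
    if masked.all():
        raise ValueError("all bins masked (normal depth too low everywhere)")
    t_tot = out.loc[~masked, "tumor_depth"].sum()
    n_tot = out.loc[~masked, "normal_depth"].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (out["tumor_depth"] / t_tot) / (out["normal_depth"] / n_tot)
        log2r = np.log2(ratio)
    log2r[masked | ~np.isfinite(log2r)] = np.nan
    log2r = log2r - np.nanmedian(log2r)
    out["log2_ratio"] = log2r
    out["masked"] = masked | ~np.isfinite(log2r)
    return out


def gc_correct(
    bins: pd.DataFrame, stratum_width: float = 0.02, min_bins_per_stratum: int = 50
) -> pd.DataFrame:
    """Subtract the per-GC-stratum median log ratio.

    GC strata of width ``stratum_width``; occupied strata with fewer than
    ``min_bins_per_stratum`` unmasked bins are merged with their nearest
    richer stratum before the median is taken. Re-centered afterwards.
    """
    out = bins.copy()
    ok = ~out["masked"]
    stratum = np.floor(out["gc"] / stratum_width).astype(int)
    counts = stratum[ok].value_counts()
    rich = counts[counts >= min_bins_per_stratum].index.to_numpy()
    if len(rich) == 0:
        # single family: correction degenerates to a constant shift
        med = out.loc[ok, "log2_ratio"].median()
        out.loc[ok, "log2_ratio"] = out.loc[ok, "log2_ratio"] - med
        return out
    rich.sort()
    # map every stratum to the nearest rich stratum
    mapped = rich[np.argmin(np.abs(stratum.to_numpy()[:, None] - rich[None, :]), axis=1)]
    out["_stratum"] = mapped
    med = out[ok].groupby("_stratum")["log2_ratio"].median()
    corr = out["_stratum"].map(med)
    out.loc[ok, "log2_ratio"] = out.loc[ok, "log2_ratio"] - corr[ok]
    out.loc[ok, "log2_ratio"] -= out.loc[ok, "log2_ratio"].median()
    out = out.drop(columns="_stratum")
    return out


# ---------------------------------------------------------------------------
# CBS segmentation
# ---------------------------------------------------------------------------

def _arc_pairs(n: int, min_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j), 0 <= i < j <= n, with min_seg <= j - i <= n - min_seg."""
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    k = j - i
    keep = (k >= min_seg) & (k <= n - min_seg)
    return i[keep], j[keep]


def _arc_stats(cs: np.ndarray, i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """|mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k)) for each arc.

    ``cs`` is the 0-prefixed cumulative sum, shape (..., n+1). The global
    standard deviation is omitted: it is permutation-invariant and cancels
    from the permutation p-value.
    """
    tot = cs[..., -1:]
    k = (j - i).astype(float)
    sum_in = cs[..., j] - cs[..., i]
    mean_in = sum_in / k
    mean_out = (tot - sum_in) / (n - k)
    return np.abs(mean_in - mean_out) / np.sqrt(1.0 / k + 1.0 / (n - k))


def _max_arc(x: np.ndarray, min_seg: int) -> tuple[float, int, int] | None:
    n = len(x)
    if n < 2 * min_seg:
        return None
    i, j = _arc_pairs(n, min_seg)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    t = _arc_stats(cs, i, j, n)
    b = int(np.argmax(t))
    return float(t[b]), int(i[b]), int(j[b])


def _adaptive_perm_pvalue(
    x: np.ndarray,
    t_obs: float,
    min_seg: int,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
    chunk: int = 100,
) -> float:
    """Permutation p for the max arc statistic, with early stopping.

    Stops as soon as the exceedance count guarantees p >= alpha, or accepts
    early (p = (1+0)/(1+done)) after max(500, 5/alpha) clean permutations.
    """
    n = len(x)
    i, j = _arc_pairs(n, min_seg)
    reject_at = math.ceil(alpha * (1 + n_perm))  # p >= alpha once count reaches this
    accept_after = max(500, int(math.ceil(5.0 / alpha)))
    count = 0
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (c, n)).copy(), axis=1)
        cs = np.concatenate([np.zeros((c, 1)), np.cumsum(perms, axis=1)], axis=1)
        t = _arc_stats(cs, i, j, n)
        count += int((t.max(axis=1) >= t_obs - 1e-12).sum())
        done += c
        if count >= reject_at:
            return max((1 + count) / (1 + done), alpha)
        if count == 0 and done >= accept_after:
            return (1 + count) / (1 + done)
    return (1 + count) / (1 + n_perm)


def _segment_chromosome(
    x: np.ndarray,
    alpha: float,
    min_bins: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive CBS on one chromosome; returns interior breakpoints."""
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        best = _max_arc(seg, min_bins)
        if best is None:
            return
        t_obs, i, j = best
        p = _adaptive_perm_pvalue(seg, t_obs, min_bins, n_perm, alpha, rng)
        if p >= alpha:
            return
        cuts = [c for c in (i, j) if 0 < c < len(seg)]
        for c in cuts:
            breakpoints.append(lo + c)
        edges = [lo] + [lo + c for c in cuts] + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(breakpoints)


def segment(
    bins: pd.DataFrame,
    alpha: float = 0.01,
    min_bins: int = 5,
    n_perm: int = 1000,
    seed: int | None = None,
    merge_tol: float = 0.1,
) -> pd.DataFrame:
    """CBS-style segmentation of the (GC-corrected) log2 ratio track.

    ``bins`` must be sorted by (chrom, start) and carry ``log2_ratio`` and
    ``masked`` columns; masked bins are skipped. Returns one row per
    segment: chrom, start, end, n_bins, mean_log2.
    """
    for col in ("log2_ratio", "masked"):
        if col not in bins.columns:
            raise ValueError(f"bins missing column {col!r}; run compute_log_ratio first")
    sorted_ok = (
        bins.groupby("chrom", sort=False)["start"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not sorted_ok:
        raise ValueError("bins must be sorted by (chrom, start)")
    rng = np.random.default_rng(seed)
    segments = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        grp = grp[~grp["masked"]]
        if grp.empty:
            continue
        x = grp["log2_ratio"].to_numpy()
        bps = _segment_chromosome(x, alpha, min_bins, n_perm, rng)
        edges = [0] + bps + [len(x)]
        raw = []
        for a, b in zip(edges[:-1], edges[1:]):
            raw.append(
                {
                    "chrom": chrom,
                    "start": int(grp["start"].iloc[a]),
                    "end": int(grp["end"].iloc[b - 1]),
                    "n_bins": b - a,
                    "mean_log2": float(x[a:b].mean()),
                    "_sum": float(x[a:b].sum()),
                }
            )
        segments.extend(_merge_segments(raw, merge_tol))
    return pd.DataFrame(
        segments, columns=["chrom", "start", "end", "n_bins", "mean_log2"]
    )


def _merge_segments(raw: list[dict], merge_tol: float) -> list[dict]:
    merged: list[dict] = []
    for seg in raw:
        if merged and abs(merged[-1]["mean_log2"] - seg["mean_log2"]) < merge_tol:
            prev = merged[-1]
            prev["end"] = seg["end"]
            prev["n_bins"] += seg["n_bins"]
            prev["_sum"] += seg["_sum"]
            prev["mean_log2"] = prev["_sum"] / prev["n_bins"]
        else:
            merged.append(dict(seg))
    for seg in merged:
        seg.pop("_sum", None)
    return merged


# ---------------------------------------------------------------------------
# gain/loss calls and the oscillation (chromothripsis-like) flag
# ---------------------------------------------------------------------------

def call_gain_loss(
    segments: pd.DataFrame,
    arm_table: pd.DataFrame | None = None,
    gain_thresh: float = 0.3,
    loss_thresh: float = -0.3,
    arm_cover: float = 0.8,
) -> pd.DataFrame:
    """Annotate segments with gain/loss/neutral calls and focal/arm-level scope.

    ``arm_table`` columns: chrom, arm, start, end (0-based half-open). A
    called segment covering >= ``arm_cover`` of an arm is arm-level.
    """
    out = segments.copy()
    call = np.where(
        out["mean_log2"] >= gain_thresh,
        "gain",
        np.where(out["mean_log2"] <= loss_thresh, "loss", "neutral"),
    )
    out["call"] = call
    scopes = []
    for row in out.itertuples():
        scope = "focal"
        if row.call != "neutral" and arm_table is not None:
            arms = arm_table[arm_table["chrom"] == row.chrom]
            for arm in arms.itertuples():
                overlap = min(row.end, arm.end) - max(row.start, arm.start)
                if overlap > 0 and overlap / (arm.end - arm.start) >= arm_cover:
                    scope = f"arm-level ({arm.arm})"
                    break
        scopes.append(scope)
    out["scope"] = scopes
    return out


def detect_oscillation(
    segments: pd.DataFrame, min_switches: int = 8, state_tol: float = 0.15
) -> tuple[bool, int]:
    """Chromothripsis-like flag: a long alternation between two copy states.

    Segment means are collapsed into discrete states by single-linkage
    clustering within ``state_tol``; the flag is raised when some run of
    consecutive segments alternates between exactly two states for at
    least ``min_switches`` segments. Returns (flag, longest run length).
    """
    if len(segments) < 2:
        return False, len(segments)
    means = segments["mean_log2"].to_numpy()
    order = np.argsort(means)
    states = np.empty(len(means), dtype=int)
    state = 0
    prev = None
    for idx in order:
        if prev is not None and means[idx] - prev > state_tol:
            state += 1
        states[idx] = state
        prev = means[idx]
    best = run = 0
    for k in range(len(states)):
        if k >= 2 and states[k] == states[k - 2] and states[k] != states[k - 1]:
            run += 1
        elif k >= 1 and states[k] != states[k - 1]:
            run = 2
        else:
            run = 1
        best = max(best, run)
    return best >= min_switches, best


def write_seg(segments: pd.DataFrame, path, sample: str) -> None:
    """SEG-format output (sample, chrom, start, end, n_bins, mean_log2)."""
    out = segments.copy()
    out.insert(0, "sample", sample)
    out.to_csv(path, sep="\t", index=False)
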