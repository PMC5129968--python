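import numpy as np
import pandas as pd
import pytest

from multiregion.copynumber import (
    call_gain_loss,
    compute_log_ratio,
    detect_oscillation,
    gc_correct,
    segment,
)
from multiregion.simulate import SimConfig, simulate_depth_profile


def make_bins(tumor, normal, gc=None, chrom="chr1"):
    n = len(tumor)
    gc = np.full(n, 0.5) if gc is None else np.asarray(gc)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "gc": gc,
            "tumor_depth": np.asarray(tumor, dtype=float),
            "normal_depth": np.asarray(normal, dtype=float),
        }
    )


def track_bins(values, chrom="chr1"):
    """Bins with a prescribed log2 track (bypasses depth simulation)."""
    out = make_bins(np.ones(len(values)), np.ones(len(values)), chrom=chrom)
    out["log2_ratio"] = np.asarray(values, dtype=float)
    out["masked"] = False
    return out


def ls_single_split(x):
    """Exhaustive least-squares best single breakpoint (oracle)."""
    n = len(x)
    best, best_sse = None, np.inf
    for b in range(1, n):
        sse = ((x[:b] - x[:b].mean()) ** 2).sum() + ((x[b:] - x[b:].mean()) ** 2).sum()
        if sse < best_sse:
            best, best_sse = b, sse
    return best


class TestLogRatio:
    def test_equal_depths_give_zero(self):
        out = compute_log_ratio(make_bins([100] * 20, [100] * 20))
        assert np.allclose(out["log2_ratio"], 0)

    def test_doubled_bin_is_plus_one(self):
        tumor = np.full(101, 100.0)
        tumor[50] = 200.0
        out = compute_log_ratio(make_bins(tumor, np.full(101, 100.0)))
        # median centering over 100 zero bins keeps the rest at 0
        assert out["log2_ratio"].iloc[50] == pytest.approx(1.0, abs=1e-9)

    def test_library_size_skew_cancels(self):
        out = compute_log_ratio(make_bins([200] * 20, [100] * 20))
        assert np.allclose(out["log2_ratio"], 0)

    def test_low_normal_depth_masked(self):
        out = compute_log_ratio(make_bins([100, 100], [100, 5]))
        assert not out["masked"].iloc[0] and out["masked"].iloc[1]

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="masked"):
            compute_log_ratio(make_bins([100] * 3, [1] * 3))


class TestGcCorrect:
    def test_constant_gc_is_a_constant_shift(self):
        out = compute_log_ratio(make_bins([100] * 200, [100] * 200))
        corr = gc_correct(out)
        assert np.allclose(corr["log2_ratio"], out["log2_ratio"], atol=1e-12)

    def test_flattens_sinusoidal_bias(self):
        cfg = SimConfig(n_trunk=0, n_branch=0, n_private=0, n_microsat=0,
                        n_bins=2000, gc_bias_amp=0.3, mean_depth=500, seed=3)
        bins = simulate_depth_profile(cfg)
        raw = compute_log_ratio(bins)
        corr = gc_correct(raw)
        strata = np.floor(corr["gc"] / 0.05)
        resid = corr.groupby(strata)["log2_ratio"].median()
        assert np.abs(resid).max() < 0.05
        # and the raw track really was biased
        raw_resid = raw.groupby(np.floor(raw["gc"] / 0.05))["log2_ratio"].median()
        assert np.abs(raw_resid).max() > 0.1

    def test_preserves_step_height(self):
        # the aberrant segment covers 25% of bins: the per-stratum median
        # correction assumes a copy-neutral majority in every GC stratum
        cfg = SimConfig(n_trunk=0, n_branch=0, n_private=0, n_microsat=0,
                        n_bins=2000, gc_bias_amp=0.3, mean_depth=500,
                        segment_spec=[(1500, 2000, 1.0)], seed=4)
        bins = simulate_depth_profile(cfg)
        corr = gc_correct(compute_log_ratio(bins))
        step = corr["log2_ratio"][1500:].mean() - corr["log2_ratio"][:1500].mean()
        assert step == pytest.approx(1.0, abs=0.05)


class TestSegment:
    def test_constant_signal_single_segment(self):
        segs = segment(track_bins(np.zeros(60)), seed=0)
        assert len(segs) == 1
        assert segs["n_bins"].iloc[0] == 60

    def test_noise_free_step_breaks_exactly_at_50(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        segs = segment(track_bins(x), seed=0)
        assert len(segs) == 2
        assert segs["start"].iloc[1] == 50 * 1000

    def test_three_steps_recovered_within_two_bins(self, rng):
        truth = [80, 150, 230]
        x = np.zeros(300)
        x[80:150] += 1.0
        x[150:230] -= 0.6
        x += rng.normal(0, 0.1, 300)
        segs = segment(track_bins(x), seed=1)
        found = sorted(segs["start"].iloc[1:] // 1000)
        assert len(found) == 3
        assert all(min(abs(f - t) for f in found) <= 2 for t in truth)
        # single-split oracle agreement on a 50-bin window around one breakpoint
        window = x[55:105]
        assert ls_single_split(window) + 55 == pytest.approx(80, abs=2)

    def test_segments_cover_bins_and_means_match(self, rng):
        x = np.r_[np.zeros(40), np.ones(40)] + rng.normal(0, 0.05, 80)
        bins = track_bins(x)
        segs = segment(bins, seed=2)
        assert segs["n_bins"].sum() == 80
        for seg in segs.itertuples():
            members = bins[(bins["start"] >= seg.start) & (bins["end"] <= seg.end)]
            assert seg.mean_log2 == pytest.approx(members["log2_ratio"].mean(), abs=1e-9)

    def test_deterministic_under_fixed_seed(self, rng):
        x = np.r_[np.zeros(50), np.full(50, 0.4)] + rng.normal(0, 0.1, 100)
        a = segment(track_bins(x), seed=7)
        b = segment(track_bins(x), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_unsorted_input_raises(self):
        bins = track_bins(np.zeros(20)).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            segment(bins, seed=0)

    def test_flat_noise_rarely_splits(self, rng):
        splits = 0
        for _ in range(20):
            segs = segment(track_bins(rng.normal(0, 0.1, 100)), alpha=0.01, seed=int(rng.integers(2**31)))
            splits += len(segs) - 1
        assert splits <= 1


class TestGainLossCalls:
    arms = pd.DataFrame(
        {"chrom": ["chr5", "chr5"], "arm": ["5p", "5q"],
         "start": [0, 48_400_000], "end": [48_400_000, 180_915_260]}
    )

    def seg(self, start, end, mean):
        return pd.DataFrame(
            {"chrom": "chr5", "start": [start], "end": [end], "n_bins": 10, "mean_log2": [mean]}
        )

    def test_neutral_segment(self):
        out = call_gain_loss(self.seg(0, 10_000_000, 0.0), self.arms)
        assert out["call"].iloc[0] == "neutral" and out["scope"].iloc[0] == "focal"

    def test_arm_level_loss_on_5q(self):
        out = call_gain_loss(self.seg(50_000_000, 175_000_000, -0.6), self.arms)
        assert out["call"].iloc[0] == "loss"
        assert out["scope"].iloc[0] == "arm-level (5q)"

    def test_focal_loss_within_5q(self):
        out = call_gain_loss(self.seg(111_000_000, 113_500_000, -0.6), self.arms)
        assert (out["call"].iloc[0], out["scope"].iloc[0]) == ("loss", "focal")

    def test_threshold_boundaries(self):
        out = call_gain_loss(self.seg(0, 1_000_000, 0.3), self.arms)
        assert out["call"].iloc[0] == "gain"
        out = call_gain_loss(self.seg(0, 1_000_000, 0.29), self.arms)
        assert out["call"].iloc[0] == "neutral"


class TestOscillation:
    def make_segs(self, means):
        return pd.DataFrame({"chrom": "chr6", "start": range(len(means)),
                             "end": range(1, len(means) + 1), "n_bins": 5,
                             "mean_log2": means})

    def test_eight_alternating_segments_flagged(self):
        flag, run = detect_oscillation(self.make_segs([-0.6, 0.4] * 4))
        assert flag and run == 8

    def test_two_segments_not_flagged(self):
        flag, _ = detect_oscillation(self.make_segs([-0.6, 0.4]))
        assert not flag

    def test_monotone_staircase_not_flagged(self):
        flag, run = detect_oscillation(self.make_segs([0.2 * k for k in range(8)]))
        assert not flag and run <= 2

    def test_alternation_broken_by_third_state(self):
        flag, _ = detect_oscillation(self.make_segs([-0.6, 0.4, -0.6, 1.4, -0.6, 0.4, -0.6, 0.4]))
        assert not flag
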