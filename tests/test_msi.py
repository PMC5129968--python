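import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import kolmogorov

from multiregion.msi import (
    MicrosatLocus,
    bh_adjust,
    call_msi_events,
    case_msi_status,
    classify_msi_status,
    ks_permutation_pvalue,
    ks_pvalue,
    ks_statistic,
    loci_from_table,
)
from multiregion.simulate import simulate_microsat_locus, triangular_profile


def hist_to_samples(hist):
    return np.repeat(list(hist.keys()), list(hist.values()))


def brute_force_D(tumor_hist, normal_hist):
    """Literal ECDF sup-distance over the pooled support."""
    t = hist_to_samples(tumor_hist).astype(float)
    u = hist_to_samples(normal_hist).astype(float)
    support = np.unique(np.concatenate([t, u]))
    ft = np.searchsorted(np.sort(t), support, side="right") / len(t)
    fu = np.searchsorted(np.sort(u), support, side="right") / len(u)
    return np.max(np.abs(ft - fu))


class TestKsStatistic:
    def test_identical_histograms(self):
        assert ks_statistic({9: 5, 10: 7}, {9: 5, 10: 7}) == 0.0

    def test_disjoint_supports(self):
        assert ks_statistic({9: 50}, {10: 50}) == 1.0

    def test_half_shifted(self):
        assert ks_statistic({9: 5, 10: 5}, {10: 10}) == 0.5

    def test_symmetry_and_proportion_invariance(self, rng):
        for _ in range(20):
            t = {int(k): int(v) for k, v in zip(range(8, 14), rng.integers(1, 30, 6))}
            u = {int(k): int(v) for k, v in zip(range(8, 14), rng.integers(1, 30, 6))}
            d = ks_statistic(t, u)
            assert d == ks_statistic(u, t)
            t3 = {k: 3 * v for k, v in t.items()}
            u5 = {k: 5 * v for k, v in u.items()}
            assert ks_statistic(t3, u5) == pytest.approx(d, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            t = {int(k): int(v) for k, v in zip(range(5, 15), rng.integers(0, 20, 10)) if v}
            u = {int(k): int(v) for k, v in zip(range(5, 15), rng.integers(0, 20, 10)) if v}
            if not t or not u:
                continue
            assert ks_statistic(t, u) == pytest.approx(brute_force_D(t, u), abs=1e-12)

    def test_matches_scipy_on_samples(self, rng):
        for _ in range(20):
            t = {int(k): int(v) + 1 for k, v in zip(range(5, 15), rng.integers(0, 20, 10))}
            u = {int(k): int(v) + 1 for k, v in zip(range(5, 15), rng.integers(0, 20, 10))}
            d_scipy = stats.ks_2samp(hist_to_samples(t), hist_to_samples(u)).statistic
            assert ks_statistic(t, u) == pytest.approx(d_scipy, abs=1e-12)


class TestKsPvalue:
    def test_zero_statistic_gives_one(self):
        assert ks_pvalue(0.0, 50, 50) == 1.0
        assert ks_pvalue(0.0, 50, 50, method="permutation",
                         tumor_hist={10: 50}, normal_hist={10: 50},
                         rng=np.random.default_rng(0)) == 1.0

    def test_complete_separation_is_overwhelming(self):
        assert ks_pvalue(1.0, 50, 50) < 1e-10
        p_perm = ks_permutation_pvalue({9: 50}, {10: 50}, n_perm=100_000,
                                       rng=np.random.default_rng(0))
        assert p_perm <= 2e-5

    def test_series_matches_scipy_kolmogorov(self):
        for lam in (0.3, 0.8, 1.2, 2.0):
            ne = 50 * 50 / 100
            d = lam / np.sqrt(ne)
            assert ks_pvalue(d, 50, 50) == pytest.approx(kolmogorov(lam), abs=1e-9)

    def test_invalid_method_raises(self):
        with pytest.raises(ValueError, match="method"):
            ks_pvalue(0.5, 10, 10, method="bootstrap")

    def test_permutation_matches_label_shuffle_oracle(self, rng):
        """The hypergeometric sampler must agree with literally shuffling
        read labels (same conditional law)."""
        t = {9: 8, 10: 12, 11: 5}
        u = {9: 4, 10: 15, 12: 6}
        p_fast = ks_permutation_pvalue(t, u, n_perm=20_000, rng=np.random.default_rng(1))
        pooled = np.concatenate([hist_to_samples(t), hist_to_samples(u)])
        n = sum(t.values())
        d_obs = ks_statistic(t, u)
        count = 0
        B = 20_000
        for _ in range(B):
            rng.shuffle(pooled)
            tt, uu = pooled[:n], pooled[n:]
            th = dict(zip(*np.unique(tt, return_counts=True)))
            uh = dict(zip(*np.unique(uu, return_counts=True)))
            if ks_statistic(th, uh) >= d_obs - 1e-12:
                count += 1
        p_slow = (1 + count) / (1 + B)
        assert p_fast == pytest.approx(p_slow, abs=0.015)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([1.0], [1.0]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.5], [0.08, 0.5]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_direct_step_up_formula(self, p):
        p = np.asarray(p)
        order = np.argsort(p, kind="stable")
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)


class TestEventCalling:
    def test_planted_event_among_nulls(self, rng):
        loci = [MicrosatLocus("unstable", {8: 50}, {10: 50})]
        profile = triangular_profile()
        for i in range(999):
            t, u = simulate_microsat_locus(profile, False, 0, 0, 60, 60, rng)
            loci.append(MicrosatLocus(f"null{i}", t, u))
        res = call_msi_events(loci, seed=0)
        assert bool(res.loc[res["locus_id"] == "unstable", "is_event"].iloc[0])
        assert res["is_event"].sum() <= 2

    def test_undercovered_loci_are_untestable_not_tested(self):
        loci = [
            MicrosatLocus("thin", {10: 5}, {10: 5}),
            MicrosatLocus("ok", {9: 30, 10: 10}, {10: 40}),
        ]
        res = call_msi_events(loci, min_reads=20).set_index("locus_id")
        assert not res.loc["thin", "testable"] and not res.loc["thin", "is_event"]
        assert res.loc["ok", "testable"]

    def test_no_testable_loci_reported_explicitly(self):
        res = call_msi_events([MicrosatLocus("thin", {10: 3}, {10: 3})])
        assert int(res["testable"].sum()) == 0
        assert not res["is_event"].any()

    @pytest.mark.parametrize("n_events,expected", [(0, "MSS"), (5, "MSS"), (46, "MSI-H"), (128, "MSI-H")])
    def test_status_thresholding(self, n_events, expected):
        assert classify_msi_status(n_events) == expected

    def test_case_status_rules(self):
        statuses = {"T1": "MSI-H", "T2": "MSI-H", "T3": "MSS"}
        assert case_msi_status(statuses, "majority") == "MSI-H"
        assert case_msi_status(statuses, "all") == "MSS"
        assert case_msi_status(statuses, "any") == "MSI-H"


class TestLociFromTable:
    def test_pooling_tumor_samples_sums_reads(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "locus_id": ["L1"] * 4,
                "sample": ["tumor:T1", "tumor:T2", "normal", "normal"],
                "length": [10, 10, 10, 11],
                "read_count": [30, 25, 40, 10],
            }
        )
        (locus,) = loci_from_table(table, ["tumor:T1", "tumor:T2"])
        assert locus.tumor_hist == {10: 55}
        assert locus.normal_hist == {10: 40, 11: 10}
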