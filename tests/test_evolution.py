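import pytest
from hypothesis import given, settings, strategies as st

from multiregion.cases import MSS_CASES, REGIONS, analyze_all_cases, analyze_fixture_case
from multiregion.evolution import (
    GeneEvent,
    analyze_case,
    build_region_tree,
    detect_biallelic_inactivation,
    detect_convergence,
    order_events,
    region_tree_from_matrix,
)

ALL = frozenset(REGIONS)


def ev(gene, etype, regions, source=""):
    return GeneEvent(gene, etype, frozenset(regions), source or f"{gene}:{etype}:{'/'.join(sorted(regions))}")


class TestBiallelic:
    def test_two_public_lof_hits_biallelic_everywhere(self):
        events = [ev("APC", "LoF_mutation", ALL, "APC:p.R215X"),
                  ev("APC", "LoF_mutation", ALL, "APC:p.K1452fs")]
        out = detect_biallelic_inactivation("APC", events, REGIONS)
        assert all(flag for flag, _ in out.values())
        assert out["T1"][1] == ("APC:p.K1452fs", "APC:p.R215X")

    def test_lof_plus_overlapping_copy_loss(self):
        events = [ev("APC", "LoF_mutation", ALL), ev("APC", "copy_loss", ALL)]
        out = detect_biallelic_inactivation("APC", events, REGIONS)
        assert all(flag for flag, _ in out.values())

    def test_single_missense_is_not_biallelic(self):
        out = detect_biallelic_inactivation("APC", [ev("APC", "missense", ALL)], REGIONS)
        assert not any(flag for flag, _ in out.values())

    def test_region_resolved_mosaic(self):
        events = [
            ev("APC", "LoF_mutation", ALL, "public_fs"),
            ev("APC", "LoF_mutation", {"T1"}, "private_x"),
            ev("APC", "copy_loss", {"T2"}, "arm_loss"),
        ]
        out = detect_biallelic_inactivation("APC", events, REGIONS)
        assert out["T1"][0] and out["T2"][0] and not out["T3"][0]

    def test_order_invariance(self):
        events = [ev("A", "LoF_mutation", {"T1"}, "x"), ev("A", "copy_loss", {"T1"}, "y")]
        assert (
            detect_biallelic_inactivation("A", events, REGIONS)
            == detect_biallelic_inactivation("A", events[::-1], REGIONS)
        )


class TestConvergence:
    def test_region_exclusive_truncating_hits(self):
        events = [ev("ARID2", "LoF_mutation", {"T1"}, "p.Q995X"),
                  ev("ARID2", "LoF_mutation", {"T2"}, "p.E376X")]
        flag, pairs = detect_convergence("ARID2", events)
        assert flag and ("p.E376X", "p.Q995X") in pairs

    def test_single_shared_event_is_not_convergent(self):
        flag, _ = detect_convergence("ARID2", [ev("ARID2", "LoF_mutation", {"T1", "T2"})])
        assert not flag

    def test_overlapping_region_sets_not_convergent(self):
        events = [ev("G", "LoF_mutation", {"T1", "T2"}, "a"),
                  ev("G", "LoF_mutation", {"T2"}, "b")]
        assert not detect_convergence("G", events)[0]

    def test_mutation_and_copy_loss_mixture(self):
        events = [
            ev("APC", "LoF_mutation", {"T1"}, "nonsense"),
            ev("APC", "copy_loss", {"T2"}, "arm_5q"),
            ev("APC", "copy_loss", {"T3"}, "focal_5q"),
        ]
        flag, pairs = detect_convergence("APC", events)
        assert flag and len(pairs) == 3

    def test_plain_missense_does_not_count(self):
        events = [ev("G", "missense", {"T1"}), ev("G", "missense", {"T2"})]
        assert not detect_convergence("G", events)[0]

    def test_order_invariance(self):
        events = [ev("G", "LoF_mutation", {"T1"}, "a"), ev("G", "hotspot_missense", {"T2"}, "b")]
        assert detect_convergence("G", events) == detect_convergence("G", events[::-1])


class TestOrderEvents:
    def test_public_before_private(self):
        events = [ev("APC", "LoF_mutation", ALL), ev("KRAS", "hotspot_missense", {"T3"})]
        strata = order_events(events, REGIONS)
        assert [e.gene for e in strata["trunk"]] == ["APC"]
        assert [e.gene for e in strata["private"]] == ["KRAS"]

    def test_all_public_single_stratum(self):
        events = [ev(g, "LoF_mutation", ALL) for g in "ABC"]
        strata = order_events(events, REGIONS)
        assert len(strata["trunk"]) == 3 and not strata["branch"] and not strata["private"]

    def test_three_level_chain(self):
        events = [ev("APC", "LoF_mutation", ALL), ev("ARID2", "LoF_mutation", {"T1", "T2"}),
                  ev("SMARCA4", "hotspot_missense", {"T1"})]
        strata = order_events(events, REGIONS)
        assert ([e.gene for e in strata["trunk"]],
                [e.gene for e in strata["branch"]],
                [e.gene for e in strata["private"]]) == (["APC"], ["ARID2"], ["SMARCA4"])

    def test_event_outside_case_regions_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            order_events([ev("G", "missense", {"T9"})], REGIONS)


class TestRegionTree:
    def test_laminar_family_accepted(self):
        counts = {ALL: 50, frozenset({"T1", "T2"}): 10,
                  frozenset({"T1"}): 5, frozenset({"T2"}): 4, frozenset({"T3"}): 6}
        accepted, incompatible = build_region_tree(counts)
        assert frozenset({"T1", "T2"}) in accepted and not incompatible

    def test_conflicting_subset_flagged_against_heavier(self):
        counts = {frozenset({"T1", "T2"}): 30, frozenset({"T2", "T3"}): 5}
        accepted, incompatible = build_region_tree(counts)
        assert accepted == [frozenset({"T1", "T2"})]
        assert incompatible == [(frozenset({"T2", "T3"}), frozenset({"T1", "T2"}))]

    def test_tie_broken_lexicographically(self):
        counts = {frozenset({"T1", "T2"}): 10, frozenset({"T2", "T3"}): 10}
        accepted, _ = build_region_tree(counts)
        assert accepted[0] == frozenset({"T1", "T2"})

    def test_single_region_matrix_rejected(self, small_case):
        from multiregion.genotyper import build_presence_matrix
        from multiregion.variants import merge_candidate_sites

        union = merge_candidate_sites(small_case.calls)
        pm = build_presence_matrix(union, small_case.evidence)
        pm.present = pm.present[["T1"]]
        with pytest.raises(ValueError, match="2 regions"):
            region_tree_from_matrix(pm)

    def test_perfect_simulation_tree_is_laminar(self, small_case):
        from multiregion.genotyper import build_presence_matrix
        from multiregion.variants import merge_candidate_sites

        union = merge_candidate_sites(small_case.calls)
        pm = build_presence_matrix(union, small_case.evidence)
        accepted, incompatible = region_tree_from_matrix(pm)
        assert ALL in accepted
        # the full set and every private singleton always nest; branch
        # mutations land on random 2-subsets, so conflicts can only be
        # between overlapping 2-subsets
        for r in REGIONS:
            assert frozenset({r}) in accepted
        assert all(len(a) == 2 and len(b) == 2 for a, b in incompatible)


class TestCuratedCases:
    """The five-adenoma fixture: qualitative evolution claims."""

    @pytest.fixture(scope="class")
    @staticmethod
    def evos():
        return analyze_all_cases()

    def test_biallelic_apc_in_every_case(self, evos):
        for case, evo in evos.items():
            assert "APC" in evo.biallelic_genes(), case

    def test_arid2_truncating_in_every_mss_case(self, evos):
        for case in MSS_CASES:
            arid2_lof = [
                e for s in evos[case].strata.values() for e in s
                if e.gene == "ARID2" and e.event_type in ("LoF_mutation", "copy_loss")
            ]
            assert arid2_lof, case

    def test_convergence_flags(self, evos):
        assert "ARID2" in evos["MSS2"].convergent_genes()
        assert "ARID2" in evos["MSS3"].convergent_genes()
        assert "APC" in evos["MSS3"].convergent_genes()

    def test_apc_on_the_trunk_everywhere(self, evos):
        for case, evo in evos.items():
            assert any(e.gene == "APC" for e in evo.strata["trunk"]), case

    def test_cancer_gene_hotspots_off_the_trunk(self, evos):
        for case, gene in [("MSS2", "KRAS"), ("MSS1", "ERBB2"), ("MSS2", "FBXW7")]:
            hot = [
                s for s, events in evos[case].strata.items()
                for e in events if e.gene == gene and e.event_type == "hotspot_missense"
            ]
            assert hot and "trunk" not in hot, (case, gene)

    def test_mosaic_case_biallelic_in_every_region(self, evos):
        per_region = evos["MSS3"].biallelic["APC"]
        assert all(flag for flag, _ in per_region.values())

    def test_text_rendering_mentions_key_findings(self):
        text = analyze_fixture_case("MSS1").render_text()
        assert "APC" in text and "biallelic" in text and "[trunk]" in text
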