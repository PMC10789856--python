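
import statistics

import numpy as np
import pytest

from wgdtiming.errors import TimingError
from wgdtiming.njtree import root_with_outgroup
from wgdtiming.pipeline import recover_timing
from wgdtiming.simulate import preset_scenario, simulate_family
from wgdtiming.timing import (Classification, ParalogLabeling, Thresholds,
                              TimingCase, classify_duplication, compute_timing,
                              locate_timing_nodes, timing_report)
from wgdtiming.tree import PhyloTree


LAB = ParalogLabeling(frozenset({"P1"}), frozenset({"P2"}), frozenset({"OG"}))


class TestLabeling:
    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            ParalogLabeling(frozenset({"x"}), frozenset({"x"}), frozenset({"o"}))

    def test_groups_non_empty(self):
        with pytest.raises(ValueError, match="non-empty"):
            ParalogLabeling(frozenset(), frozenset({"y"}), frozenset({"o"}))

    def test_group_of(self):
        lab = ParalogLabeling(frozenset({"x"}), frozenset({"y"}),
                              frozenset({"o"}), frozenset({"z"}))
        assert lab.group_of("x") == "paralog_1"
        assert lab.group_of("z") == "other"


class TestLocate:
    def test_simple(self):
        tree = PhyloTree.from_newick("((P1:4,P2:4):1,OG:5);")
        node_a, node_b, warns = locate_timing_nodes(tree, LAB)
        assert node_a is tree.root
        assert {c.label for c in node_b.children} == {"P1", "P2"}
        assert not warns

    def test_duplication_at_ingroup_root_errors(self):
        tree = PhyloTree.from_newick("((P1:1,OG:1):1,P2:2);")
        rooted = root_with_outgroup(tree, {"OG"})
        with pytest.raises(TimingError):
            locate_timing_nodes(rooted, LAB)

    def test_multi_species_clades(self):
        tree = PhyloTree.from_newick(
            "(((s1P1:1,s2P1:1):2,(s1P2:1,s2P2:1):2):1,OG:4);")
        lab = ParalogLabeling(frozenset({"s1P1", "s2P1"}),
                              frozenset({"s1P2", "s2P2"}), frozenset({"OG"}))
        node_a, node_b, warns = locate_timing_nodes(tree, lab)
        assert node_a is tree.root
        assert len(node_b.children) == 2 and not warns

    def test_interleaved_paralogs_warn(self):
        tree = PhyloTree.from_newick("(((P1:1,P2a:1):1,P2b:2):1,OG:3);")
        lab = ParalogLabeling(frozenset({"P1"}), frozenset({"P2a", "P2b"}),
                              frozenset({"OG"}))
        _, _, warns = locate_timing_nodes(tree, lab)
        assert warns and "non-monophyletic" in warns[0]

    def test_unrooted_input_rejected(self):
        tree = PhyloTree.from_newick("(P1:1,P2:1,OG:1);")
        with pytest.raises(TimingError, match="rooted"):
            locate_timing_nodes(tree, LAB)


class TestComputeTiming:
    def test_constructed_ancient(self):
        tree = PhyloTree.from_newick("((P1:4.0,P2:4.0):1.0,OG:5.0);")
        res = compute_timing(tree, LAB)
        assert res.ab == pytest.approx(1.0)
        assert res.bc == pytest.approx(4.0)
        assert res.ratio == pytest.approx(4.0)
        assert res.classification is Classification.ANCIENT

    def test_constructed_recent(self):
        tree = PhyloTree.from_newick("((P1:0.3,P2:0.3):2.0,OG:2.3);")
        res = compute_timing(tree, LAB)
        assert res.ratio == pytest.approx(0.15)
        assert res.classification is Classification.RECENT

    def test_bc_is_mean_over_tips(self):
        tree = PhyloTree.from_newick("((P1:3.0,P2:5.0):1.0,OG:5.0);")
        res = compute_timing(tree, LAB)
        assert res.bc == pytest.approx(4.0)
        assert res.bc_per_tip == {"P1": 3.0, "P2": 5.0}

    def test_degenerate_stem(self):
        tree = PhyloTree.from_newick("((P1:4,P2:4):0.0,OG:5);")
        with pytest.raises(TimingError, match="degenerate"):
            compute_timing(tree, LAB)

    def test_scale_invariance(self):
        tree = PhyloTree.from_newick("((P1:4.0,P2:3.0):1.5,OG:5.0);")
        base = compute_timing(tree, LAB).ratio
        for k in (0.1, 10.0):
            scaled = compute_timing(tree.scale(k), LAB).ratio
            assert abs(scaled - base) < 1e-12

    def test_clock_identity(self):
        # ultrametric ingroup: heights A (node a) and B (node b)
        height_a, height_b = 1.8, 1.0
        tree = PhyloTree.from_newick(
            "(((P1:1.0,P2:1.0):0.8,other:1.8):0.9,OG:2.7);")
        tree.root_is_insertion = True  # root sits mid-stem, node a is below
        lab = ParalogLabeling(frozenset({"P1"}), frozenset({"P2"}),
                              frozenset({"OG"}), frozenset({"other"}))
        res = compute_timing(tree, lab)
        assert res.ratio == pytest.approx(height_b / (height_a - height_b),
                                          abs=1e-12)

    def test_root_placement_insensitive(self):
        # slide the inserted root along the outgroup stem: same statistic
        lab = ParalogLabeling(frozenset({"P1"}), frozenset({"P2"}),
                              frozenset({"OG"}), frozenset({"other"}))
        results = []
        for split in ("0.5,OG:2.5", "1.2,OG:1.8", "2.9,OG:0.1"):
            tree = PhyloTree.from_newick(
                f"(((P1:1.0,P2:1.0):0.8,other:1.8):{split});")
            tree.root_is_insertion = True
            results.append(compute_timing(tree, lab))
        assert len({round(r.ab, 12) for r in results}) == 1
        assert len({round(r.ratio, 12) for r in results}) == 1

    def test_misplaced_paralog_tip_excluded(self):
        tree = PhyloTree.from_newick(
            "(((P1:1,P2:1):1,stray:2):1,OG:3);")
        lab = ParalogLabeling(frozenset({"P1"}), frozenset({"P2", "lost"}),
                              frozenset({"OG"}), frozenset({"stray"}))
        res = compute_timing(tree, lab)
        assert set(res.bc_per_tip) == {"P1", "P2"}


class TestClassify:
    def test_ancient(self):
        assert classify_duplication(1.23) is Classification.ANCIENT

    def test_recent(self):
        assert classify_duplication(0.15) is Classification.RECENT

    def test_indeterminate(self):
        assert classify_duplication(0.75) is Classification.INDETERMINATE

    def test_custom_thresholds(self):
        th = Thresholds(ancient=2.0, recent=0.1)
        assert classify_duplication(1.23, th) is Classification.INDETERMINATE

    def test_invalid_ratio(self):
        with pytest.raises(TimingError):
            classify_duplication(0.0)
        with pytest.raises(TimingError):
            classify_duplication(float("nan"))


class TestReport:
    def two_cases(self):
        ancient = PhyloTree.from_newick("((P1:4.0,P2:4.0):1.0,OG:5.0);")
        recent = PhyloTree.from_newick("((P1:0.3,P2:0.3):2.0,OG:2.3);")
        p1, p2 = frozenset({"P1"}), frozenset({"P2"})
        og = {"default": frozenset({"OG"})}
        return [
            TimingCase("anc", p1, p2, og, tree=ancient,
                       molecule=None),
            TimingCase("rec", p1, p2, og, tree=recent, molecule=None),
        ]

    def test_two_rows(self):
        table = timing_report(self.two_cases())
        assert len(table) == 2
        assert list(table["classification"]) == ["ancient", "recent"]
        assert table["ratio"].tolist() == pytest.approx([4.0, 0.15])

    def test_empty_case_list(self):
        table = timing_report([])
        assert len(table) == 0

    def test_errors_collected_not_fatal(self):
        bad = PhyloTree.from_newick("((P1:1,OG:1):1,P2:2);")
        cases = self.two_cases() + [
            TimingCase("bad", frozenset({"P1"}), frozenset({"P2"}),
                       {"default": frozenset({"OG"})}, tree=bad)]
        table = timing_report(cases)
        assert len(table) == 3
        assert table.iloc[2]["error"] != ""

    def test_two_outgroups_concordance(self):
        fam = simulate_family(preset_scenario("ancient_2R", seed=5))
        rooted = {"og": frozenset({"OG"}), "alt": frozenset({"other1"})}
        case = TimingCase("sim", fam.labeling.paralog_1,
                          fam.labeling.paralog_2, rooted, tree=fam.true_tree)
        table = timing_report([case])
        assert len(table) == 2
        assert table["concordance"].iloc[0] <= 1.5


class TestRecovery:
    def test_median_ratio_near_truth(self):
        ratios = []
        for seed in range(8):
            fam = simulate_family(preset_scenario("ancient_2R", seed=seed))
            ratios.append(recover_timing(fam).ratio)
        truth = 1.0 / (1.8 - 1.0)
        med = statistics.median(ratios)
        assert truth * 0.75 <= med <= truth * 1.25
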