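"""Chronogram parsing, node ages, ultrametricity and recent-divergence counts."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paramodiv as pv
from paramodiv.errors import ChronogramError, UltrametricityError


class TestReading:
    def test_parses_three_tip_newick(self, three_tip_tree):
        assert three_tip_tree.n_tips == 3
        assert sorted(three_tip_tree.tip_labels) == ["A", "B", "C"]
        root = three_tip_tree.tree.seed_node
        assert len(root.child_nodes()) == 2

    def test_single_tip_rejected(self):
        with pytest.raises(ChronogramError, match=">= 2 tips"):
            pv.chronogram_from_string("(A:1.0);")

    def test_garbage_rejected_with_parse_context(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1.0,B:1.0:3.0,C:4.0);")
        with pytest.raises(ChronogramError, match="could not parse"):
            pv.read_chronogram(p)

    def test_missing_branch_length_names_edge(self):
        with pytest.raises(ChronogramError, match="missing branch length.*'C'"):
            pv.chronogram_from_string("((A:1.0,B:1.0):3.0,C);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ChronogramError, match="duplicate"):
            pv.chronogram_from_string("((A:1.0,A:1.0):3.0,C:4.0);")

    def test_unrooted_flag_rejected(self):
        with pytest.raises(ChronogramError, match="unrooted"):
            pv.chronogram_from_string("[&U] ((A:1.0,B:1.0):3.0,C:4.0);")

    def test_nexus_round_trip(self, tmp_path, three_tip_tree):
        p = tmp_path / "t.nex"
        three_tip_tree.write(p, schema="nexus")
        back = pv.read_chronogram(p, schema="nexus")
        assert back.n_tips == 3
        assert pv.crown_age(back) == pytest.approx(4.0, abs=1e-9)

    def test_simulated_tree_round_trips(self, tmp_path):
        chron = pv.simulate_yule(
            pv.SimulationConfig(birth_rate=0.6, stop_tips=20, seed=5)
        )
        p = tmp_path / "sim.nwk"
        chron.write(p, precision=9)
        back = pv.read_chronogram(p)
        assert sorted(back.tip_labels) == sorted(chron.tip_labels)
        a1 = sorted(pv.node_ages(chron).values())
        a2 = sorted(pv.node_ages(back).values())
        np.testing.assert_allclose(a1, a2, atol=1e-8)


class TestAges:
    def test_three_tip_ages(self, three_tip_tree):
        ages = pv.node_ages(three_tip_tree)
        assert sorted(ages.values()) == pytest.approx([0, 0, 0, 1.0, 4.0])

    def test_balanced_tree_ages(self, balanced_tree):
        ages = pv.node_ages(balanced_tree)
        internal = sorted(a for a in ages.values() if a > 0)
        assert internal == pytest.approx([2.0, 3.0, 4.0])

    def test_crown_age_is_max_age(self, three_tip_tree, balanced_tree):
        for t in (three_tip_tree, balanced_tree):
            assert pv.crown_age(t) == max(pv.node_ages(t).values())

    def test_two_tip_crown_age_matches_aragoa_row(self):
        t = pv.chronogram_from_string("(A:0.42,B:0.42);")
        assert pv.crown_age(t) == pytest.approx(0.42)

    def test_yule_stop_time_sets_crown_age(self):
        t = pv.simulate_yule(pv.SimulationConfig(birth_rate=0.5, stop_time=5.0, seed=11))
        assert pv.crown_age(t) == pytest.approx(5.0, abs=1e-9)

    def test_ages_equal_recorded_event_times(self):
        chron = pv.simulate_yule(
            pv.SimulationConfig(birth_rate=0.7, stop_time=6.0, seed=2)
        )
        internal = sorted(a for a in pv.node_ages(chron).values() if a > 0)
        expected = sorted(6.0 - e for e in chron.event_times)
        np.testing.assert_allclose(internal, expected, atol=1e-9)

    def test_parent_age_geq_child_age(self):
        chron = pv.simulate_yule(pv.SimulationConfig(birth_rate=1.0, stop_tips=30, seed=8))
        ages = pv.node_ages(chron)
        for node in chron.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert ages[node.parent_node] >= ages[node] - 1e-12

    def test_non_ultrametric_rejected_with_spread(self):
        t = pv.chronogram_from_string("((A:1.0,B:1.5):3.0,C:4.0);")
        with pytest.raises(UltrametricityError) as exc:
            pv.node_ages(t)
        assert exc.value.max_deviation == pytest.approx(0.5)


class TestUltrametricCheck:
    def test_exact_tree_passes(self, three_tip_tree):
        ok, dev = pv.check_ultrametric(three_tip_tree)
        assert ok and dev == 0

    def test_deviation_reported(self):
        t = pv.chronogram_from_string("((A:1.0,B:1.5):3.0,C:4.0);")
        ok, dev = pv.check_ultrametric(t)
        assert not ok
        assert dev == pytest.approx(0.5)

    def test_tiny_perturbation_within_tolerance(self):
        t = pv.chronogram_from_string("((A:1.000000001,B:1.0):3.0,C:4.000000001);")
        ok, _ = pv.check_ultrametric(t, tol=1e-6)
        assert ok


class TestPleistoceneCount:
    def test_young_cherry_counts_both_tips(self, three_tip_tree):
        assert pv.count_pleistocene_tips(three_tip_tree, threshold=2.58) == (2, 3)

    def test_old_cherry_counts_none(self):
        t = pv.chronogram_from_string("((A:3.0,B:3.0):1.0,C:4.0);")
        assert pv.count_pleistocene_tips(t, threshold=2.58) == (0, 3)

    def test_boundary_rule_strict_vs_inclusive(self):
        t = pv.chronogram_from_string("((A:2.58,B:2.58):1.42,C:4.0);")
        assert pv.count_pleistocene_tips(t, boundary="strict") == (0, 3)
        assert pv.count_pleistocene_tips(t, boundary="inclusive") == (2, 3)

    def test_polytomy_children_share_divergence_age(self):
        t = pv.chronogram_from_string("((A:1.0,B:1.0,C:1.0):3.0,D:4.0);")
        assert pv.count_pleistocene_tips(t, threshold=2.58) == (3, 4)

    def test_nonpositive_threshold_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="threshold"):
            pv.count_pleistocene_tips(three_tip_tree, threshold=0.0)

    def test_matches_brute_force_on_simulated_tree(self):
        chron = pv.simulate_yule(pv.SimulationConfig(birth_rate=1.0, stop_tips=50, seed=13))
        k, n = pv.count_pleistocene_tips(chron, threshold=2.58)
        ages = pv.node_ages(chron)
        brute = sum(
            1 for leaf in chron.tree.leaf_nodes() if ages[leaf.parent_node] < 2.58
        )
        assert n == 50
        assert k == brute

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        threshold=st.floats(min_value=0.01, max_value=20.0),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_monotone_in_threshold_and_limits(self, threshold, seed):
        chron = pv.simulate_yule(
            pv.SimulationConfig(birth_rate=0.8, stop_tips=15, seed=seed)
        )
        k1, n = pv.count_pleistocene_tips(chron, threshold=threshold)
        k2, _ = pv.count_pleistocene_tips(chron, threshold=threshold * 2)
        assert 0 <= k1 <= k2 <= n
        big, _ = pv.count_pleistocene_tips(chron, threshold=1e9)
        tiny, _ = pv.count_pleistocene_tips(chron, threshold=1e-12)
        assert big == n and tiny == 0

    def test_newick_round_trip_preserves_count_and_crown(self, tmp_path):
        chron = pv.simulate_yule(pv.SimulationConfig(birth_rate=0.9, stop_tips=25, seed=3))
        p = tmp_path / "t.nwk"
        chron.write(p, precision=9)
        back = pv.read_chronogram(p)
        assert pv.count_pleistocene_tips(back) == pv.count_pleistocene_tips(chron)
        assert pv.crown_age(back) == pytest.approx(pv.crown_age(chron), abs=1e-8)
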