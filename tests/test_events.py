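"""Chronograms, transition counting, relative timing and tallies."""

import numpy as np
import pytest

import saltcross as sc
from saltcross.ancestral import TraitHistory, ensure_node_ids, node_id
from saltcross.ctmc import RateModel
from saltcross.events import events_table, time_histogram
from saltcross.phylo_io import Habitat


def history_from_states(tree, states: dict[str, Habitat]) -> TraitHistory:
    """Build a TraitHistory directly from a node-id -> state map."""
    ensure_node_ids(tree)
    transitions = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        a, b = states[node_id(nd.parent_node)], states[node_id(nd)]
        if a is not b:
            transitions.append((node_id(nd), a, b))
    return TraitHistory(tree=tree, states=states, transitions=transitions)


class TestMplChronogram:
    def test_hand_example(self):
        t = sc.read_tree("((A:1,B:3):2,C:6);")
        chrono = sc.mpl_chronogram(t)
        cherry = t.mrca(taxon_labels=["A", "B"])
        # cherry age mean(1,3)=2; root mean(3,5,6)=14/3; relative 2/(14/3)
        assert chrono.ages[node_id(cherry)] == pytest.approx(0.42857, abs=1e-5)
        assert chrono.ages[node_id(t.seed_node)] == 1.0
        assert chrono.ages["A"] == 0.0 and chrono.ages["C"] == 0.0

    def test_two_tip_tree(self):
        chrono = sc.mpl_chronogram(sc.read_tree("(A:2,B:4);"))
        assert chrono.ages[node_id(chrono.tree.seed_node)] == 1.0
        assert chrono.ages["A"] == 0.0 and chrono.ages["B"] == 0.0

    def test_ultrametric_tree_recovers_depths(self):
        tree = sc.simulate_tree(sc.SimulationConfig(num_tips=30, seed=3))
        depth = max(
            lf.distance_from_root() for lf in tree.leaf_node_iter()
        )
        chrono = sc.mpl_chronogram(tree)
        for nd in tree.preorder_node_iter():
            expect = (depth - nd.distance_from_root()) / depth
            assert chrono.ages[node_id(nd)] == pytest.approx(expect, abs=1e-6)

    def test_parent_strictly_older_than_child(self):
        # unbalanced lengths force monotonicity enforcement paths
        t = sc.read_tree("(((A:0.1,B:0.1):5,C:0.2):1,D:8);")
        chrono = sc.mpl_chronogram(t)
        for nd in t.preorder_node_iter():
            for c in nd.child_nodes():
                assert chrono.ages[node_id(nd)] > chrono.ages[node_id(c)]

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="zero total depth"):
            sc.mpl_chronogram(sc.read_tree("(A:0,B:0);"))


class TestCountTransitions:
    @pytest.fixture
    def quartet_tree(self):
        return sc.read_tree("((a:1,b:1):1,(c:1,d:1):1);")

    def test_established_clade_is_counted(self, quartet_tree):
        ensure_node_ids(quartet_tree)
        cd = node_id(quartet_tree.mrca(taxon_labels=["c", "d"]))
        ab = node_id(quartet_tree.mrca(taxon_labels=["a", "b"]))
        root = node_id(quartet_tree.seed_node)
        M, NM = Habitat.MARINE, Habitat.NON_MARINE
        states = {root: M, ab: M, cd: NM, "a": M, "b": M, "c": NM, "d": NM}
        events = sc.count_transitions(history_from_states(quartet_tree, states))
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "M->NM"
        assert ev.persistent_tip_count == 2
        assert ev.counted

    def test_singleton_flip_not_counted(self, quartet_tree):
        ensure_node_ids(quartet_tree)
        cd = node_id(quartet_tree.mrca(taxon_labels=["c", "d"]))
        ab = node_id(quartet_tree.mrca(taxon_labels=["a", "b"]))
        root = node_id(quartet_tree.seed_node)
        M, NM = Habitat.MARINE, Habitat.NON_MARINE
        states = {root: M, ab: M, cd: M, "a": M, "b": M, "c": NM, "d": M}
        events = sc.count_transitions(history_from_states(quartet_tree, states))
        assert len(events) == 1
        assert not events[0].counted
        assert events[0].persistent_tip_count == 1
        # removing the persistence filter recovers the total
        assert all(
            e.counted
            for e in sc.count_transitions(
                history_from_states(quartet_tree, states), min_clade_size=1
            )
        )

    def test_back_transition_blocks_persistence(self):
        # chain a-(b,(c,d)): switch at {b,c,d} ancestor, back-switch at {c,d}
        t = sc.read_tree("(a:1,(b:1,(c:1,d:1):1):1);")
        ensure_node_ids(t)
        M, NM = Habitat.MARINE, Habitat.NON_MARINE
        bcd = node_id(t.mrca(taxon_labels=["b", "c", "d"]))
        cd = node_id(t.mrca(taxon_labels=["c", "d"]))
        root = node_id(t.seed_node)
        states = {root: M, bcd: NM, cd: M, "a": M, "b": NM, "c": M, "d": M}
        events = {e.edge: e for e in sc.count_transitions(history_from_states(t, states))}
        # the M->NM event only reaches tip b in the new state
        assert events[bcd].persistent_tip_count == 1
        assert not events[bcd].counted
        # the nested back-transition reaches c and d
        assert events[cd].persistent_tip_count == 2
        assert events[cd].counted

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_identity_on_random_histories(self, seed):
        """State-change edges = maximal monochromatic subtrees - 1."""
        tree = sc.simulate_tree(sc.SimulationConfig(num_tips=40, seed=800 + seed))
        at, truth = sc.simulate_history(tree, RateModel(0.2, 0.3), seed=900 + seed)
        hist = history_from_states(tree, dict(truth.node_states))
        events = sc.count_transitions(hist, min_clade_size=1)
        # count maximal same-state connected components by union of non-change edges
        n_nodes = sum(1 for _ in tree.preorder_node_iter())
        n_change = len(events)
        # components = nodes - non-change-edges; subtract 1 for the root component
        n_edges = n_nodes - 1
        components = n_nodes - (n_edges - n_change)
        assert n_change == components - 1


class TestEventTimes:
    def test_midpoint_formula(self):
        t = sc.read_tree("((A:1,B:3):2,C:6);")
        chrono = sc.mpl_chronogram(t)
        chrono.ages["x_parent"] = 0.6
        chrono.ages["x_child"] = 0.2
        ev = sc.TransitionEvent(
            edge="x_child", parent="x_parent", direction="M->NM",
            persistent_tip_count=2, counted=True,
        )
        (out,) = sc.event_times([ev], chrono)
        assert out.relative_time == pytest.approx(0.6)

    def test_boundary_placements(self):
        chrono = sc.mpl_chronogram(sc.read_tree("(A:2,B:4);"))
        root = node_id(chrono.tree.seed_node)
        ev = sc.TransitionEvent(
            edge="A", parent=root, direction="M->NM",
            persistent_tip_count=2, counted=True,
        )
        # terminal edge, child age 0: relative_time = 1 - parent_age/2
        (out,) = sc.event_times([ev], chrono)
        assert out.relative_time == pytest.approx(1 - 0.5)
        (out,) = sc.event_times([ev], chrono, placement="parent")
        assert out.relative_time == pytest.approx(0.0)
        (out,) = sc.event_times([ev], chrono, placement="child")
        assert out.relative_time == pytest.approx(1.0)

    def test_unknown_edge_rejected(self):
        chrono = sc.mpl_chronogram(sc.read_tree("(A:2,B:4);"))
        ev = sc.TransitionEvent(
            edge="nope", parent="nope2", direction="M->NM",
            persistent_tip_count=2, counted=True,
        )
        with pytest.raises(KeyError, match="absent from chronogram"):
            sc.event_times([ev], chrono)

    @pytest.mark.parametrize("seed", range(4))
    def test_times_in_unit_interval_and_histogram_totals(self, seed):
        tree = sc.simulate_tree(sc.SimulationConfig(num_tips=60, seed=700 + seed))
        model = RateModel(0.15, 0.15)
        at, _ = sc.simulate_history(tree, model, seed=710 + seed)
        hist = sc.joint_ml_states(at, model)
        events = sc.event_times(sc.count_transitions(hist), sc.mpl_chronogram(at.tree))
        for ev in events:
            assert 0.0 <= ev.relative_time <= 1.0
        hdf = time_histogram(events, bins=20)
        counted = sum(1 for e in events if e.counted)
        assert hdf["count"].sum() == counted


class TestTally:
    def _events(self, n_mnm, n_nmm):
        out = []
        for i in range(n_mnm):
            out.append(sc.TransitionEvent(f"e{i}", "p", "M->NM", 2, True))
        for i in range(n_nmm):
            out.append(sc.TransitionEvent(f"f{i}", "p", "NM->M", 2, True))
        return out

    def test_hand_counts(self):
        df = sc.tally([self._events(2, 1)])
        counted = df[df["population"] == "counted"].set_index("direction")
        assert counted.loc["M->NM", "total"] == 2
        assert counted.loc["NM->M", "total"] == 1

    def test_identical_histories_zero_iqr(self):
        df = sc.tally([self._events(3, 2)] * 5)
        counted = df[df["population"] == "counted"]
        assert (counted["q3"] - counted["q1"]).abs().max() == 0.0

    def test_asymmetric_simulation_orders_medians(self):
        """Started marine with q_MN >> q_NM and slow mixing, the net flux
        out of marine gives more M->NM than NM->M events per history."""
        sets = []
        for rep in range(8):
            tree = sc.simulate_tree(sc.SimulationConfig(num_tips=80, seed=20 + rep))
            model = RateModel(0.5, 0.05)
            at, truth = sc.simulate_history(
                tree, model, root_state=sc.Habitat.MARINE, seed=50 + rep
            )
            hist = history_from_states(tree, dict(truth.node_states))
            sets.append(sc.count_transitions(hist, min_clade_size=1))
        df = sc.tally(sets)
        detected = df[df["population"] == "all"].set_index("direction")
        assert detected.loc["M->NM", "median"] > detected.loc["NM->M", "median"]

    def test_events_table_columns(self):
        df = events_table(self._events(1, 1))
        assert {"edge", "direction", "counted", "persistent_tip_count"} <= set(df.columns)
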