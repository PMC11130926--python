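"""Representative collapsing, thresholding, refinement, and overlay."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from qsalvage.association import FusionCall, NeighborhoodRecord
from qsalvage.profiler import MarkerSet, classify_profile
from qsalvage.records import PairScore, ProteinRecord
from qsalvage.ssn import (
    SSN, SSNNode, build_network, cluster_profile_overlay,
    collapse_representatives, initial_threshold, refine_until_homogeneous,
)


def prot(pid, length=300, genome="g"):
    return ProteinRecord(pid, genome, "c", 0, "+", length)


def singleton_nodes(ids):
    return {i: SSNNode(i, (i,), {}) for i in ids}


class TestCollapseRepresentatives:
    def test_transitive_single_linkage(self):
        pairs = [PairScore("A", "B", 95, 10), PairScore("B", "C", 92, 10)]
        nodes = collapse_representatives(
            pairs, [prot("A", 500), prot("B", 300), prot("C", 400)], 90)
        (node,) = nodes.values()
        assert node.members == ("A", "B", "C")
        assert node.node_id == "A"  # longest member is the representative

    def test_boundary_identity_is_strict(self):
        pairs = [PairScore("A", "B", 90.0, 10)]
        nodes = collapse_representatives(pairs, [prot("A"), prot("B")], 90)
        assert len(nodes) == 2

    def test_no_pairs_every_protein_own_node(self):
        nodes = collapse_representatives([], [prot("A"), prot("B")], 90)
        assert set(nodes) == {"A", "B"}

    def test_rep_tie_breaks_to_smallest_id(self):
        pairs = [PairScore("Z", "B", 99, 10)]
        nodes = collapse_representatives(pairs, [prot("Z"), prot("B")], 90)
        assert set(nodes) == {"B"}

    def test_independent_of_pair_order(self):
        pairs = [PairScore("A", "B", 95, 1), PairScore("C", "D", 93, 1),
                 PairScore("B", "C", 91, 1)]
        proteins = [prot(x) for x in "ABCD"]
        a = collapse_representatives(pairs, proteins, 90)
        b = collapse_representatives(list(reversed(pairs)), proteins, 90)
        assert {k: v.members for k, v in a.items()} == {
            k: v.members for k, v in b.items()}

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="B"):
            collapse_representatives([PairScore("A", "B", 95, 1)], [prot("A")], 90)


class TestInitialThreshold:
    def test_median_of_identity_band(self):
        pairs = [PairScore("a", "b", 39, 48), PairScore("a", "c", 40, 50),
                 PairScore("b", "c", 41, 52)]
        assert initial_threshold(pairs, 40) == 50.0

    def test_no_band_falls_back_to_min_as(self):
        pairs = [PairScore("a", "b", 90, 120), PairScore("a", "c", 90, 80)]
        assert initial_threshold(pairs, 40) == 80.0

    def test_single_in_band_pair(self):
        assert initial_threshold([PairScore("a", "b", 40, 37)], 40) == 37.0

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            initial_threshold([], 40)


class TestBuildNetwork:
    def test_components_split_at_threshold(self):
        nodes = singleton_nodes("ABC")
        pairs = [PairScore("A", "B", 70, 100), PairScore("B", "C", 70, 50)]
        net = build_network(nodes, pairs, 60)
        assert [set(c) for _, c in net.clusters] == [{"A", "B"}, {"C"}]

    def test_threshold_zero_keeps_graph_connected(self):
        nodes = singleton_nodes("ABC")
        pairs = [PairScore("A", "B", 70, 10), PairScore("B", "C", 70, 5)]
        net = build_network(nodes, pairs, 0)
        assert len(net.clusters) == 1

    def test_threshold_above_max_as_gives_singletons(self):
        nodes = singleton_nodes("ABC")
        pairs = [PairScore("A", "B", 70, 10), PairScore("B", "C", 70, 5)]
        net = build_network(nodes, pairs, 11)
        assert all(len(c) == 1 for _, c in net.clusters)

    def test_node_level_as_is_max_over_member_pairs(self):
        nodes = {"A": SSNNode("A", ("A", "A2"), {}), "B": SSNNode("B", ("B",), {})}
        pairs = [PairScore("A", "B", 70, 40), PairScore("A2", "B", 70, 90)]
        net = build_network(nodes, pairs, 50)
        assert net.edges == [("A", "B", 90.0)]

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 5000), n=st.integers(2, 40))
    def test_components_equal_dfs_oracle(self, seed, n):
        rng = random.Random(seed)
        ids = [f"n{i}" for i in range(n)]
        nodes = singleton_nodes(ids)
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.1:
                    pairs.append(PairScore(ids[i], ids[j], 50,
                                           rng.uniform(0, 100)))
        t = rng.uniform(0, 100)
        net = build_network(nodes, pairs, t)
        assert {frozenset(c) for _, c in net.clusters} == dfs_components(ids, [
            (p.protein_a, p.protein_b) for p in pairs if p.alignment_score >= t
        ])

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 5000), t1=st.floats(0, 50), dt=st.floats(0.1, 50))
    def test_higher_threshold_refines_partition(self, seed, t1, dt):
        rng = random.Random(seed)
        ids = [f"n{i}" for i in range(20)]
        nodes = singleton_nodes(ids)
        pairs = [PairScore(a, b, 50, rng.uniform(0, 100))
                 for i, a in enumerate(ids) for b in ids[i + 1:]
                 if rng.random() < 0.2]
        low = build_network(nodes, pairs, t1)
        high = build_network(nodes, pairs, t1 + dt)
        coarse = {n: cid for cid, c in low.clusters for n in c}
        for _, fine_members in high.clusters:
            assert len({coarse[n] for n in fine_members}) == 1


def dfs_components(ids, edges):
    adj = {i: [] for i in ids}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen, comps = set(), set()
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v])
        seen |= comp
        comps.add(frozenset(comp))
    return comps


def labeled_nodes(labels):
    return {
        nid: SSNNode(nid, (nid,), {"profile_category": lab})
        for nid, lab in labels.items()
    }


class TestRefinement:
    def _barbell(self):
        labels = {f"x{i}": "X" for i in range(5)}
        labels.update({f"y{i}": "Y" for i in range(5)})
        nodes = labeled_nodes(labels)
        pairs = []
        for grp in ("x", "y"):
            ids = [f"{grp}{i}" for i in range(5)]
            pairs += [PairScore(a, b, 80, 100)
                      for i, a in enumerate(ids) for b in ids[i + 1:]]
        pairs.append(PairScore("x0", "y0", 45, 42))  # low-AS bridge
        return build_network(nodes, pairs, 40)

    def test_bridge_drops_at_first_sufficient_step(self):
        net = self._barbell()
        refined, report, visited = refine_until_homogeneous(
            net, "profile_category", step=5, majority=0.9)
        assert report.homogeneous
        assert len(refined.clusters) == 2
        assert visited[0] == 40 and refined.threshold == 45.0

    def test_already_homogeneous_returns_at_iteration_zero(self):
        nodes = labeled_nodes({"a": "X", "b": "X", "c": "X"})
        net = build_network(nodes, [PairScore("a", "b", 80, 100),
                                    PairScore("b", "c", 80, 100)], 50)
        refined, report, visited = refine_until_homogeneous(
            net, "profile_category")
        assert visited == [50] and refined is net and report.homogeneous

    def test_inseparable_mixed_clique_ends_all_singletons(self):
        labels = {"a": "X", "b": "Y", "c": "X", "d": "Y"}
        nodes = labeled_nodes(labels)
        ids = sorted(labels)
        pairs = [PairScore(a, b, 70, 60.0)
                 for i, a in enumerate(ids) for b in ids[i + 1:]]
        net = build_network(nodes, pairs, 50)
        refined, report, visited = refine_until_homogeneous(
            net, "profile_category", step=5)
        assert report.homogeneous
        assert all(len(c) == 1 for _, c in refined.clusters)
        # iteration bound: ceil((max_threshold - initial)/step) + 1 visits
        assert len(visited) <= (65 - 50) / 5 + 1

    def test_non_positive_step_rejected(self):
        net = build_network(labeled_nodes({"a": "X"}), [], 0)
        with pytest.raises(ValueError):
            refine_until_homogeneous(net, "profile_category", step=0)


class TestOverlay:
    def _profiles(self):
        markers = MarkerSet()
        row_direct = {m: m == "bTGT" for m in markers.all_markers()}
        row_non = {m: False for m in markers.all_markers()}
        return [classify_profile("g1", row_direct),
                classify_profile("g2", row_non)]

    def _net(self):
        nodes = {
            "p1": SSNNode("p1", ("p1",), {"member_genomes": {"p1": "g1"}}),
            "p2": SSNNode("p2", ("p2",), {"member_genomes": {"p2": "g2"}}),
        }
        return build_network(nodes, [], 0)

    def _rec(self, distance):
        return NeighborhoodRecord("p1", "bTGT", "n1", frozenset({"PFC"}),
                                  distance, "g1")

    def test_candidate_at_distance_three_fills_node(self):
        net = cluster_profile_overlay(
            self._net(), self._profiles(), [self._rec(3)], [], {"PFC"})
        assert net.nodes["p1"].attributes["filled"]

    def test_candidate_at_distance_four_does_not_fill(self):
        net = cluster_profile_overlay(
            self._net(), self._profiles(), [self._rec(4)], [], {"PFC"})
        assert not net.nodes["p1"].attributes["filled"]

    def test_fusion_member_fills_without_neighbors(self):
        fusion = FusionCall("p1", "g1", 800, "bTGT", frozenset({"PFC"}),
                            ("bTGT", "PFC"))
        net = cluster_profile_overlay(
            self._net(), self._profiles(), [], [fusion], {"PFC"})
        assert net.nodes["p1"].attributes["filled"]
        assert net.nodes["p1"].attributes["fused"]

    def test_genomes_without_tgt_get_gray_border(self):
        net = cluster_profile_overlay(
            self._net(), self._profiles(), [self._rec(1)], [], {"PFC"})
        assert net.nodes["p2"].attributes["border"] == "gray"
        assert net.nodes["p1"].attributes["border"] == "q_salvager_direct"

    def test_missing_profile_names_genome(self):
        profiles = [p for p in self._profiles() if p.genome_id != "g2"]
        with pytest.raises(ValueError, match="g2"):
            cluster_profile_overlay(self._net(), profiles, [self._rec(1)],
                                    [], {"PFC"})
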