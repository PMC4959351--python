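"""Expansion engine: set operators, recursion cells, RN assembly.

The worked-example network pins every printed identity of the
recursion; random networks are checked against the naive uncached
oracle and against breadth-first reachability in the no-inter limit.
"""

import networkx as nx
import pytest

from conftest import make_random_net
from naive_gim import naive_cell
from morm import (
    AnchorSpec,
    BMKNError,
    ExpansionState,
    diagonal_profile,
    expand,
    initial_sets,
    inter_step,
    intra_step,
    relatedness_network,
)
from morm.model import BMKN, Concept, TypedEdge


class TestSetOperators:
    def test_intra_step_returns_neighbors_without_input(self, fig3):
        assert intra_step(fig3, {"D1", "D2"}, "D") == {"D3", "D4"}
        assert intra_step(fig3, {"S1", "S2"}, "S") == {"S3", "S4", "S5"}
        assert intra_step(fig3, set(), "D") == set()

    def test_inter_step_crosses_ontologies(self, fig3):
        assert inter_step(fig3, {"S1", "S2"}, "S", "D") == {"D9", "D10"}
        assert inter_step(fig3, {"D1", "D2"}, "D", "S") == {"S3"}
        assert inter_step(fig3, {"D0"}, "D", "S") == {"S1", "S2"}

    def test_wrong_ontology_member_rejected(self, fig3):
        with pytest.raises(BMKNError):
            intra_step(fig3, {"S1"}, "D")
        with pytest.raises(BMKNError):
            inter_step(fig3, {"D1"}, "S", "D")


class TestInitialSets:
    def test_worked_example_grounding(self, fig3, fig3_anchor):
        sets = initial_sets(fig3, fig3_anchor)
        assert sets == {"D": {"D1", "D2"}, "S": {"S1", "S2"}}

    def test_isolated_anchor_all_empty(self, fig3):
        sets = initial_sets(fig3, AnchorSpec("D12"))
        assert all(not s for s in sets.values())

    def test_three_ontology_case_matches_direct_neighbor_scan(self):
        net = make_random_net(seed=7)
        anchor = "O1_0"
        sets = initial_sets(net, AnchorSpec(anchor))
        assert set(sets) == net.ontologies
        for t, members in sets.items():
            if t == "O1":
                assert members == net.out_neighbors(anchor, "intra") - {anchor}
            else:
                expected = {
                    v for v in net.out_neighbors(anchor, "inter")
                    if net.ontology_of(v) == t
                }
                assert members == expected - {anchor}


# the nine printed identities of the worked example
FIG3_CELLS = [
    (0, 0, "D", {"D1", "D2"}),
    (0, 0, "S", {"S1", "S2"}),
    (0, 1, "D", {"D1", "D2", "D3", "D4"}),
    (1, 0, "D", {"D1", "D2", "D9", "D10"}),
    (1, 1, "D", {"D1", "D2", "D3", "D4", "D9", "D10"}),
    (0, 1, "S", {"S1", "S2", "S3", "S4", "S5"}),
    (1, 0, "S", {"S1", "S2", "S3"}),
    (1, 1, "S", {"S1", "S2", "S3", "S4", "S5"}),
    (2, 2, "D", {"D1", "D2", "D3", "D4", "D9", "D10", "D11", "D12"}),
]


class TestExpansion:
    @pytest.mark.parametrize("i,j,t,expected", FIG3_CELLS)
    def test_worked_example_cells(self, fig3, fig3_anchor, i, j, t, expected):
        assert expand(fig3, fig3_anchor, i, j, t) == expected

    def test_negative_indices_rejected(self, fig3, fig3_anchor):
        with pytest.raises(BMKNError):
            ExpansionState(fig3, fig3_anchor).cell(-1, 0, "D")

    def test_no_inter_edges_makes_i_irrelevant(self):
        net = make_random_net(seed=3, inter_rate=0.0)
        anchor = AnchorSpec("O1_0")
        for i in range(4):
            for j in range(4):
                assert expand(net, anchor, i, j, "O1") == expand(net, anchor, 0, j, "O1")

    @pytest.mark.parametrize("seed", range(12))
    def test_memoized_engine_equals_naive_oracle(self, seed):
        net = make_random_net(seed=seed)
        anchor = AnchorSpec(f"O{seed % 3 + 1}_0")
        state = ExpansionState(net, anchor)
        for i in range(4):
            for j in range(4):
                for t in net.ontologies:
                    assert state.cell(i, j, t) == naive_cell(
                        net, anchor.anchor, i, j, t
                    ), (seed, i, j, t)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_inter_limit_equals_bfs_reachability(self, seed):
        """Without inter edges, cell (i, j) in the anchor ontology is the
        forward intra ball of radius j+1 (the initial set is already one
        step out, as the worked example's 0D1 = {D1..D4} shows), and
        every other ontology's cells are empty."""
        net = make_random_net(seed=seed, inter_rate=0.0)
        anchor = AnchorSpec("O1_0")
        intra_graph = nx.DiGraph(
            (e.source, e.target)
            for e in net.edges()
            if net.classify_edge(e) == "intra"
        )
        intra_graph.add_nodes_from(net.concept_ids())
        dist = nx.single_source_shortest_path_length(intra_graph, "O1_0")
        state = ExpansionState(net, anchor)
        for j in range(4):
            ball = {v for v, d in dist.items() if 0 < d <= j + 1}
            for i in range(5):
                assert state.cell(i, j, "O1") == ball
                assert state.cell(i, j, "O2") == frozenset()

    @pytest.mark.parametrize("seed", range(10))
    def test_no_intra_limit_equals_inter_walk_enumeration(self, seed):
        """Without intra edges the diagonal at step i is exactly the set
        of nodes reachable by forward inter-edge walks of length <= i+1."""
        net = make_random_net(
            seed=seed, concepts_per_ontology=10, tree_branching=9,
            intra_extra_rate=0.0, inter_rate=0.08,
        )
        # drop the tree edges, keeping only inter links
        for e in list(net.edges()):
            if net.classify_edge(e) == "intra":
                net.graph.remove_edge(e.source, e.target, key=e.rel)
        anchor = "O1_0"
        inter_graph = nx.DiGraph((e.source, e.target) for e in net.edges())
        inter_graph.add_nodes_from(net.concept_ids())
        dist = nx.single_source_shortest_path_length(inter_graph, anchor)
        state = ExpansionState(net, AnchorSpec(anchor))
        for i in range(4):
            reach = {v for v, d in dist.items() if 0 < d <= i + 1}
            got = set()
            for t in net.ontologies:
                got |= state.cell(i, i, t)
            assert got == reach


class TestInvariants:
    @pytest.mark.parametrize("seed", range(15))
    def test_diagonal_monotone_and_contains_initial_sets(self, seed):
        net = make_random_net(seed=seed)
        anchor = AnchorSpec("O1_1")
        state = ExpansionState(net, anchor)
        init = initial_sets(net, anchor)
        for t in net.ontologies:
            prev = frozenset()
            for i in range(5):
                diag = state.cell(i, i, t)
                assert prev <= diag
                prev = diag
            for i in range(3):
                for j in range(3):
                    assert init[t] <= state.cell(i, j, t)

    @pytest.mark.parametrize("seed", range(15))
    def test_anchor_never_appears_in_any_cell(self, seed):
        net = make_random_net(seed=seed, inter_rate=0.1)
        anchor = AnchorSpec("O2_0", steps=2)
        state = ExpansionState(net, anchor)
        for i in range(4):
            for j in range(4):
                for t in net.ontologies:
                    assert "O2_0" not in state.cell(i, j, t)
        rn = relatedness_network(net, anchor)
        assert "O2_0" not in rn.node_ids


class TestRelatednessNetwork:
    def test_worked_example_rn(self, fig3, fig3_anchor):
        rn = relatedness_network(fig3, fig3_anchor)
        d_side = {n.id for n in rn.nodes if n.ontology == "D"}
        assert d_side == {"D1", "D2", "D3", "D4", "D9", "D10", "D11", "D12"}
        assert rn.has_path("D0", "S2", "S3", "D11")  # the misdiagnosis chain

    def test_first_collection_annotations(self, fig3, fig3_anchor):
        rn = relatedness_network(fig3, fig3_anchor)
        first = {n.id: (n.first_i, n.first_j) for n in rn.nodes}
        assert first["D1"] == (0, 0)
        assert first["D9"] == (1, 0)
        state = ExpansionState(fig3, fig3_anchor)
        for node in rn.nodes:
            assert node.id in state.cell(node.first_i, node.first_j, node.ontology)

    def test_steps_zero_gives_initial_sets_only(self, fig3):
        rn = relatedness_network(fig3, AnchorSpec("D0", steps=0))
        assert rn.node_ids == {"D1", "D2", "S1", "S2"}

    def test_isolated_anchor_gives_empty_rn(self, fig3):
        rn = relatedness_network(fig3, AnchorSpec("D12", steps=2))
        assert rn.node_ids == set() and rn.edges == []


class TestDiagonalProfile:
    def test_worked_example_profile(self, fig3, fig3_anchor):
        profile, fixpoint = diagonal_profile(fig3, fig3_anchor, 3)
        assert profile[1]["D"] == {"D1", "D2", "D3", "D4", "D9", "D10"}
        assert profile[2]["D"] - profile[1]["D"] == {"D11", "D12"}
        assert fixpoint == 3

    def test_intra_chain_reaches_fixpoint_when_exhausted(self):
        net = BMKN()
        net.register_ontology("A")
        for k in range(4):
            net.add_concept(Concept(f"a{k}", f"a{k}", "A"))
        for k in range(3):
            net.add_edge(TypedEdge(f"a{k}", f"a{k+1}", "is_a"))
        profile, fixpoint = diagonal_profile(net, AnchorSpec("a0"), 5)
        assert fixpoint == 3
        assert profile[-1]["A"] == {"a1", "a2", "a3"}

    def test_isolated_anchor_fixpoint_zero(self, fig3):
        _, fixpoint = diagonal_profile(fig3, AnchorSpec("D12"), 2)
        assert fixpoint == 0
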