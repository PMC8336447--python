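import networkx as nx
import pytest

import admixorient as ao
from admixorient.moves import IllegalMove, edge_addition_is_legal

from oracles import edge_addition_by_surgery, tail_move_by_surgery


class TestReachability:
    @pytest.mark.parametrize("seed,h", [(0, 0), (1, 1), (2, 2)])
    def test_matches_per_pair_dfs(self, seed, h):
        net = ao.random_graph(6, h, seed).network
        index = ao.build_reachability(net)
        for u in net.graph.nodes:
            for v in net.graph.nodes:
                assert index.reaches(u, v) == nx.has_path(net.graph, u, v)

    def test_root_reaches_everything(self, m1):
        index = ao.build_reachability(m1.network)
        root = m1.network.root
        assert all(index.reaches(root, v) for v in m1.network.graph.nodes)


class TestEdgeAddition:
    def test_caterpillar_plus_d_to_a_arc_gives_the_case_study_topology(self, m1):
        tree = ao.DirectedNetwork.caterpillar(list("ABCDE"))
        net = ao.apply_edge_addition(
            tree, tree.pendant_edge("D"), tree.pendant_edge("A")
        )
        assert ao.same_modulo_root(net, m1.network)
        assert net.h == tree.h + 1
        assert net.graph.number_of_edges() == tree.graph.number_of_edges() + 3

    def test_self_pair_rejected(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCD"))
        e = tree.pendant_edge("A")
        with pytest.raises(IllegalMove):
            ao.apply_edge_addition(tree, e, e)

    def test_cycle_forcing_pair_rejected(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCD"))
        # f above e on the same root path: head(f) reaches tail(e)
        root = tree.root
        f = sorted(tree.graph.out_edges(root))[0]
        e = tree.pendant_edge("A")
        if not nx.has_path(tree.graph, f[1], e[0]):
            f = sorted(tree.graph.out_edges(root))[1]
        assert nx.has_path(tree.graph, f[1], e[0])
        with pytest.raises(IllegalMove):
            ao.apply_edge_addition(tree, e, f)

    def test_legality_predicate_matches_surgery_oracle_on_5_leaf_nets(self, m1):
        nets = [ao.DirectedNetwork.caterpillar(list("ABCDE")), m1.network]
        for net in nets:
            for e in net.edges():
                for f in net.edges():
                    if e == f:
                        continue
                    oracle = edge_addition_by_surgery(net, e, f)
                    assert edge_addition_is_legal(net, e, f) == (
                        oracle is not None
                    ), (e, f)
                    if oracle is not None:
                        assert ao.same_modulo_root(
                            ao.apply_edge_addition(net, e, f), oracle
                        )

    def test_neighborhood_size_is_bounded(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCDE"))
        nbhd = ao.enumerate_edge_additions(
            tree, ao.all_zero_labeling(tree), gene_flow_only=True
        )
        n_edges = tree.graph.number_of_edges()
        assert len(nbhd) <= n_edges * (n_edges - 1)
        for _, child, lab in nbhd:
            assert ao.validate_directed(child).ok
            assert lab is not None
            assert len(lab.gene_flow_edges()) == 1


class TestTailMoves:
    def test_move_then_inverse_recovers_start(self, m1):
        net = m1.network
        moves = ao.enumerate_tail_moves(net)
        assert moves
        _, child = moves[0]
        back = [c for _, c in ao.enumerate_tail_moves(child)]
        assert any(ao.same_modulo_root(b, net) for b in back)

    @pytest.mark.parametrize("name", ["tree", "m1"])
    def test_neighborhood_matches_surgery_oracle(self, name, m1):
        net = (
            ao.DirectedNetwork.caterpillar(list("ABCDE"))
            if name == "tree"
            else m1.network
        )
        ours = [child for _, child in ao.enumerate_tail_moves(net)]
        oracle = []
        for e in net.edges():
            for f in net.edges():
                child = tail_move_by_surgery(net, e, f)
                if child is not None:
                    oracle.append(child)
        # same neighborhoods as sets of modulo-root classes
        for child in ours:
            assert any(ao.same_modulo_root(child, o) for o in oracle)
        for o in oracle:
            assert any(ao.same_modulo_root(o, child) for child in ours)

    @pytest.mark.parametrize("seed,h", [(5, 1), (6, 2), (7, 0)])
    def test_all_neighbors_valid_and_counts_preserved(self, seed, h):
        net = ao.random_graph(6, h, seed).network
        for _, child in ao.enumerate_tail_moves(net):
            assert ao.validate_directed(child).ok
            assert child.h == net.h
            assert child.graph.number_of_edges() == net.graph.number_of_edges()
            assert len(child.graph) == len(net.graph)

    @pytest.mark.parametrize("seed", [8, 9])
    def test_neighborhoods_are_symmetric(self, seed):
        net = ao.random_graph(5, 1, seed).network
        for _, child in ao.enumerate_tail_moves(net)[:10]:
            back = [c for _, c in ao.enumerate_tail_moves(child)]
            assert any(ao.same_modulo_root(b, net) for b in back)


class TestHeadMoves:
    def test_sources_are_admixture_edges_and_h_preserved(self, m1):
        moves = ao.enumerate_head_moves(m1.network)
        assert moves
        (t,) = m1.network.admixture_nodes
        for mv, child in moves:
            assert mv.source[1] == t
            assert ao.validate_directed(child).ok
            assert child.h == m1.network.h

    def test_move_then_inverse_recovers_start(self, m1):
        _, child = ao.enumerate_head_moves(m1.network)[0]
        back = [c for _, c in ao.enumerate_head_moves(child)]
        assert any(ao.same_modulo_root(b, m1.network) for b in back)

    def test_no_head_move_turns_the_local_optimum_into_the_truth(
        self, m1, m1_report
    ):
        n1 = m1_report["n1"]
        for _, child in ao.enumerate_head_moves(n1):
            assert not ao.same_modulo_root(child, m1.network)


class TestMoveDistance:
    def test_zero_for_identical_networks(self, m1):
        assert ao.move_distance(m1.network, m1.network) == 0

    def test_one_for_a_single_tail_move(self, m1):
        _, child = ao.enumerate_tail_moves(m1.network)[0]
        d = ao.move_distance(m1.network, child, cap=2)
        assert d in (0, 1)  # some moves produce an isomorphic network

    def test_cap_sentinel(self, m1, m1_report):
        d = ao.move_distance(m1_report["n1"], m1.network, cap=2)
        assert d == ">=2"
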