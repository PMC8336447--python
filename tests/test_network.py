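import itertools

import networkx as nx
import pytest

import admixorient as ao
from admixorient.network import (
    TreeBasedLabeling,
    _labeling_from_choices,
    is_tree_based_labeling,
)


def _net(edges, labels):
    return ao.DirectedNetwork.from_edge_list(edges, labels)


class TestValidateDirected:
    def test_m1_fixture_is_valid(self, m1):
        assert ao.validate_directed(m1.network).ok

    def test_cycle_is_reported(self):
        net = _net(
            [(0, 1), (0, 2), (1, 3), (1, 4), (3, 1)],
            {2: "A", 4: "B"},
        )
        report = ao.validate_directed(net)
        assert not report.ok
        assert any("cycle" in v or "non-binary" in v for v in report.violations)

    def test_in2_out2_vertex_is_non_binary(self):
        # vertex 1 has in-degree 2 and out-degree 2 (degree sum 4)
        net = _net(
            [(0, 1), (0, 2), (2, 1), (2, 5), (1, 3), (1, 4)],
            {3: "A", 4: "B", 5: "C"},
        )
        report = ao.validate_directed(net)
        assert not report.ok
        assert any("non-binary" in v for v in report.violations)

    def test_unlabeled_leaf_is_reported(self):
        net = _net([(0, 1), (0, 2)], {1: "A"})
        report = ao.validate_directed(net)
        assert not report.ok


class TestToUndirected:
    def test_root_suppression_removes_one_edge(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCDE"))
        und = ao.to_undirected(tree)
        assert und.graph.number_of_edges() == tree.graph.number_of_edges() - 1
        assert all(und.graph.degree(v) in (1, 3) for v in und.graph.nodes)

    def test_admixture_node_has_degree_three(self, m1):
        und = ao.to_undirected(m1.network)
        (t,) = m1.network.admixture_nodes
        assert und.graph.degree(t) == 3

    def test_orientations_of_one_network_map_to_isomorphic_outputs(
        self, m1, m1_report
    ):
        # N1 and the truth are orientations of the same undirected network
        assert ao.is_isomorphic(
            ao.to_undirected(m1_report["n1"]), ao.to_undirected(m1.network)
        )


class TestIsomorphism:
    def test_internal_id_permutation_is_isomorphic(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCD"))
        und = ao.to_undirected(tree)
        mapping = {v: v + 100 for v in und.graph.nodes}
        permuted = ao.UndirectedNetwork(
            nx.relabel_nodes(und.graph, mapping),
            {mapping[v]: name for v, name in und.labels.items()},
        )
        assert ao.is_isomorphic(und, permuted)

    def test_different_splits_are_not_isomorphic(self):
        ab_cd = ao.to_undirected(ao.DirectedNetwork.caterpillar(list("ABCD")))
        ac_bd = ao.to_undirected(ao.DirectedNetwork.caterpillar(list("ACBD")))
        assert not ao.is_isomorphic(ab_cd, ac_bd)

    def test_label_set_mismatch_is_false(self):
        a = ao.to_undirected(ao.DirectedNetwork.caterpillar(list("ABCD")))
        b = ao.to_undirected(ao.DirectedNetwork.caterpillar(list("ABCE")))
        assert not ao.is_isomorphic(a, b)


class TestTreeBasedLabelings:
    def test_tree_has_single_all_zero_labeling(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCDE"))
        labelings = ao.enumerate_labelings(tree)
        assert len(labelings) == 1
        assert set(labelings[0].as_dict().values()) == {0}
        assert ao.find_tree_based_labeling(tree) == labelings[0]

    def test_m1_has_at_most_two_labelings_with_one_gene_flow_edge(self, m1):
        labelings = ao.enumerate_labelings(m1.network)
        assert 1 <= len(labelings) <= 2
        (t,) = m1.network.admixture_nodes
        for lab in labelings:
            flow = lab.gene_flow_edges()
            assert len(flow) == 1
            assert flow[0][1] == t

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_enumeration_matches_brute_force_on_h2_networks(self, seed):
        fx = ao.random_graph(6, 2, seed)
        net = fx.network
        admix = net.admixture_nodes
        in_edges = {m: sorted(net.graph.in_edges(m)) for m in admix}
        # independent filter of the 2^h gene-flow in-edge choices,
        # checking the three labeling rules directly
        expected = []
        for bits in itertools.product(range(2), repeat=len(admix)):
            choice = {m: in_edges[m][b] for m, b in zip(admix, bits)}
            lab = _labeling_from_choices(net, choice)
            psi = lab.as_dict()
            root = net.root
            ok = all(psi[e] == 0 for e in net.graph.out_edges(root))
            for v in net.graph.nodes:
                ins = [psi[e] for e in net.graph.in_edges(v)]
                if v != root and ins.count(0) != 1:
                    ok = False
                outs = [psi[e] for e in net.graph.out_edges(v)]
                if outs and 0 not in outs:
                    ok = False
            if ok:
                expected.append(lab)
        assert ao.enumerate_labelings(net) == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_find_agrees_with_enumeration(self, seed):
        fx = ao.random_graph(5 + seed % 3, min(2, 3 + seed % 3 - 2), seed)
        found = ao.find_tree_based_labeling(fx.network)
        all_labs = ao.enumerate_labelings(fx.network)
        if all_labs:
            assert found is not None
            assert found in all_labs
        else:
            assert found is None


class TestStructuralInvariants:
    @pytest.mark.parametrize("seed,h", [(0, 0), (1, 1), (2, 2), (3, 1)])
    def test_edge_count_identity(self, seed, h):
        net = ao.random_graph(6, h, seed).network
        g = net.graph
        assert g.number_of_edges() == len(g) - 1 + net.h
        assert net.h == h


class TestDisplayedTrees:
    def test_tree_displays_only_itself(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCD"))
        trees = ao.displayed_trees(tree)
        assert len(trees) == 1
        assert ao.is_isomorphic_directed(trees[0], tree)

    def test_m1_displays_the_two_expected_trees(self, m1):
        trees = ao.displayed_trees(m1.network)
        assert len(trees) == 2
        # one tree is the caterpillar with A sister to B; the other
        # attaches A below D's pendant edge
        cat = ao.DirectedNetwork.caterpillar(list("ABCDE"))
        alt = ao.DirectedNetwork.caterpillar(list("BCADE"))
        # build ((B,C),(A,D)),E shape: caterpillar helper cannot make it,
        # so check by triplet profile instead for the second tree
        assert sum(ao.is_isomorphic_directed(t, cat) for t in trees) == 1
        other = next(t for t in trees if not ao.is_isomorphic_directed(t, cat))
        prof = ao.triplet_profile(other)
        assert prof[frozenset("ABD")] == {(("A", "D"), "B")}

    @pytest.mark.parametrize("seed", [11, 12])
    def test_h2_networks_display_at_most_four_trees(self, seed):
        net = ao.random_graph(6, 2, seed).network
        trees = ao.displayed_trees(net)
        assert 1 <= len(trees) <= 4
        for t in trees:
            assert ao.validate_directed(t).ok
            assert t.h == 0
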