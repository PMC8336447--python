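import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import admixorient as ao
from admixorient.drift import DriftParams, F2Dataset, perfect_fit_loglik

from oracles import brownian_f2, tree_path_f2


def three_leaf_admixture(gamma):
    """Root rho with sides u (-> A) and v (-> C); B admixed between them."""
    # ids: 0=rho, 1=u, 2=v, 3=m, A=4, B=5, C=6
    net = ao.DirectedNetwork.from_edge_list(
        [(0, 1), (0, 2), (1, 4), (2, 6), (1, 3), (2, 3), (3, 5)],
        {4: "A", 5: "B", 6: "C"},
    )
    lengths = {
        (0, 1): 0.1, (0, 2): 0.1, (1, 4): 0.3, (2, 6): 0.4,
        (1, 3): 0.0, (2, 3): 0.0, (3, 5): 0.1,
    }
    params = DriftParams(
        lengths=lengths, gammas={3: gamma}, gamma_edges={3: (1, 3)}
    )
    return net, params


class TestPathWeights:
    def test_tree_weights_are_indicator_of_root_path(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABCD"))
        params = DriftParams(lengths={e: 0.1 for e in tree.edges()})
        weights = ao.path_weights(tree, params)
        import networkx as nx

        for name, p in weights.items():
            leaf = tree.leaf_of(name)
            path = nx.shortest_path(tree.graph, tree.root, leaf)
            on_path = set(zip(path[:-1], path[1:]))
            for e, w in p.items():
                assert w == (1.0 if e in on_path else 0.0)

    def test_symmetric_admixture_splits_weight_in_half(self):
        net, params = three_leaf_admixture(0.5)
        w = ao.path_weights(net, params)["B"]
        assert w[(3, 5)] == 1.0
        assert w[(1, 3)] == w[(2, 3)] == 0.5
        assert w[(0, 1)] == w[(0, 2)] == 0.5

    def test_asymmetric_gamma_propagates_to_root_edge(self):
        net, params = three_leaf_admixture(0.25)
        w = ao.path_weights(net, params)["B"]
        assert w[(0, 1)] == pytest.approx(0.25)
        assert w[(0, 2)] == pytest.approx(0.75)

    def test_flow_conservation(self, m1):
        weights = ao.path_weights(m1.network, m1.params)
        g = m1.network.graph
        for name, p in weights.items():
            leaf = m1.network.leaf_of(name)
            for v in g.nodes:
                if v in (m1.network.root, leaf):
                    continue
                inflow = sum(p[e] for e in g.in_edges(v))
                outflow = sum(p[e] for e in g.out_edges(v))
                assert inflow == pytest.approx(outflow, abs=1e-12)


class TestExpectedF2:
    def test_tree_pair_is_path_length_sum(self):
        tree = ao.DirectedNetwork.caterpillar(list("ABC"))
        lengths = {e: 0.1 * (i + 1) for i, e in enumerate(tree.edges())}
        params = DriftParams(lengths=lengths)
        y = ao.expected_f2(tree, params)
        oracle = tree_path_f2(tree, lengths)
        pairs = ao.leaf_pairs(tree.populations)
        for k, pair in enumerate(pairs):
            assert y[k] == pytest.approx(oracle[pair], abs=1e-12)

    def test_hand_computed_admixed_pair(self):
        net, params = three_leaf_admixture(0.5)
        y = ao.expected_f2(net, params)
        pairs = ao.leaf_pairs(["A", "B", "C"])
        f2 = dict(zip(pairs, y))
        # A-B: 0.25*(0.1+0.1) + 0.3 + 0.1; A-C is the plain path sum
        assert f2[("A", "B")] == pytest.approx(0.45)
        assert f2[("A", "C")] == pytest.approx(0.9)

    @pytest.mark.parametrize("gamma", [0.5, 0.25])
    def test_monte_carlo_brownian_oracle(self, gamma):
        net, params = three_leaf_admixture(gamma)
        n_reps = 100_000
        mc = brownian_f2(
            net, params.lengths, params.gammas, params.gamma_edges,
            n_reps, seed=1234,
        )
        y = ao.expected_f2(net, params)
        pairs = ao.leaf_pairs(net.populations)
        for k, pair in enumerate(pairs):
            # sd of a squared-Gaussian mean is about sqrt(2)*Y/sqrt(R)
            tol = 3 * math.sqrt(2.0) * y[k] / math.sqrt(n_reps)
            assert mc[pair] == pytest.approx(y[k], abs=tol)

    def test_root_relocation_invariance(self):
        net, params = three_leaf_admixture(0.3)
        # slide the root along the edge toward u: rho' -> u (0.02) and
        # the remainder merges into the edge toward v (0.08 + 0.1)
        moved = ao.DirectedNetwork.from_edge_list(
            [(7, 1), (7, 2), (1, 4), (2, 6), (1, 3), (2, 3), (3, 5)],
            {4: "A", 5: "B", 6: "C"},
        )
        lengths = dict(params.lengths)
        del lengths[(0, 1)], lengths[(0, 2)]
        lengths[(7, 1)] = 0.02
        lengths[(7, 2)] = 0.08 + 0.1
        moved_params = DriftParams(
            lengths=lengths, gammas={3: 0.3}, gamma_edges={3: (1, 3)}
        )
        np.testing.assert_allclose(
            ao.expected_f2(net, params), ao.expected_f2(moved, moved_params),
            atol=1e-12,
        )


class TestLogLikelihood:
    def test_perfect_fit_closed_forms(self):
        # -(n/2)(2 ln z + ln 2 pi) at z = 1e-4
        assert round(perfect_fit_loglik(10, 1e-4)) == 83
        assert round(perfect_fit_loglik(15, 1e-4)) == 124
        assert perfect_fit_loglik(10, 1e-4) == pytest.approx(82.914, abs=5e-4)

    def test_perfect_fit_equals_closed_form_via_likelihood(self):
        pairs = ao.leaf_pairs(list("ABCDE"))
        x = np.linspace(0.1, 0.5, len(pairs))
        data = F2Dataset(pairs, x, np.full(len(pairs), 1e-4))
        assert ao.log_likelihood(data, x) == pytest.approx(
            perfect_fit_loglik(len(pairs), 1e-4)
        )

    def test_single_pair_one_sigma_contribution(self):
        data = F2Dataset([("A", "B")], np.array([0.2]), np.array([0.01]))
        y = np.array([0.2 - 0.01])
        expected = -0.5 * (1.0 + 2.0 * math.log(0.01) + math.log(2 * math.pi))
        assert ao.log_likelihood(data, y) == pytest.approx(expected)

    def test_maximized_at_observed_vector(self):
        pairs = ao.leaf_pairs(list("ABCD"))
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.4, len(pairs))
        data = F2Dataset(pairs, x, np.full(len(pairs), 1e-3))
        at_x = ao.log_likelihood(data, x)
        for _ in range(10):
            assert ao.log_likelihood(data, x + rng.normal(0, 1e-3, len(x))) < at_x

    def test_nonpositive_se_rejected(self):
        pairs = [("A", "B")]
        with pytest.raises(ValueError):
            F2Dataset(pairs, np.array([0.1]), np.array([0.0]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_no_expected_vector_beats_the_observed_one(self, seed):
        rng = np.random.default_rng(seed)
        pairs = ao.leaf_pairs(list("ABCD"))
        x = rng.uniform(0.01, 0.5, len(pairs))
        se = float(rng.uniform(1e-4, 1e-2))
        data = F2Dataset(pairs, x, np.full(len(pairs), se))
        y = x + rng.normal(0.0, se, len(x))
        assert ao.log_likelihood(data, y) <= ao.log_likelihood(data, x)


class TestResiduals:
    def test_zero_at_perfect_fit_and_single_shift(self, m1):
        y = m1.data.reordered().x.copy()
        raw, scaled = ao.residuals(m1.data.reordered(), y)
        assert np.all(raw == 0) and np.all(scaled == 0)
        y2 = y.copy()
        y2[3] += 1e-3
        raw, scaled = ao.residuals(m1.data.reordered(), y2)
        assert raw[3] == pytest.approx(-1e-3)
        assert np.count_nonzero(raw) == 1
        assert scaled[3] == pytest.approx(-10.0)
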