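"""Model fixtures and the noisy f2 simulator.

``make_m1`` builds the five-population case-study model in which a
starting-tree-based search without the orientation step is trapped in a
local optimum: a caterpillar tree on A..E rooted at E, with an edge
addition from the pendant edge of D onto the pendant edge of A, so that
A is admixed.  The numeric constants are fixture choices; the
phenomenology they must produce (the true network is the unique global
optimum among one-event networks, the NJ/ML tree is not a base tree of
the truth, and the best edge addition from that tree makes E admixed)
is asserted by :func:`validate_m1`.

``random_graph`` produces generic random admixture-graph fixtures, and
``simulate_f2`` adds independent Gaussian noise to a fixture's exact f2
vector, emulating finite-data sampling error of the summary statistics.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .drift import (
    DriftParams,
    F2Dataset,
    default_gamma_edges,
    expected_f2,
    leaf_pairs,
)
from .fitting import score_graph
from .metrics import triplet_distance
from .moves import apply_edge_addition, enumerate_edge_additions
from .network import (
    DirectedNetwork,
    all_zero_labeling,
    displayed_trees,
    is_isomorphic_directed,
    same_modulo_root,
    validate_directed,
)

DEFAULT_SE = 1e-4


@dataclass(eq=False)
class ModelFixture:
    """A ground-truth admixture graph with its exact f2 dataset."""

    name: str
    network: DirectedNetwork
    params: DriftParams
    data: F2Dataset

    @property
    def outgroup(self) -> Optional[str]:
        """A population whose pendant edge hangs off the root, if any."""
        root = self.network.root
        for child in self.network.graph.successors(root):
            if child in self.network.labels:
                return self.network.labels[child]
        return None


def _exact_dataset(net: DirectedNetwork, params: DriftParams, se: float) -> F2Dataset:
    pairs = leaf_pairs(net.populations)
    y = expected_f2(net, params)
    return F2Dataset(pairs, y.copy(), np.full(len(pairs), se))


# -- the M1 case-study fixture ------------------------------------------

# Drift lengths (units of drift) for the true network; keys are symbolic
# edge names resolved in make_m1.  Chosen so that the admixture signal
# pulls A strongly toward the D lineage, which is what defeats the
# starting tree.
_M1_LENGTHS = {
    ("rho", "E"): 0.0909,
    ("rho", "v3"): 0.1911,
    ("v3", "s"): 0.1025,
    ("s", "D"): 0.0879,
    ("v3", "v2"): 0.1259,
    ("v2", "C"): 0.1990,
    ("v2", "v1"): 0.1900,
    ("v1", "B"): 0.0947,
    ("v1", "t"): 0.1528,
    ("s", "t"): 0.1020,
    ("t", "A"): 0.1082,
}
_M1_GAMMA = 0.671  # weight on the gene-flow arc s -> t into A


def make_m1(se: float = DEFAULT_SE) -> ModelFixture:
    """The five-population case-study fixture (one admixed leaf, A)."""
    net = DirectedNetwork.caterpillar(["A", "B", "C", "D", "E"])
    # the caterpillar is ((((A,B),C),D),E); add the gene-flow arc from
    # the pendant edge of D onto the pendant edge of A
    e = net.pendant_edge("D")
    f = net.pendant_edge("A")
    net = apply_edge_addition(net, e, f)
    ids = _m1_vertex_names(net)
    lengths = {
        (ids[a], ids[b]): c for (a, b), c in _M1_LENGTHS.items()
    }
    t = ids["t"]
    params = DriftParams(
        lengths=lengths,
        gammas={t: _M1_GAMMA},
        gamma_edges={t: (ids["s"], t)},
    )
    params.validate(net)
    return ModelFixture("M1", net, params, _exact_dataset(net, params, se))


def _m1_vertex_names(net: DirectedNetwork) -> dict:
    """Symbolic names for the M1 vertices, keyed by structure."""
    g = net.graph
    names = {}
    root = net.root
    names["rho"] = root
    for v, lab in net.labels.items():
        names[lab] = v
    (t,) = net.admixture_nodes
    names["t"] = t
    a = net.leaf_of("A")
    d = net.leaf_of("D")
    (s,) = [p for p in g.predecessors(t) if d in g.successors(p)]
    names["s"] = s
    (v1,) = [p for p in g.predecessors(t) if p != s]
    names["v1"] = v1
    (v2,) = g.predecessors(v1)
    names["v2"] = v2
    (v3,) = g.predecessors(v2)
    names["v3"] = v3
    return names


def all_one_event_networks(populations: List[str]):
    """Every network with one admixture node, modulo the root position.

    Generated by applying every legal edge addition to every rooted
    tree topology and deduplicating by isomorphism of the derooted
    admixture-marked graph.  Used for brute-force optimality checks on
    small population sets.
    """
    from .network import network_hash
    from .search import _all_unrooted_topologies
    from .orientation import OrientationSpec, orient

    buckets: dict = {}
    nets: List[DirectedNetwork] = []
    for u in _all_unrooted_topologies(sorted(populations)):
        for root_edge in sorted(tuple(sorted(e)) for e in u.graph.edges()):
            rooted = orient(u, OrientationSpec(root_edge, frozenset()))
            if rooted is None:
                continue
            for _, child, _lab in enumerate_edge_additions(
                rooted, all_zero_labeling(rooted), gene_flow_only=True
            ):
                bucket = buckets.setdefault(network_hash(child), [])
                if not any(same_modulo_root(child, other) for other in bucket):
                    bucket.append(child)
                    nets.append(child)
    return nets


def validate_m1(fixture: Optional[ModelFixture] = None, full: bool = False) -> dict:
    """Assert the case-study phenomenology of the M1 fixture.

    Always checks: (ii) the NJ/ML starting tree is not a base tree of
    the truth, and (iii) the best gene-flow edge addition from that tree
    yields a network with E admixed.  With ``full=True`` additionally
    checks (i): the truth is the unique global optimum over all
    one-event networks on five populations (brute force).  Returns a
    small report dict; raises AssertionError on any failure.
    """
    from .search import SearchConfig, starting_tree

    fx = fixture or make_m1()
    truth = fx.network
    config = SearchConfig(num_admixture=1, outgroup="E")
    n0 = starting_tree(fx.data, config)
    base_trees = displayed_trees(truth)
    assert not any(
        is_isomorphic_directed(n0, bt) for bt in base_trees
    ), "starting tree must not be a base tree of the truth"

    best = None
    for _, child, lab in enumerate_edge_additions(
        n0, all_zero_labeling(n0), gene_flow_only=True
    ):
        fit, _ = score_graph(child, fx.data, "treemix")
        if best is None or fit.loglik > best[1] + 1e-9:
            best = (child, fit.loglik)
    assert best is not None
    n1 = best[0]
    (m,) = n1.admixture_nodes
    admixed_leaf = _admixed_population(n1)
    assert admixed_leaf == "E", f"expected E admixed in N1, got {admixed_leaf}"

    report = {
        "n0": n0,
        "n1": n1,
        "n1_loglik": best[1],
        "triplet_distance_n1": triplet_distance(n1, truth),
    }
    if full:
        truth_fit, _ = score_graph(truth, fx.data, "treemix")
        for cand in all_one_event_networks(truth.populations):
            if same_modulo_root(cand, truth):
                continue
            fit, _ = score_graph(cand, fx.data, "treemix")
            assert fit.loglik < truth_fit.loglik - 1e-6, (
                "a non-true one-event network matches the optimum"
            )
        report["global_optimum"] = True
    return report


def _admixed_population(net: DirectedNetwork) -> Optional[str]:
    """The population under the admixture node, if it is leaf-incident."""
    import networkx as nx

    (m,) = net.admixture_nodes
    below = nx.descendants(net.graph, m) | {m}
    leaves = sorted(net.labels[v] for v in below if v in net.labels)
    return leaves[0] if len(leaves) == 1 else None


# -- random fixtures -----------------------------------------------------


def _population_names(n: int) -> List[str]:
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [f"P{i:02d}" for i in range(n)]


def random_graph(
    n_pops: int,
    h: int,
    seed: int,
    se: float = DEFAULT_SE,
) -> ModelFixture:
    """Random admixture-graph fixture: random tree plus h gene-flow arcs.

    The first population is attached directly below the root so it can
    serve as an outgroup; its pendant edge is excluded from edge
    additions.  Lengths ~ U(0.01, 0.5), proportions ~ U(0.1, 0.9).
    """
    if h > n_pops - 2:
        raise ValueError("h must be at most n_pops - 2")
    rng = np.random.default_rng(seed)
    pops = _population_names(n_pops)
    import networkx as nx

    g = nx.DiGraph()
    labels = {}
    # random rooted tree on pops[1:], outgroup pops[0] at the root
    leaf_ids = list(range(1, n_pops))
    for i, p in zip(leaf_ids, pops[1:]):
        labels[i] = p
    nxt = n_pops
    sub_root = leaf_ids[0]
    for leaf in leaf_ids[1:]:
        if g.number_of_edges() == 0:
            g.add_edge(nxt, sub_root)
            g.add_edge(nxt, leaf)
            sub_root = nxt
            nxt += 1
            continue
        e = sorted(g.edges())[rng.integers(g.number_of_edges())]
        w = nxt
        nxt += 1
        g.remove_edge(*e)
        g.add_edge(e[0], w)
        g.add_edge(w, e[1])
        g.add_edge(w, leaf)
    root = nxt
    og = 0
    labels[og] = pops[0]
    g.add_edge(root, og)
    g.add_edge(root, sub_root)
    net = DirectedNetwork(g, labels)
    labeling = all_zero_labeling(net)
    for _ in range(h):
        og_edge = net.pendant_edge(pops[0])
        options = [
            (mv, child, lab)
            for mv, child, lab in enumerate_edge_additions(
                net, labeling, gene_flow_only=True
            )
            if mv.source != og_edge and mv.target != og_edge
        ]
        if not options:
            raise ValueError("no legal gene-flow edge addition remains")
        _, net, labeling = options[rng.integers(len(options))]
    report = validate_directed(net)
    assert report.ok, report.violations
    lengths = {e: float(rng.uniform(0.01, 0.5)) for e in net.edges()}
    gamma_edges = default_gamma_edges(net)
    gammas = {m: float(rng.uniform(0.1, 0.9)) for m in net.admixture_nodes}
    params = DriftParams(lengths=lengths, gammas=gammas, gamma_edges=gamma_edges)
    params.validate(net)
    return ModelFixture(
        f"random-n{n_pops}-h{h}-s{seed}", net, params, _exact_dataset(net, params, se)
    )


def simulate_f2(
    fixture: ModelFixture, se: float, seed: int
) -> F2Dataset:
    """Noisy dataset: X_i = Y_i + se * eps_i with independent N(0,1) eps."""
    if se <= 0:
        raise ValueError("se must be positive")
    rng = np.random.default_rng(seed)
    y = fixture.data.reordered().x  # exact expected f2 of the fixture
    pairs = leaf_pairs(fixture.network.populations)
    x = y + se * rng.standard_normal(len(pairs))
    return F2Dataset(pairs, x, np.full(len(pairs), se))
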