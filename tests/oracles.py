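"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own optimized code paths: the
orientation oracle enumerates every direction assignment, the move
oracles perform direct graph surgery followed by validation, and the
Monte-Carlo oracle simulates Brownian drift increments edge by edge.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from admixorient import (
    DirectedNetwork,
    UndirectedNetwork,
    validate_directed,
)


def orientations_by_assignment(
    u: UndirectedNetwork,
    root_edge: Tuple[int, int],
    admix_set: frozenset,
) -> List[DirectedNetwork]:
    """All valid orientations found by trying every direction assignment.

    The root subdivides ``root_edge`` with both halves directed outward;
    every other edge is assigned each direction in turn.  A candidate is
    kept when it is a valid directed network whose admixture-node set is
    exactly ``admix_set``.
    """
    edges = [tuple(sorted(e)) for e in u.graph.edges()]
    root_edge = tuple(sorted(root_edge))
    others = sorted(e for e in edges if e != root_edge)
    root = max(u.graph.nodes) + 1
    found = []
    for bits in itertools.product((0, 1), repeat=len(others)):
        g = nx.DiGraph()
        g.add_nodes_from(u.graph.nodes)
        g.add_edge(root, root_edge[0])
        g.add_edge(root, root_edge[1])
        for e, b in zip(others, bits):
            g.add_edge(e[b], e[1 - b])
        net = DirectedNetwork(g, dict(u.labels))
        if not validate_directed(net).ok:
            continue
        if set(net.admixture_nodes) != set(admix_set):
            continue
        found.append(net)
    return found


def edge_addition_by_surgery(
    net: DirectedNetwork, e: Tuple[int, int], f: Tuple[int, int]
) -> Optional[DirectedNetwork]:
    """Apply-and-validate edge addition with no legality shortcut."""
    if e == f:
        return None
    g = net.graph.copy()
    s = max(g.nodes) + 1
    t = s + 1
    g.remove_edge(*e)
    g.add_edge(e[0], s)
    g.add_edge(s, e[1])
    g.remove_edge(*f)
    g.add_edge(f[0], t)
    g.add_edge(t, f[1])
    g.add_edge(s, t)
    out = DirectedNetwork(g, dict(net.labels))
    return out if validate_directed(out).ok else None


def tail_move_by_surgery(
    net: DirectedNetwork, e: Tuple[int, int], f: Tuple[int, int]
) -> Optional[DirectedNetwork]:
    """Direct tail-move surgery: detach, suppress, subdivide, validate."""
    if e == f or not net.graph.has_edge(*e) or not net.graph.has_edge(*f):
        return None
    u, v = e
    g = net.graph.copy()
    g.remove_edge(u, v)
    merged = None
    if g.in_degree(u) == 1 and g.out_degree(u) == 1:
        (p,) = g.predecessors(u)
        (c,) = g.successors(u)
        if p == c or g.has_edge(p, c):
            return None
        g.remove_node(u)
        g.add_edge(p, c)
        merged = (p, c)
    elif g.in_degree(u) == 0 and g.out_degree(u) == 1:
        g.remove_node(u)
    else:
        return None
    tgt = f
    if not g.has_edge(*tgt):
        if merged is not None and f in ((merged[0], u), (u, merged[1])):
            tgt = merged
        else:
            return None
    w = max(g.nodes) + 1
    g.remove_edge(*tgt)
    g.add_edge(tgt[0], w)
    g.add_edge(w, tgt[1])
    if g.has_edge(w, v):
        return None
    g.add_edge(w, v)
    out = DirectedNetwork(g, dict(net.labels))
    if not validate_directed(out).ok:
        return None
    if len(out.admixture_nodes) != len(net.admixture_nodes):
        return None
    return out


def brownian_f2(
    net: DirectedNetwork,
    lengths: Dict[Tuple[int, int], float],
    gammas: Dict[int, float],
    gamma_edges: Dict[int, Tuple[int, int]],
    n_reps: int,
    seed: int,
) -> Dict[Tuple[str, str], float]:
    """Monte-Carlo f2 via simulated Brownian drift of allele frequencies.

    Each replicate draws an independent Gaussian increment of variance
    c_e on every edge; an admixture node's frequency is the γ-weighted
    average of the frequencies arriving along its two incoming edges
    (allele frequencies mix linearly under admixture).
    """
    rng = np.random.default_rng(seed)
    g = net.graph
    topo = list(nx.topological_sort(g))
    vals = {net.root: np.zeros(n_reps)}
    for v in topo:
        if v == net.root:
            continue
        in_edges = sorted(g.in_edges(v))
        if len(in_edges) == 1:
            (e,) = in_edges
            vals[v] = vals[e[0]] + np.sqrt(lengths[e]) * rng.standard_normal(n_reps)
        else:
            e_gamma = gamma_edges[v]
            e_other = next(e for e in in_edges if e != e_gamma)
            gm = gammas[v]
            via_gamma = vals[e_gamma[0]] + np.sqrt(lengths[e_gamma]) * rng.standard_normal(n_reps)
            via_other = vals[e_other[0]] + np.sqrt(lengths[e_other]) * rng.standard_normal(n_reps)
            vals[v] = gm * via_gamma + (1.0 - gm) * via_other
    leaves = {name: vals[v] for v, name in net.labels.items()}
    out = {}
    for a, b in itertools.combinations(sorted(leaves), 2):
        out[(a, b)] = float(np.mean((leaves[a] - leaves[b]) ** 2))
    return out


def tree_path_f2(
    net: DirectedNetwork, lengths: Dict[Tuple[int, int], float]
) -> Dict[Tuple[str, str], float]:
    """Pairwise path-length distances on a tree (independent of the model)."""
    g = nx.Graph()
    for u, v in net.graph.edges():
        g.add_edge(u, v, weight=lengths[(u, v)])
    out = {}
    leaves = {name: v for v, name in net.labels.items()}
    for a, b in itertools.combinations(sorted(leaves), 2):
        out[(a, b)] = nx.shortest_path_length(
            g, leaves[a], leaves[b], weight="weight"
        )
    return out
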