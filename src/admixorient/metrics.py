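"""Topological accuracy metrics for admixture graphs.

The triplet distance between two networks counts the 3-leaf subsets on
which they display different sets of rooted triplet topologies, where a
network's triplet set for {a, b, c} is the union over its displayed
trees of the single rooted triplet each tree induces.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Set, Tuple

import networkx as nx

from .network import DirectedNetwork, displayed_trees

Triplet = Tuple[Tuple[str, str], str]  # ((a, b), c) means ab|c


def _tree_triplets(tree: DirectedNetwork) -> Dict[FrozenSet[str], Triplet]:
    """Rooted triplet topology per 3-subset of a displayed tree."""
    g = tree.graph
    root = tree.root
    leaves = {name: v for v, name in tree.labels.items()}
    ancestors = {
        name: nx.ancestors(g, v) | {v} for name, v in leaves.items()
    }
    depth = nx.shortest_path_length(g, root)
    out: Dict[FrozenSet[str], Triplet] = {}
    for a, b, c in itertools.combinations(sorted(leaves), 3):
        best_pair, best_depth = None, -1
        for x, y in ((a, b), (a, c), (b, c)):
            mrca = max(ancestors[x] & ancestors[y], key=lambda v: depth[v])
            if depth[mrca] > best_depth:
                best_pair, best_depth = (x, y), depth[mrca]
        z = ({a, b, c} - set(best_pair)).pop()
        out[frozenset((a, b, c))] = (tuple(sorted(best_pair)), z)
    return out


def triplet_profile(net: DirectedNetwork) -> Dict[FrozenSet[str], Set[Triplet]]:
    """Union of displayed-tree triplets per 3-subset of populations."""
    profile: Dict[FrozenSet[str], Set[Triplet]] = {
        frozenset(t): set()
        for t in itertools.combinations(net.populations, 3)
    }
    for tree in displayed_trees(net):
        for key, trip in _tree_triplets(tree).items():
            profile[key].add(trip)
    return profile


def triplet_distance(a: DirectedNetwork, b: DirectedNetwork) -> int:
    """Number of 3-subsets whose displayed triplet sets differ."""
    if a.populations != b.populations:
        raise ValueError("networks are labeled by different population sets")
    pa, pb = triplet_profile(a), triplet_profile(b)
    return sum(1 for key in pa if pa[key] != pb[key])
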