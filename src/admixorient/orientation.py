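"""Orienting undirected networks and maximum-likelihood orientation search.

Specifying a root edge and the set of admixture nodes determines at most
one valid orientation of an undirected binary network; it can be found
by constraint propagation on required in-degrees.  The orientation
neighborhood of a directed network N is the set of valid orientations of
its undirected version; restricting the root to the outgroup's pendant
edge gives the outgroup-rooted neighborhood searched by the
maximum-likelihood network orientation (MLNO) step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import networkx as nx

from .drift import F2Dataset
from .fitting import FitResult, score_graph
from .network import (
    DirectedNetwork,
    Edge,
    UndirectedNetwork,
    is_isomorphic_directed,
    to_undirected,
    validate_directed,
)


@dataclass(frozen=True)
class OrientationSpec:
    """Root edge to subdivide plus the vertices designated as admixed."""

    root_edge: Edge
    admix_set: FrozenSet[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "admix_set", frozenset(self.admix_set))


def orient(u: UndirectedNetwork, spec: OrientationSpec) -> Optional[DirectedNetwork]:
    """Unique valid orientation for the spec, or ``None`` if none exists.

    The root subdivides ``root_edge`` and directs both incident edges
    outward; every other vertex has a required in-degree (2 for members
    of ``admix_set``, 1 otherwise).  Constraint propagation repeatedly
    directs edges away from saturated vertices and toward vertices whose
    remaining undirected edges are all needed as incoming.  Returns
    ``None`` on a stall, a conflict, or a final graph that fails
    validation.
    """
    ra, rb = spec.root_edge
    if not u.graph.has_edge(ra, rb):
        raise ValueError(f"root edge {spec.root_edge} not in network")
    bad = spec.admix_set - set(u.internal_vertices)
    if bad:
        raise ValueError(f"admixture candidates {sorted(bad)} are not internal vertices")

    root = max(u.graph.nodes, default=-1) + 1
    required: Dict[int, int] = {}
    for v in u.graph.nodes:
        if u.graph.degree(v) == 1:
            required[v] = 1
        else:
            required[v] = 2 if v in spec.admix_set else 1
    required[root] = 0

    directed = nx.DiGraph()
    directed.add_nodes_from(u.graph.nodes)
    directed.add_node(root)
    undecided: Set[Tuple[int, int]] = {
        tuple(sorted(e)) for e in u.graph.edges() if tuple(sorted(e)) != tuple(sorted((ra, rb)))
    }
    in_count = {v: 0 for v in required}
    incident: Dict[int, Set[Tuple[int, int]]] = {v: set() for v in required}
    for e in undecided:
        incident[e[0]].add(e)
        incident[e[1]].add(e)

    def assign(edge: Tuple[int, int], tail: int, head: int) -> bool:
        """Direct edge tail→head; False on conflict."""
        undecided.discard(edge)
        incident[edge[0]].discard(edge)
        incident[edge[1]].discard(edge)
        directed.add_edge(tail, head)
        in_count[head] += 1
        return in_count[head] <= required[head]

    directed.add_edge(root, ra)
    directed.add_edge(root, rb)
    in_count[ra] += 1
    in_count[rb] += 1
    if in_count[ra] > required[ra] or in_count[rb] > required[rb]:
        return None

    progress = True
    while progress and undecided:
        progress = False
        for v in sorted(required):
            pending = sorted(incident[v])
            if not pending:
                continue
            deficit = required[v] - in_count[v]
            if deficit < 0:
                return None
            if deficit == 0:
                for e in pending:
                    other = e[0] if e[1] == v else e[1]
                    if not assign(e, v, other):
                        return None
                progress = True
            elif deficit == len(pending):
                for e in pending:
                    other = e[0] if e[1] == v else e[1]
                    if not assign(e, other, v):
                        return None
                progress = True
    if undecided:
        return None
    net = DirectedNetwork(directed, dict(u.labels))
    report = validate_directed(net)
    if not report.ok:
        return None
    if set(net.admixture_nodes) != set(spec.admix_set):
        return None
    return net


def enumerate_orientations(
    n: DirectedNetwork,
    outgroup: str,
    all_roots: bool = False,
) -> List[DirectedNetwork]:
    """Valid orientations of n's undirected version, deduplicated.

    By default the root is restricted to the outgroup's pendant edge
    (the outgroup-rooted orientation neighborhood); ``all_roots`` lifts
    the restriction.  Admixture sets range over all ways of choosing h
    internal vertices.  Deterministic order: root edges then admixture
    sets, both lexicographic.
    """
    if outgroup not in n.populations:
        raise ValueError(f"unknown outgroup {outgroup!r}")
    u = to_undirected(n)
    h = n.h
    root_edges: List[Edge]
    if all_roots:
        root_edges = sorted(tuple(sorted(e)) for e in u.graph.edges())
    else:
        root_edges = [u.pendant_edge(outgroup)]
    candidates = [v for v in u.internal_vertices]
    out: List[DirectedNetwork] = []
    for root_edge in root_edges:
        for admix in itertools.combinations(candidates, h):
            net = orient(u, OrientationSpec(root_edge, frozenset(admix)))
            if net is None:
                continue
            if any(is_isomorphic_directed(net, o) for o in out):
                continue
            out.append(net)
    return out


def mlno(
    n: DirectedNetwork,
    data: F2Dataset,
    convention: str = "treemix",
    outgroup: Optional[str] = None,
    all_roots: bool = False,
    max_h: int = 6,
) -> Tuple[DirectedNetwork, FitResult]:
    """Exhaustive maximum-likelihood network orientation.

    Scores every member of the (outgroup-rooted) orientation
    neighborhood of n with :func:`score_graph` and returns the argmax,
    ties broken by enumeration order.  The input network's own refit is
    the fallback, so the returned likelihood never decreases.
    """
    if n.h > max_h:
        raise ValueError(
            f"h={n.h} exceeds the exhaustive-search cap {max_h}; "
            "constrain the search or raise max_h"
        )
    if outgroup is None:
        raise ValueError("an outgroup population is required")
    best_net = n
    best_fit, _ = score_graph(n, data, convention)
    try:
        orientations = enumerate_orientations(n, outgroup, all_roots=all_roots)
    except ValueError:
        # the undirected version is not a simple binary network (root
        # children adjacent); the input refit is the only candidate
        return best_net, best_fit
    for cand in orientations:
        try:
            fit, _ = score_graph(cand, data, convention)
        except ValueError:
            continue  # no tree-based labeling under the treemix convention
        if fit.loglik > best_fit.loglik:
            best_net, best_fit = cand, fit
    return best_net, best_fit
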