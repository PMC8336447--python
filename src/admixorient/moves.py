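"""Topology-modifying moves on directed networks and their neighborhoods.

Three elementary rearrangements are implemented:

* edge addition — subdivide edges e and f with new vertices s and t and
  add the linking arc s→t, creating one new admixture node;
* tail move — relocate the tail (source vertex) of an edge so that it
  subdivides another edge;
* head move — relocate the head (target vertex) of an admixture edge.

A move is *legal* when the result is again a valid binary network.  For
edge additions, legality is decided by a reachability precomputation
(the linking arc s→t creates a cycle exactly when head(f) already
reaches tail(e)); for the other moves the candidate network is built and
validated directly.  Both routes are cross-checked against each other in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple, Union

import networkx as nx

from .network import (
    DirectedNetwork,
    Edge,
    TreeBasedLabeling,
    network_hash,
    same_modulo_root,
    suppress_degree_two,
    validate_directed,
)


@dataclass(frozen=True)
class Move:
    kind: str  # "edge_addition" | "tail" | "head"
    source: Edge
    target: Edge


class IllegalMove(ValueError):
    pass


# -- reachability --------------------------------------------------------


class ReachabilityIndex:
    """Transitive closure of the network DAG: R[u] = vertices reachable from u."""

    def __init__(self, reach: Dict[int, Set[int]]):
        self.reach = reach

    def reaches(self, u: int, v: int) -> bool:
        return v in self.reach[u]


def build_reachability(net: DirectedNetwork) -> ReachabilityIndex:
    """Closure computed in one reverse-topological sweep."""
    g = net.graph
    reach: Dict[int, Set[int]] = {}
    for v in reversed(list(nx.topological_sort(g))):
        acc: Set[int] = {v}
        for c in g.successors(v):
            acc |= reach[c]
        reach[v] = acc
    return ReachabilityIndex(reach)


# -- edge addition -------------------------------------------------------


def edge_addition_is_legal(
    net: DirectedNetwork, e: Edge, f: Edge, index: Optional[ReachabilityIndex] = None
) -> bool:
    if e == f or not net.graph.has_edge(*e) or not net.graph.has_edge(*f):
        return False
    if index is None:
        index = build_reachability(net)
    # the linking arc runs from inside e to inside f; a cycle appears iff
    # head(f) already reaches tail(e)
    if index.reaches(f[1], e[0]):
        return False
    return True


def apply_edge_addition(net: DirectedNetwork, e: Edge, f: Edge) -> DirectedNetwork:
    """Subdivide e with s and f with t and add the linking arc s→t."""
    if not edge_addition_is_legal(net, e, f):
        raise IllegalMove(f"illegal edge addition {e} -> {f}")
    out = net.copy()
    s = out.fresh_id()
    t = s + 1
    g = out.graph
    g.remove_edge(*e)
    g.add_edge(e[0], s)
    g.add_edge(s, e[1])
    g.remove_edge(*f)
    g.add_edge(f[0], t)
    g.add_edge(t, f[1])
    g.add_edge(s, t)
    report = validate_directed(out)
    if not report.ok:
        raise IllegalMove(f"edge addition produced invalid network: {report.violations}")
    return out


def enumerate_edge_additions(
    net: DirectedNetwork,
    labeling: Optional[TreeBasedLabeling] = None,
    gene_flow_only: bool = False,
) -> List[Tuple[Move, DirectedNetwork, Optional[TreeBasedLabeling]]]:
    """All legal edge additions, in lexicographic (e, f) order.

    With ``gene_flow_only`` both e and f must be base-tree (ψ=0) edges
    and the labeling is extended to the result: the subdivision halves
    inherit their parent edge's label and the linking arc is labeled 1.
    """
    if gene_flow_only and labeling is None:
        raise ValueError("gene_flow_only requires a labeling")
    index = build_reachability(net)
    psi = labeling.as_dict() if labeling is not None else None
    out = []
    for e in net.edges():
        for f in net.edges():
            if e == f:
                continue
            if gene_flow_only and (psi[e] != 0 or psi[f] != 0):
                continue
            if not edge_addition_is_legal(net, e, f, index):
                continue
            try:
                child = apply_edge_addition(net, e, f)
            except IllegalMove:
                continue
            new_lab: Optional[TreeBasedLabeling] = None
            if gene_flow_only:
                s = net.fresh_id()
                t = s + 1
                new_psi = dict(psi)
                del new_psi[e]
                del new_psi[f]
                new_psi[(e[0], s)] = psi[e]
                new_psi[(s, e[1])] = psi[e]
                new_psi[(f[0], t)] = psi[f]
                new_psi[(t, f[1])] = psi[f]
                new_psi[(s, t)] = 1
                new_lab = TreeBasedLabeling.from_dict(new_psi)
            out.append((Move("edge_addition", e, f), child, new_lab))
    return out


# -- tail and head moves -------------------------------------------------


def _detach_and_subdivide(
    net: DirectedNetwork,
    removed: Edge,
    target: Edge,
    reattach: str,
) -> DirectedNetwork:
    """Shared mechanics of tail and head moves.

    Removes ``removed`` = (u, v), suppresses whichever endpoint lost the
    edge, subdivides ``target`` with a fresh vertex w and reattaches the
    dangling endpoint: ``reattach='tail'`` adds w→v, ``reattach='head'``
    adds u→w.  ``target`` may be an edge that only exists after the
    suppression (the two edges merged at the suppressed vertex).
    """
    u, v = removed
    out = net.copy()
    g = out.graph
    if not g.has_edge(u, v):
        raise IllegalMove(f"edge {removed} not in network")
    if target == removed:
        raise IllegalMove("source and target edge coincide")
    g.remove_edge(u, v)
    moving = u if reattach == "tail" else v
    anchor = v if reattach == "tail" else u
    # suppress the vertex that lost an incident edge
    merged: Optional[Edge] = None
    if moving not in g.nodes:
        raise IllegalMove("degenerate move")
    ind, outd = g.in_degree(moving), g.out_degree(moving)
    if ind == 1 and outd == 1:
        (p,) = g.predecessors(moving)
        (c,) = g.successors(moving)
        if p == c or g.has_edge(p, c):
            raise IllegalMove("suppression would create a parallel arc")
        g.remove_node(moving)
        g.add_edge(p, c)
        merged = (p, c)
    elif ind == 0 and outd == 1:
        # old root left with a single child: delete it, child becomes root
        (c,) = g.successors(moving)
        g.remove_node(moving)
        merged = None
    else:
        raise IllegalMove(
            f"vertex {moving} (in {ind}, out {outd}) cannot be suppressed"
        )
    # resolve the target edge after suppression
    tgt = target
    if not g.has_edge(*tgt):
        if merged is not None and target in (
            (merged[0], moving),
            (moving, merged[1]),
        ):
            tgt = merged
        else:
            raise IllegalMove(f"target edge {target} no longer exists")
    w = out.fresh_id()
    g.remove_edge(*tgt)
    g.add_edge(tgt[0], w)
    g.add_edge(w, tgt[1])
    if reattach == "tail":
        if g.has_edge(w, anchor):
            raise IllegalMove("parallel arc")
        g.add_edge(w, anchor)
    else:
        if g.has_edge(anchor, w):
            raise IllegalMove("parallel arc")
        g.add_edge(anchor, w)
    report = validate_directed(out)
    if not report.ok:
        raise IllegalMove(f"move produced invalid network: {report.violations}")
    return out


def apply_tail_move(net: DirectedNetwork, e: Edge, f: Edge) -> DirectedNetwork:
    """Relocate the tail of e so that it subdivides f."""
    child = _detach_and_subdivide(net, e, f, "tail")
    if child.h != net.h:
        raise IllegalMove("tail move changed the number of admixture nodes")
    return child


def apply_head_move(net: DirectedNetwork, a: Edge, f: Edge) -> DirectedNetwork:
    """Relocate the head of admixture edge a so that it subdivides f."""
    if net.graph.in_degree(a[1]) != 2:
        raise IllegalMove(f"{a} is not an admixture edge")
    child = _detach_and_subdivide(net, a, f, "head")
    if child.h != net.h:
        raise IllegalMove("head move changed the number of admixture nodes")
    return child


def _enumerate(
    net: DirectedNetwork, kind: str
) -> List[Tuple[Move, DirectedNetwork]]:
    apply = apply_tail_move if kind == "tail" else apply_head_move
    out = []
    edges = net.edges()
    sources = edges if kind == "tail" else [
        e for e in edges if net.graph.in_degree(e[1]) == 2
    ]
    for e in sources:
        # targets include edges that appear only after suppressing e's
        # endpoint; enumerating current edges covers them because the
        # merged edge is addressed by either of its halves
        for f in edges:
            if f == e:
                continue
            try:
                child = apply(net, e, f)
            except IllegalMove:
                continue
            out.append((Move(kind, e, f), child))
    return out


def enumerate_tail_moves(net: DirectedNetwork) -> List[Tuple[Move, DirectedNetwork]]:
    """All legal tail moves, lexicographic in (e, f)."""
    return _enumerate(net, "tail")


def enumerate_head_moves(net: DirectedNetwork) -> List[Tuple[Move, DirectedNetwork]]:
    """All legal head moves of admixture edges, lexicographic in (a, f)."""
    return _enumerate(net, "head")


# -- BFS move distance ---------------------------------------------------


def _dedup_key(net: DirectedNetwork) -> str:
    return network_hash(net)


class _ClassStore:
    """Isomorphism classes (modulo root), bucketed by WL hash."""

    def __init__(self) -> None:
        self.buckets: Dict[str, List[DirectedNetwork]] = {}

    def add(self, net: DirectedNetwork) -> bool:
        """Insert; returns True if the class was new."""
        key = _dedup_key(net)
        bucket = self.buckets.setdefault(key, [])
        for other in bucket:
            if same_modulo_root(net, other):
                return False
        bucket.append(net)
        return True

    def __contains__(self, net: DirectedNetwork) -> bool:
        for other in self.buckets.get(_dedup_key(net), []):
            if same_modulo_root(net, other):
                return True
        return False


def three_move_paths(
    a: DirectedNetwork, b: DirectedNetwork, kind: str = "tail"
) -> List[Tuple[DirectedNetwork, DirectedNetwork]]:
    """Intermediate pairs (x, y) of every length-3 move path a → x → y → b.

    Networks are compared modulo the root position; tail-move adjacency
    is symmetric on equivalence classes, so y is adjacent to b iff y
    lies in b's neighborhood.  Returns one representative per distinct
    (class of x, class of y) pair.
    """
    enumerate_fn = enumerate_tail_moves if kind == "tail" else enumerate_head_moves
    b_nbrs = _ClassStore()
    for _, child in enumerate_fn(b):
        b_nbrs.add(child)
    layer1 = _ClassStore()
    xs: List[DirectedNetwork] = []
    for _, child in enumerate_fn(a):
        if layer1.add(child):
            xs.append(child)
    out: List[Tuple[DirectedNetwork, DirectedNetwork]] = []
    for x in xs:
        seen_y = _ClassStore()
        for _, y in enumerate_fn(x):
            if not seen_y.add(y):
                continue
            if y in b_nbrs:
                out.append((x, y))
    return out


def move_distance(
    a: DirectedNetwork,
    b: DirectedNetwork,
    kind: str = "tail",
    cap: int = 4,
) -> Union[int, str]:
    """Minimum number of moves transforming a into b, modulo the root.

    Breadth-first search with isomorphism deduplication; returns the
    sentinel string ``">=cap"`` (with the numeric cap) when b is not
    reached within ``cap`` moves.
    """
    if a.populations != b.populations or a.h != b.h:
        raise ValueError("networks must share populations and admixture count")
    if same_modulo_root(a, b):
        return 0
    seen = _ClassStore()
    seen.add(a)
    frontier = [a]
    enumerate_fn = enumerate_tail_moves if kind == "tail" else enumerate_head_moves
    for depth in range(1, cap + 1):
        nxt: List[DirectedNetwork] = []
        for net in frontier:
            for _, child in enumerate_fn(net):
                if not seen.add(child):
                    continue
                if same_modulo_root(child, b):
                    return depth
                nxt.append(child)
        frontier = nxt
        if not frontier:
            break
    return f">={cap}"
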