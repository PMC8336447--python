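"""Binary directed and undirected phylogenetic networks.

A directed phylogenetic network is a rooted, binary, leaf-labeled DAG in
which internal vertices of in-degree 2 ("admixture nodes") represent gene
flow between lineages.  The undirected version of a network is obtained by
dropping edge directions and suppressing the root; it is the domain of the
orientation search.

Vertices are opaque integer ids; only leaves carry population labels.
All enumeration orders are lexicographic in vertex ids so that every
downstream search is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

Edge = Tuple[int, int]


class DirectedNetwork:
    """Rooted binary leaf-labeled phylogenetic network.

    Parameters
    ----------
    graph:
        A :class:`networkx.DiGraph` whose nodes are integer ids.
    labels:
        Mapping from leaf vertex id to population name.  Must be a
        bijection onto the population set.
    """

    def __init__(self, graph: nx.DiGraph, labels: Dict[int, str]):
        self.graph = graph
        self.labels = dict(labels)

    # -- basic accessors -------------------------------------------------

    @property
    def root(self) -> int:
        roots = [v for v in self.graph.nodes if self.graph.in_degree(v) == 0]
        if len(roots) != 1:
            raise ValueError(f"network has {len(roots)} in-degree-0 vertices")
        return roots[0]

    @property
    def leaves(self) -> List[int]:
        return sorted(v for v in self.graph.nodes if self.graph.out_degree(v) == 0)

    @property
    def populations(self) -> List[str]:
        return sorted(self.labels.values())

    @property
    def admixture_nodes(self) -> List[int]:
        return sorted(v for v in self.graph.nodes if self.graph.in_degree(v) == 2)

    @property
    def h(self) -> int:
        return len(self.admixture_nodes)

    def edges(self) -> List[Edge]:
        return sorted(self.graph.edges())

    def leaf_of(self, population: str) -> int:
        for v, name in self.labels.items():
            if name == population:
                return v
        raise KeyError(population)

    def pendant_edge(self, population: str) -> Edge:
        leaf = self.leaf_of(population)
        preds = list(self.graph.predecessors(leaf))
        if len(preds) != 1:
            raise ValueError(f"leaf {population} has in-degree {len(preds)}")
        return (preds[0], leaf)

    def fresh_id(self) -> int:
        return max(self.graph.nodes, default=-1) + 1

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(self.graph.copy(), dict(self.labels))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"DirectedNetwork({len(self.graph)} vertices, "
            f"{self.graph.number_of_edges()} edges, h={self.h}, "
            f"S={self.populations})"
        )

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_edge_list(cls, edges: Iterable[Edge], labels: Dict[int, str]) -> "DirectedNetwork":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(g, labels)

    @classmethod
    def caterpillar(cls, populations: List[str]) -> "DirectedNetwork":
        """Caterpillar tree rooted at the last population.

        ``caterpillar(["A", "B", "C", "D", "E"])`` builds the rooted tree
        ``((((A,B),C),D),E)`` with E hanging off the root.
        """
        if len(populations) < 3:
            raise ValueError("need at least 3 populations")
        g = nx.DiGraph()
        labels: Dict[int, str] = {}
        leaf_ids = {p: i for i, p in enumerate(populations)}
        for p, i in leaf_ids.items():
            labels[i] = p
        nxt = len(populations)
        # cherry of first two populations
        g.add_edge(nxt, leaf_ids[populations[0]])
        g.add_edge(nxt, leaf_ids[populations[1]])
        prev = nxt
        nxt += 1
        for p in populations[2:]:
            g.add_edge(nxt, prev)
            g.add_edge(nxt, leaf_ids[p])
            prev = nxt
            nxt += 1
        return cls(g, labels)


class UndirectedNetwork:
    """Unrooted binary leaf-labeled network (leaves degree 1, internal degree 3)."""

    def __init__(self, graph: nx.Graph, labels: Dict[int, str]):
        self.graph = graph
        self.labels = dict(labels)

    @property
    def leaves(self) -> List[int]:
        return sorted(v for v in self.graph.nodes if self.graph.degree(v) == 1)

    @property
    def internal_vertices(self) -> List[int]:
        return sorted(v for v in self.graph.nodes if self.graph.degree(v) > 1)

    @property
    def populations(self) -> List[str]:
        return sorted(self.labels.values())

    def leaf_of(self, population: str) -> int:
        for v, name in self.labels.items():
            if name == population:
                return v
        raise KeyError(population)

    def pendant_edge(self, population: str) -> Edge:
        leaf = self.leaf_of(population)
        nbrs = list(self.graph.neighbors(leaf))
        if len(nbrs) != 1:
            raise ValueError(f"leaf {population} has degree {len(nbrs)}")
        return tuple(sorted((leaf, nbrs[0])))  # type: ignore[return-value]

    def copy(self) -> "UndirectedNetwork":
        return UndirectedNetwork(self.graph.copy(), dict(self.labels))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"UndirectedNetwork({len(self.graph)} vertices, "
            f"{self.graph.number_of_edges()} edges, S={self.populations})"
        )


@dataclass
class ValidityReport:
    ok: bool
    violations: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_directed(net: DirectedNetwork) -> ValidityReport:
    """Check the directed binary network invariants, reporting violations.

    Rules checked: single root of in-degree 0 / out-degree 2; leaves of
    in-degree 1 / out-degree 0 labeled bijectively; internal vertices with
    in-degree + out-degree = 3; acyclic; everything reachable from the
    root; no self-loops (parallel arcs cannot be represented in the
    underlying simple digraph).
    """
    g = net.graph
    violations: List[str] = []
    if len(g) == 0:
        return ValidityReport(False, ["empty graph"])
    for u, v in g.edges():
        if u == v:
            violations.append(f"self-loop at {u}")
    roots = [v for v in g.nodes if g.in_degree(v) == 0]
    if len(roots) != 1:
        violations.append(f"expected exactly one root, found {sorted(roots)}")
    else:
        root = roots[0]
        if g.out_degree(root) != 2:
            violations.append(f"root {root} has out-degree {g.out_degree(root)}")
    for v in g.nodes:
        ind, outd = g.in_degree(v), g.out_degree(v)
        if ind == 0:
            continue  # root handled above
        if outd == 0:
            if ind != 1:
                violations.append(f"leaf {v} has in-degree {ind}")
            if v not in net.labels:
                violations.append(f"leaf {v} is unlabeled")
        else:
            if ind + outd != 3:
                violations.append(f"non-binary vertex {v} (in {ind}, out {outd})")
    leaf_set = {v for v in g.nodes if g.out_degree(v) == 0}
    extra = set(net.labels) - leaf_set
    if extra:
        violations.append(f"labels on non-leaf vertices {sorted(extra)}")
    names = [net.labels[v] for v in sorted(set(net.labels) & leaf_set)]
    if len(names) != len(set(names)):
        violations.append("leaf labels are not distinct")
    if not nx.is_directed_acyclic_graph(g):
        violations.append("graph contains a directed cycle (parallel/cycle)")
    elif len(roots) == 1:
        reachable = nx.descendants(g, roots[0]) | {roots[0]}
        missing = set(g.nodes) - reachable
        if missing:
            violations.append(f"vertices unreachable from root: {sorted(missing)}")
    return ValidityReport(not violations, violations)


def to_undirected(net: DirectedNetwork) -> UndirectedNetwork:
    """Drop edge directions and suppress the root.

    The two root-incident edges are merged into a single edge, so the
    edge count decreases by exactly one.
    """
    report = validate_directed(net)
    if not report.ok:
        raise ValueError(f"invalid network: {report.violations}")
    root = net.root
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(net.graph.edges())
    a, b = sorted(net.graph.successors(root))
    g.remove_node(root)
    if g.has_edge(a, b):
        raise ValueError("root suppression would create a parallel edge")
    g.add_edge(a, b)
    return UndirectedNetwork(g, dict(net.labels))


def _undirected_node_match(labels_a: Dict[int, str], labels_b: Dict[int, str]):
    def match(attrs_a, attrs_b):
        return attrs_a.get("label") == attrs_b.get("label")

    return match


def _labeled_graph(u: UndirectedNetwork) -> nx.Graph:
    g = u.graph.copy()
    for v in g.nodes:
        g.nodes[v]["label"] = u.labels.get(v)
    return g


def is_isomorphic(a: UndirectedNetwork, b: UndirectedNetwork) -> bool:
    """Leaf-label-preserving isomorphism of undirected networks."""
    if a.populations != b.populations:
        return False
    ga, gb = _labeled_graph(a), _labeled_graph(b)
    return nx.is_isomorphic(
        ga, gb, node_match=lambda x, y: x.get("label") == y.get("label")
    )


def is_isomorphic_directed(a: DirectedNetwork, b: DirectedNetwork) -> bool:
    """Leaf-label-preserving isomorphism of directed networks (root included)."""
    if a.populations != b.populations:
        return False
    ga, gb = a.graph.copy(), b.graph.copy()
    for v in ga.nodes:
        ga.nodes[v]["label"] = a.labels.get(v)
    for v in gb.nodes:
        gb.nodes[v]["label"] = b.labels.get(v)
    return nx.is_isomorphic(
        ga, gb, node_match=lambda x, y: x.get("label") == y.get("label")
    )


def _derooted_marked_graph(net: DirectedNetwork) -> nx.MultiGraph:
    """Undirected root-suppressed version with admixture nodes marked.

    Because the admixture-node set together with a root edge determines
    the orientation uniquely, two networks are equal *modulo the root
    position* iff their marked derooted graphs are isomorphic.  A
    multigraph is used so that networks whose root children are
    adjacent (suppression creates a parallel edge) still compare.
    """
    admix = set(net.admixture_nodes)
    root = net.root
    g = nx.MultiGraph()
    g.add_nodes_from(v for v in net.graph.nodes if v != root)
    g.add_edges_from(
        (u, v) for u, v in net.graph.edges() if root not in (u, v)
    )
    a, b = sorted(net.graph.successors(root))
    g.add_edge(a, b)
    for v in g.nodes:
        if v in net.labels:
            g.nodes[v]["mark"] = ("leaf", net.labels[v])
        elif v in admix:
            g.nodes[v]["mark"] = ("admix",)
        else:
            g.nodes[v]["mark"] = ("tree",)
    return g


def same_modulo_root(a: DirectedNetwork, b: DirectedNetwork) -> bool:
    """Equality of directed networks ignoring where the root sits."""
    if a.populations != b.populations or a.h != b.h:
        return False
    ga, gb = _derooted_marked_graph(a), _derooted_marked_graph(b)
    return nx.is_isomorphic(
        ga, gb, node_match=lambda x, y: x["mark"] == y["mark"]
    )


def network_hash(net: DirectedNetwork) -> str:
    """Cheap invariant of the modulo-root equivalence class.

    Weisfeiler–Lehman hash of the marked derooted graph; equal networks
    hash equal, so it is safe for bucketing before exact isomorphism.
    """
    mg = _derooted_marked_graph(net)
    g = nx.Graph()
    g.add_nodes_from(mg.nodes)
    for u, v in mg.edges():
        if g.has_edge(u, v):
            g[u][v]["mult"] += 1
        else:
            g.add_edge(u, v, mult=1)
    for v in g.nodes:
        g.nodes[v]["wl"] = str(mg.nodes[v]["mark"])
    for u, v in g.edges():
        g[u][v]["mult"] = str(g[u][v]["mult"])
    return nx.weisfeiler_lehman_graph_hash(
        g, node_attr="wl", edge_attr="mult", iterations=4
    )


def suppress_degree_two(net: DirectedNetwork) -> DirectedNetwork:
    """Suppress in-1/out-1 vertices and prune out-degree-1 roots, in place.

    Returns ``net`` for chaining.  Raises if a merge would create a
    parallel arc.
    """
    g = net.graph
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            ind, outd = g.in_degree(v), g.out_degree(v)
            if ind == 1 and outd == 1:
                (p,) = g.predecessors(v)
                (c,) = g.successors(v)
                if p == c or g.has_edge(p, c):
                    raise ValueError("suppression would create a parallel arc or loop")
                g.remove_node(v)
                g.add_edge(p, c)
                changed = True
            elif ind == 0 and outd == 1:
                # dangling root: its single child becomes the new root
                g.remove_node(v)
                changed = True
            elif ind == 0 and outd == 0 and len(g) > 1:
                g.remove_node(v)
                changed = True
    return net


# -- tree-based labelings -----------------------------------------------


@dataclass(frozen=True)
class TreeBasedLabeling:
    """0/1 edge labeling separating base-tree edges (0) from gene flow (1).

    Valid labelings satisfy: every non-root vertex has exactly one
    incoming edge labeled 0; every internal vertex has at least one
    outgoing edge labeled 0; both root-outgoing edges are labeled 0.
    """

    psi: Tuple[Tuple[Edge, int], ...]

    @classmethod
    def from_dict(cls, psi: Dict[Edge, int]) -> "TreeBasedLabeling":
        return cls(tuple(sorted(psi.items())))

    def as_dict(self) -> Dict[Edge, int]:
        return dict(self.psi)

    def label(self, edge: Edge) -> int:
        return self.as_dict()[edge]

    def base_tree_edges(self) -> List[Edge]:
        return [e for e, lab in self.psi if lab == 0]

    def gene_flow_edges(self) -> List[Edge]:
        return [e for e, lab in self.psi if lab == 1]


def all_zero_labeling(net: DirectedNetwork) -> TreeBasedLabeling:
    return TreeBasedLabeling.from_dict({e: 0 for e in net.edges()})


def is_tree_based_labeling(net: DirectedNetwork, labeling: TreeBasedLabeling) -> bool:
    psi = labeling.as_dict()
    g = net.graph
    if set(psi) != set(g.edges()):
        return False
    root = net.root
    for v in g.nodes:
        in_zero = sum(1 for e in g.in_edges(v) if psi[e] == 0)
        if v != root and in_zero != 1:
            return False
        if g.out_degree(v) > 0:
            out_zero = sum(1 for e in g.out_edges(v) if psi[e] == 0)
            if out_zero < 1:
                return False
    for e in g.out_edges(root):
        if psi[e] != 0:
            return False
    return True


def _labeling_from_choices(
    net: DirectedNetwork, choice: Dict[int, Edge]
) -> TreeBasedLabeling:
    """Build ψ from a per-admixture-node choice of the gene-flow in-edge."""
    psi = {e: 0 for e in net.graph.edges()}
    for e in choice.values():
        psi[e] = 1
    return TreeBasedLabeling.from_dict(psi)


def enumerate_labelings(net: DirectedNetwork, max_h: int = 12) -> List[TreeBasedLabeling]:
    """All tree-based labelings, by brute force over the 2^h in-edge choices.

    Order is deterministic: admixture nodes sorted by id, and for each
    node the candidate gene-flow in-edge sorted by (tail, head).
    """
    report = validate_directed(net)
    if not report.ok:
        raise ValueError(f"invalid network: {report.violations}")
    admix = net.admixture_nodes
    if len(admix) > max_h:
        raise ValueError(f"h={len(admix)} exceeds enumeration guard {max_h}")
    in_edges = {m: sorted(net.graph.in_edges(m)) for m in admix}
    out: List[TreeBasedLabeling] = []
    for bits in itertools.product(range(2), repeat=len(admix)):
        choice = {m: in_edges[m][b] for m, b in zip(admix, bits)}
        lab = _labeling_from_choices(net, choice)
        if is_tree_based_labeling(net, lab):
            out.append(lab)
    return out


def find_tree_based_labeling(net: DirectedNetwork) -> Optional[TreeBasedLabeling]:
    """Find one tree-based labeling, or ``None`` if none exists.

    The choice of gene-flow in-edge per admixture node is a 2-SAT
    instance: each constraint ("at least one out-edge of v labeled 0",
    "root out-edges labeled 0") forbids at most two simultaneous
    gene-flow choices, because out-degrees are at most 2.  Solved via
    the implication graph / strongly-connected-components algorithm,
    which is linear in the network size.
    """
    report = validate_directed(net)
    if not report.ok:
        raise ValueError(f"invalid network: {report.violations}")
    g = net.graph
    admix = net.admixture_nodes
    if not admix:
        return all_zero_labeling(net)
    in_edges = {m: sorted(g.in_edges(m)) for m in admix}
    # variable x_m: True  -> in_edges[m][1] is the gene-flow edge
    #              False -> in_edges[m][0] is the gene-flow edge
    index = {m: i for i, m in enumerate(admix)}

    def lit_edge_is_gene_flow(e: Edge):
        """Literal asserting edge e is labeled 1, or None if e cannot be."""
        m = e[1]
        if m not in index:
            return None
        e0, e1 = in_edges[m]
        if e == e1:
            return (index[m], True)
        return (index[m], False)

    clauses: List[List[Tuple[int, bool]]] = []
    root = net.root
    for e in g.out_edges(root):
        lit = lit_edge_is_gene_flow(e)
        if lit is not None:
            clauses.append([(lit[0], not lit[1])])  # e must be 0
    for v in g.nodes:
        if g.out_degree(v) == 0 or v == root:
            continue
        lits = [lit_edge_is_gene_flow(e) for e in sorted(g.out_edges(v))]
        maybe_one = [l for l in lits if l is not None]
        if len(maybe_one) < g.out_degree(v):
            continue  # some out-edge is always labeled 0
        # forbid all out-edges simultaneously gene flow
        clauses.append([(var, not val) for var, val in maybe_one])

    assignment = _solve_2sat(len(admix), clauses)
    if assignment is None:
        return None
    choice = {m: in_edges[m][1 if assignment[index[m]] else 0] for m in admix}
    lab = _labeling_from_choices(net, choice)
    assert is_tree_based_labeling(net, lab)
    return lab


def _solve_2sat(
    n_vars: int, clauses: List[List[Tuple[int, bool]]]
) -> Optional[List[bool]]:
    """Standard implication-graph 2-SAT; clauses of size 1 or 2."""

    def node(var: int, val: bool) -> int:
        return 2 * var + (1 if val else 0)

    impl = nx.DiGraph()
    impl.add_nodes_from(range(2 * n_vars))
    for clause in clauses:
        if len(clause) == 1:
            (v, val) = clause[0]
            impl.add_edge(node(v, not val), node(v, val))
        else:
            (v1, a), (v2, b) = clause
            impl.add_edge(node(v1, not a), node(v2, b))
            impl.add_edge(node(v2, not b), node(v1, a))
    comp_of: Dict[int, int] = {}
    for i, comp in enumerate(nx.strongly_connected_components(impl)):
        for nd in comp:
            comp_of[nd] = i
    order = {}
    cond = nx.condensation(impl)
    for pos, c in enumerate(nx.topological_sort(cond)):
        order[c] = pos
    out: List[bool] = []
    for v in range(n_vars):
        ct, cf = comp_of[node(v, True)], comp_of[node(v, False)]
        if ct == cf:
            return None
        # later in topological order == chosen value
        out.append(order[cond.graph["mapping"][node(v, True)]] >
                   order[cond.graph["mapping"][node(v, False)]])
    return out


def displayed_trees(net: DirectedNetwork) -> List[DirectedNetwork]:
    """Rooted trees displayed by the network.

    One candidate per combination of keeping exactly one incoming edge
    at each admixture node; unreachable vertices are removed and
    degree-2 vertices suppressed.  Deduplicated by isomorphism.
    """
    admix = net.admixture_nodes
    in_edges = {m: sorted(net.graph.in_edges(m)) for m in admix}
    trees: List[DirectedNetwork] = []
    for bits in itertools.product(range(2), repeat=len(admix)):
        t = net.copy()
        for m, b in zip(admix, bits):
            t.graph.remove_edge(*in_edges[m][1 - b])
        root = net.root
        keep = nx.descendants(t.graph, root) | {root}
        for v in set(t.graph.nodes) - keep:
            t.graph.remove_node(v)
        # prune internal vertices left childless by edge removal, then
        # suppress the resulting degree-2 chain
        changed = True
        while changed:
            changed = False
            for v in list(t.graph.nodes):
                if t.graph.out_degree(v) == 0 and v not in net.labels:
                    t.graph.remove_node(v)
                    changed = True
        suppress_degree_two(t)
        t.labels = {v: net.labels[v] for v in t.graph.nodes if v in net.labels}
        if not any(is_isomorphic_directed(t, s) for s in trees):
            trees.append(t)
    return trees
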