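"""Starting-tree-based maximum-likelihood search with optional MLNO step.

The driver mirrors the classic f2-based pipeline: build a starting tree
rooted at the outgroup, then for each requested admixture event (i) add
the best legal gene-flow edge, (ii) hill-climb with tail moves, and
(iii) optionally replace the network by its maximum-likelihood
orientation.  With the orientation step disabled this is the plain
starting-tree-based baseline, which the case-study fixture demonstrates
can be trapped in a local optimum.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .drift import F2Dataset, leaf_pairs
from .fitting import FitResult, fit_params, score_graph
from .moves import enumerate_edge_additions, enumerate_tail_moves
from .network import (
    DirectedNetwork,
    TreeBasedLabeling,
    UndirectedNetwork,
    all_zero_labeling,
    find_tree_based_labeling,
)
from .orientation import OrientationSpec, mlno, orient


@dataclass
class SearchConfig:
    num_admixture: int = 0
    outgroup: Optional[str] = None
    start_mode: str = "nj"  # "nj" | "exact_ml" | "random_addition"
    exhaustive_edge_addition: bool = True
    candidate_pairs: int = 5  # heuristic mode: top-k scaled-residual pairs
    mlno: bool = False
    mlno_all_roots: bool = False
    mlno_max_h: int = 6
    convention: str = "treemix"
    seed: int = 0
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.num_admixture < 0:
            raise ValueError("num_admixture must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(eq=False)
class TraceEntry:
    step: str
    network: DirectedNetwork
    loglik: float


@dataclass(eq=False)
class SearchTrace:
    entries: List[TraceEntry] = field(default_factory=list)

    def record(self, step: str, network: DirectedNetwork, loglik: float) -> None:
        self.entries.append(TraceEntry(step, network, loglik))


# -- starting trees ------------------------------------------------------


def nj_tree(data: F2Dataset) -> UndirectedNetwork:
    """Neighbor-joining tree on the f2 matrix (f2 is additive on trees)."""
    import networkx as nx
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    pops = data.populations
    if len(pops) < 3:
        raise ValueError("neighbor joining needs at least 3 populations")
    n = len(pops)
    mat = np.zeros((n, n))
    data = data.reordered()
    for k, (a, b) in enumerate(data.pairs):
        i, j = pops.index(a), pops.index(b)
        mat[i, j] = mat[j, i] = data.x[k]
    tree = skbio_nj(DistanceMatrix(mat, ids=pops))

    g = nx.Graph()
    labels = {}
    counter = itertools.count()
    ids = {}

    def walk(node) -> int:
        vid = next(counter)
        ids[id(node)] = vid
        if node.is_tip():
            labels[vid] = node.name
        for child in node.children:
            cid = walk(child)
            g.add_edge(vid, cid)
        return vid

    root_id = walk(tree)
    # skbio trees carry a degree-2 or degree-3 top node; suppress degree-2
    while g.degree(root_id) == 2:
        a, b = list(g.neighbors(root_id))
        g.remove_node(root_id)
        g.add_edge(a, b)
        break
    return UndirectedNetwork(g, labels)


def _root_unrooted_tree(u: UndirectedNetwork, outgroup: str) -> DirectedNetwork:
    net = orient(u, OrientationSpec(u.pendant_edge(outgroup), frozenset()))
    if net is None:
        raise ValueError("failed to root the tree at the outgroup")
    return net


def _all_unrooted_topologies(pops: List[str]):
    """Yield every unrooted binary leaf-labeled topology by leaf insertion."""
    import networkx as nx

    pops = sorted(pops)
    if len(pops) < 3:
        raise ValueError("need at least 3 populations")
    base = nx.Graph()
    center = -1
    for i in range(3):
        base.add_edge(center, i)
    labels = {i: pops[i] for i in range(3)}

    def grow(g: "nx.Graph", next_leaf: int):
        if next_leaf == len(pops):
            yield UndirectedNetwork(g.copy(), {**labels, **{
                i: pops[i] for i in range(3, len(pops))
            }})
            return
        fresh = -(next_leaf + 10)
        for e in sorted(tuple(sorted(ed)) for ed in g.edges()):
            g2 = g.copy()
            g2.remove_edge(*e)
            g2.add_edge(e[0], fresh)
            g2.add_edge(fresh, e[1])
            g2.add_edge(fresh, next_leaf)
            yield from grow(g2, next_leaf + 1)

    yield from grow(base, 3)


def starting_tree(data: F2Dataset, config: SearchConfig) -> DirectedNetwork:
    """Rooted starting tree per the configured mode."""
    if config.outgroup is None or config.outgroup not in data.populations:
        raise ValueError("config.outgroup must name a population in the data")
    if config.start_mode == "nj":
        return _root_unrooted_tree(nj_tree(data), config.outgroup)
    if config.start_mode == "exact_ml":
        pops = data.populations
        if len(pops) > 8:
            raise ValueError("exact_ml starting tree is guarded to <= 8 populations")
        best: Optional[Tuple[float, DirectedNetwork]] = None
        for u in _all_unrooted_topologies(pops):
            net = _root_unrooted_tree(u, config.outgroup)
            fit = fit_params(net, all_zero_labeling(net), config.convention, data)
            if best is None or fit.loglik > best[0] + 1e-12:
                best = (fit.loglik, net)
        assert best is not None
        return best[1]
    if config.start_mode == "random_addition":
        return _random_addition_tree(data, config)
    raise ValueError(f"unknown start mode {config.start_mode!r}")


def _random_addition_tree(data: F2Dataset, config: SearchConfig) -> DirectedNetwork:
    """Stepwise ML leaf insertion in a seeded random order, then tail climbing."""
    rng = random.Random(config.seed)
    pops = [p for p in data.populations if p != config.outgroup]
    rng.shuffle(pops)
    first = sorted([config.outgroup, pops[0], pops[1]])
    sub = _subset_data(data, first)
    net = _root_unrooted_tree(nj_tree(sub), config.outgroup)
    for pop in pops[2:]:
        present = sorted(net.populations + [pop])
        sub = _subset_data(data, present)
        best: Optional[Tuple[float, DirectedNetwork]] = None
        for e in net.edges():
            trial = net.copy()
            w = trial.fresh_id()
            leaf = w + 1
            trial.graph.remove_edge(*e)
            trial.graph.add_edge(e[0], w)
            trial.graph.add_edge(w, e[1])
            trial.graph.add_edge(w, leaf)
            trial.labels[leaf] = pop
            fit = fit_params(trial, all_zero_labeling(trial), config.convention, sub)
            if best is None or fit.loglik > best[0] + 1e-12:
                best = (fit.loglik, trial)
        assert best is not None
        net = best[1]
    net, _, _ = hill_climb(net, all_zero_labeling(net), data, config)
    return net


def _subset_data(data: F2Dataset, pops: List[str]) -> F2Dataset:
    keep = [k for k, (a, b) in enumerate(data.pairs) if a in pops and b in pops]
    return F2Dataset(
        [data.pairs[k] for k in keep], data.x[keep], data.se[keep]
    )


# -- network-scoring helpers --------------------------------------------


def _score(
    net: DirectedNetwork,
    labeling: Optional[TreeBasedLabeling],
    data: F2Dataset,
    config: SearchConfig,
) -> FitResult:
    if config.convention == "admixturegraph":
        return fit_params(net, None, "admixturegraph", data)
    if labeling is None:
        labeling = find_tree_based_labeling(net)
        if labeling is None:
            raise ValueError("network admits no tree-based labeling")
    return fit_params(net, labeling, "treemix", data)


def add_admixture_step(
    net: DirectedNetwork,
    labeling: TreeBasedLabeling,
    data: F2Dataset,
    config: SearchConfig,
) -> Tuple[DirectedNetwork, TreeBasedLabeling, FitResult]:
    """Best network in the gene-flow edge addition neighborhood.

    Exhaustive mode scores every legal addition between base-tree edges.
    Heuristic mode restricts candidates to edges on the root paths of
    the populations in the top-k absolute scaled-residual pairs.
    """
    candidates = enumerate_edge_additions(net, labeling, gene_flow_only=True)
    if not candidates:
        raise ValueError("empty legal gene-flow edge addition neighborhood")
    if not config.exhaustive_edge_addition:
        base_fit = _score(net, labeling, data, config)
        order = np.argsort(-np.abs(base_fit.scaled_residuals))
        data_sorted = data.reordered()
        hot: set = set()
        for k in order[: config.candidate_pairs]:
            hot.update(data_sorted.pairs[k])
        allowed = _root_path_edges(net, hot)
        candidates = [
            (mv, child, lab)
            for mv, child, lab in candidates
            if mv.source in allowed and mv.target in allowed
        ] or candidates
    best = None
    for mv, child, lab in candidates:
        fit = _score(child, lab, data, config)
        if best is None or fit.loglik > best[2].loglik + 1e-12:
            best = (child, lab, fit)
    assert best is not None
    return best


def _root_path_edges(net: DirectedNetwork, pops: set) -> set:
    import networkx as nx

    root = net.root
    out = set()
    for pop in pops:
        leaf = net.leaf_of(pop)
        for path in nx.all_simple_paths(net.graph, root, leaf):
            out.update(zip(path[:-1], path[1:]))
    return out


def hill_climb(
    net: DirectedNetwork,
    labeling: Optional[TreeBasedLabeling],
    data: F2Dataset,
    config: SearchConfig,
) -> Tuple[DirectedNetwork, Optional[TreeBasedLabeling], FitResult]:
    """Steepest-ascent tail-move climbing from the given network."""
    current_fit = _score(net, labeling, data, config)
    while True:
        best = None
        for _, child in enumerate_tail_moves(net):
            child_lab = (
                find_tree_based_labeling(child)
                if config.convention == "treemix"
                else None
            )
            if config.convention == "treemix" and child_lab is None:
                continue
            fit = _score(child, child_lab, data, config)
            if best is None or fit.loglik > best[2].loglik + 1e-12:
                best = (child, child_lab, fit)
        if best is None or best[2].loglik <= current_fit.loglik + config.tolerance:
            return net, labeling, current_fit
        net, labeling, current_fit = best


def run_search(
    data: F2Dataset, config: SearchConfig
) -> Tuple[SearchTrace, DirectedNetwork, FitResult]:
    """Full pipeline: starting tree, then per-event addition/climb/orient."""
    trace = SearchTrace()
    net = starting_tree(data, config)
    labeling: Optional[TreeBasedLabeling] = all_zero_labeling(net)
    fit = _score(net, labeling, data, config)
    trace.record("starting_tree", net, fit.loglik)
    for i in range(config.num_admixture):
        net, labeling, fit = add_admixture_step(net, labeling, data, config)
        trace.record(f"edge_addition_{i + 1}", net, fit.loglik)
        net, labeling, fit = hill_climb(net, labeling, data, config)
        trace.record(f"tail_climb_{i + 1}", net, fit.loglik)
        if config.mlno:
            net, fit = mlno(
                net,
                data,
                convention=config.convention,
                outgroup=config.outgroup,
                all_roots=config.mlno_all_roots,
                max_h=config.mlno_max_h,
            )
            labeling = find_tree_based_labeling(net)
            trace.record(f"mlno_{i + 1}", net, fit.loglik)
    return trace, net, fit
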