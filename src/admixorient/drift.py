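"""Expected f2-statistics under an admixture graph and their likelihood.

Under the Gaussian drift approximation, allele frequencies evolve by
zero-mean increments with variance equal to the branch length (in drift
units), and an admixed lineage inherits from one parent with probability
γ and from the other with probability 1−γ.  For populations i, j the
expected f2-statistic is

    Y(i, j) = Σ_e (p_i(e) − p_j(e))² · c_e

where p_i(e) is the admixture-weighted probability that the lineage of
leaf i traverses edge e on its way to the root, and c_e is the drift
length of e.  On a tree this reduces to the path-length distance between
the two leaves.

The observed f2 vector X with per-entry scale Z is modeled as
independent Gaussians centered on Y, giving the composite log-likelihood

    log ℓ = −(1/2) Σ_i [ (X_i − Y_i)²/Z_i² + 2 log Z_i + log 2π ].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import DirectedNetwork, Edge, validate_directed

Pair = Tuple[str, str]


@dataclass
class DriftParams:
    """Numeric parameters of an admixture graph.

    ``lengths`` maps every edge to a nonnegative drift length.  For each
    admixture node, ``gamma_edges`` designates one of its two incoming
    edges; ``gammas`` gives the inheritance probability γ ∈ [0, 1]
    carried by that edge (the other incoming edge carries 1−γ).
    """

    lengths: Dict[Edge, float]
    gammas: Dict[int, float] = field(default_factory=dict)
    gamma_edges: Dict[int, Edge] = field(default_factory=dict)

    def validate(self, net: DirectedNetwork) -> None:
        edges = set(net.graph.edges())
        missing = edges - set(self.lengths)
        if missing:
            raise ValueError(f"missing lengths for edges {sorted(missing)}")
        for e, c in self.lengths.items():
            if c < 0:
                raise ValueError(f"negative length on {e}")
        for m in net.admixture_nodes:
            if m not in self.gammas:
                raise ValueError(f"missing admixture proportion for node {m}")
            if not 0.0 <= self.gammas[m] <= 1.0:
                raise ValueError(f"γ out of [0,1] for node {m}")
            e = self.gamma_edges.get(m)
            if e is None or e not in net.graph.in_edges(m):
                raise ValueError(f"γ for node {m} not attached to an incoming edge")

    def inflow_share(self, net: DirectedNetwork, edge: Edge) -> float:
        """Probability that a lineage at head(edge) came through ``edge``."""
        v = edge[1]
        if net.graph.in_degree(v) != 2:
            return 1.0
        g = self.gammas[v]
        return g if self.gamma_edges[v] == edge else 1.0 - g


def default_gamma_edges(net: DirectedNetwork) -> Dict[int, Edge]:
    """Designate the lexicographically smaller in-edge of each admixture node."""
    return {m: sorted(net.graph.in_edges(m))[0] for m in net.admixture_nodes}


@dataclass
class F2Dataset:
    """Observed f2-statistics over all unordered population pairs.

    ``pairs`` lists each pair once, sorted within the pair and across
    the list; ``x`` is the observed f2 and ``se`` the per-entry standard
    error used as the scale in the likelihood.
    """

    pairs: List[Pair]
    x: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        pops = sorted({p for pair in self.pairs for p in pair})
        expected = leaf_pairs(pops)
        if sorted(self.pairs) != expected:
            raise ValueError("pairs must cover every unordered population pair once")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if len(self.pairs) != len(self.x) or len(self.pairs) != len(self.se):
            raise ValueError("pairs, x and se must have matching lengths")

    @property
    def populations(self) -> List[str]:
        return sorted({p for pair in self.pairs for p in pair})

    def reordered(self) -> "F2Dataset":
        """Copy with pairs in canonical sorted order."""
        idx = sorted(range(len(self.pairs)), key=lambda i: self.pairs[i])
        return F2Dataset(
            [self.pairs[i] for i in idx], self.x[idx], self.se[idx]
        )

    def index_of(self, a: str, b: str) -> int:
        key = (min(a, b), max(a, b))
        return self.pairs.index(key)


def leaf_pairs(populations: Sequence[str]) -> List[Pair]:
    pops = sorted(populations)
    return [(a, b) for a, b in itertools.combinations(pops, 2)]


# -- path weights and expected f2 ---------------------------------------


class F2Model:
    """Precomputed traversal structure for fast repeated f2 evaluation.

    Fitting evaluates the design matrix for thousands of candidate
    admixture proportions; this caches the topological order and
    in-edge lists once so each evaluation is a plain dictionary sweep.
    """

    def __init__(self, net: DirectedNetwork, columns: Optional[List[Edge]] = None):
        report = validate_directed(net)
        if not report.ok:
            raise ValueError(f"invalid network: {report.violations}")
        import networkx as nx

        g = net.graph
        self.columns: List[Edge] = (
            list(columns) if columns is not None else sorted(g.edges())
        )
        self.col_index = {e: k for k, e in enumerate(self.columns)}
        self.rev_topo = list(nx.topological_sort(g))[::-1]
        self.in_edges = {v: sorted(g.in_edges(v)) for v in g.nodes}
        self.admix = sorted(net.admixture_nodes)
        self.leaf_names = sorted((name, v) for v, name in net.labels.items())
        self.pairs = leaf_pairs(net.populations)

    def _shares(
        self, gammas: Dict[int, float], gamma_edges: Dict[int, Edge]
    ) -> Dict[Edge, float]:
        share: Dict[Edge, float] = {}
        for m in self.admix:
            e0, e1 = self.in_edges[m]
            gm = gammas[m]
            if gamma_edges[m] == e0:
                share[e0], share[e1] = gm, 1.0 - gm
            else:
                share[e0], share[e1] = 1.0 - gm, gm
        return share

    def leaf_edge_weights(
        self, gammas: Dict[int, float], gamma_edges: Dict[int, Edge]
    ) -> Dict[str, Dict[Edge, float]]:
        share = self._shares(gammas, gamma_edges)
        out: Dict[str, Dict[Edge, float]] = {}
        for name, leaf in self.leaf_names:
            w: Dict[int, float] = {leaf: 1.0}
            p: Dict[Edge, float] = {}
            for v in self.rev_topo:
                wv = w.get(v, 0.0)
                if wv == 0.0:
                    continue
                for e in self.in_edges[v]:
                    contrib = wv * share.get(e, 1.0)
                    p[e] = contrib
                    w[e[0]] = w.get(e[0], 0.0) + contrib
            out[name] = p
        return out

    def design(
        self, gammas: Dict[int, float], gamma_edges: Dict[int, Edge]
    ) -> np.ndarray:
        pw = self.leaf_edge_weights(gammas, gamma_edges)
        a = np.zeros((len(self.pairs), len(self.columns)))
        for k, (i, j) in enumerate(self.pairs):
            pi, pj = pw[i], pw[j]
            for e in pi.keys() | pj.keys():
                col = self.col_index.get(e)
                if col is not None:
                    a[k, col] = (pi.get(e, 0.0) - pj.get(e, 0.0)) ** 2
        return a


def path_weights(
    net: DirectedNetwork, params: DriftParams
) -> Dict[str, Dict[Edge, float]]:
    """Admixture-weighted edge-usage probabilities per leaf.

    For each population i, ``p[i][e]`` is the total probability that the
    root-to-leaf inheritance path of i traverses edge e.  Computed in a
    single reverse-topological pass: a leaf's own weight is 1 and the
    weight entering a vertex is split across its incoming edges by the
    admixture proportions (trivially for tree vertices).
    """
    report = validate_directed(net)
    if not report.ok:
        raise ValueError(f"invalid network: {report.violations}")
    params.validate(net)
    import networkx as nx

    topo = list(nx.topological_sort(net.graph))
    out: Dict[str, Dict[Edge, float]] = {}
    for leaf, name in sorted(net.labels.items(), key=lambda kv: kv[1]):
        w = {v: 0.0 for v in net.graph.nodes}
        w[leaf] = 1.0
        p: Dict[Edge, float] = {}
        for v in reversed(topo):
            if v == leaf:
                pass
            elif net.graph.out_degree(v) == 0:
                continue
            for e in net.graph.in_edges(v):
                share = params.inflow_share(net, e)
                contrib = w[v] * share
                p[e] = contrib
                w[e[0]] = w.get(e[0], 0.0) + contrib
        # fill untouched edges with zero
        for e in net.graph.edges():
            p.setdefault(e, 0.0)
        out[name] = p
    return out


def f2_design_matrix(
    net: DirectedNetwork,
    params: DriftParams,
    edges: Optional[List[Edge]] = None,
) -> Tuple[List[Pair], List[Edge], np.ndarray]:
    """Coefficient matrix A with A[k, e] = (p_i(e) − p_j(e))² for pair k.

    The expected f2 vector is ``A @ c`` for the edge-length vector c, so
    for fixed admixture proportions the fit is a linear least-squares
    problem in the lengths.
    """
    if edges is None:
        edges = net.edges()
    weights = path_weights(net, params)
    pairs = leaf_pairs(net.populations)
    a = np.zeros((len(pairs), len(edges)))
    for k, (i, j) in enumerate(pairs):
        pi, pj = weights[i], weights[j]
        for c, e in enumerate(edges):
            a[k, c] = (pi[e] - pj[e]) ** 2
    return pairs, edges, a


def expected_f2(net: DirectedNetwork, params: DriftParams) -> np.ndarray:
    """Expected f2 vector over all pairs, in canonical pair order."""
    pairs, edges, a = f2_design_matrix(net, params)
    c = np.array([params.lengths[e] for e in edges])
    return a @ c


def log_likelihood(data: F2Dataset, y: np.ndarray) -> float:
    """Composite Gaussian log-likelihood of the expected vector y."""
    y = np.asarray(y, dtype=float)
    if y.shape != data.x.shape:
        raise ValueError("expected vector does not match dataset")
    z = data.se
    return float(
        -0.5 * np.sum(((data.x - y) / z) ** 2 + 2.0 * np.log(z) + np.log(2.0 * np.pi))
    )


def perfect_fit_loglik(n_pairs: int, se: float) -> float:
    """Likelihood upper bound attained at Y = X with constant scale."""
    return -0.5 * n_pairs * (2.0 * np.log(se) + np.log(2.0 * np.pi))


def residuals(data: F2Dataset, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Raw residuals X − Y and scaled residuals (X − Y)/Z, in data order."""
    y = np.asarray(y, dtype=float)
    raw = data.x - y
    return raw, raw / data.se
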