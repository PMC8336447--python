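"""Fitting drift parameters to observed f2-statistics for a fixed topology.

The three branch lengths incident to an admixture node are not jointly
identifiable, so fitting conventions pin some of them to zero:

* ``admixturegraph`` — both incoming edges of every admixture node are
  fixed to 0 and the outgoing edge is estimated.
* ``treemix`` — requires a tree-based labeling ψ; the free edges are
  exactly the ψ=0 edges whose tail is not an admixture node (so the
  outgoing edge and the ψ=1 incoming edge are fixed to 0).

For fixed admixture proportions the expected f2 vector is linear in the
edge lengths, so the profile problem is a nonnegative least-squares fit
solved exactly; the proportions are then optimized by multi-start
coordinate descent with bounded one-dimensional refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .drift import (
    DriftParams,
    F2Dataset,
    F2Model,
    default_gamma_edges,
    log_likelihood,
    residuals,
)
from .network import (
    DirectedNetwork,
    Edge,
    TreeBasedLabeling,
    enumerate_labelings,
    is_tree_based_labeling,
)

CONVENTIONS = ("admixturegraph", "treemix")

_GAMMA_GRID = tuple(0.05 + 0.1 * k for k in range(10))


@dataclass(eq=False)
class FitResult:
    params: DriftParams
    loglik: float
    converged: bool
    residuals: np.ndarray
    scaled_residuals: np.ndarray
    labeling: Optional[TreeBasedLabeling] = None


def free_edges(
    net: DirectedNetwork,
    convention: str,
    labeling: Optional[TreeBasedLabeling],
) -> List[Edge]:
    """Edges whose lengths are estimated (the rest are fixed to 0)."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    admix = set(net.admixture_nodes)
    if convention == "admixturegraph":
        return [e for e in net.edges() if e[1] not in admix]
    if labeling is None:
        raise ValueError("treemix convention requires a tree-based labeling")
    if not is_tree_based_labeling(net, labeling):
        raise ValueError("labeling is not tree-based for this network")
    psi = labeling.as_dict()
    return [e for e in net.edges() if psi[e] == 0 and e[0] not in admix]


def _nnls_profile(
    model: "F2Model",
    data: F2Dataset,
    gammas: Dict[int, float],
    gamma_edges: Dict[int, Edge],
) -> Tuple[float, np.ndarray]:
    """Exact NNLS solution of the length profile; returns (sse, lengths)."""
    a = model.design(gammas, gamma_edges)
    aw = a / data.se[:, None]
    xw = data.x / data.se
    if a.shape[1] == 0:
        return float(np.sum(xw**2)), np.zeros(0)
    c, rnorm = nnls(aw, xw)
    return float(rnorm**2), c


def fit_params(
    net: DirectedNetwork,
    labeling: Optional[TreeBasedLabeling],
    convention: str,
    data: F2Dataset,
    tol: float = 1e-10,
    max_rounds: int = 200,
) -> FitResult:
    """Maximize the composite likelihood over free lengths and proportions.

    Proportions start from a coarse grid (all combinations for h ≤ 2,
    axis-wise scans plus the centered vector otherwise); the best starts
    are refined by coordinate descent, alternating bounded scalar
    optimization of each γ with the exact NNLS length profile.
    """
    if data.populations != net.populations:
        raise ValueError("dataset populations do not match the network")
    data = data.reordered()
    free = free_edges(net, convention, labeling)
    admix = net.admixture_nodes
    gamma_edges = default_gamma_edges(net)
    model = F2Model(net, columns=free)

    def objective(gamma_vec: np.ndarray) -> Tuple[float, np.ndarray]:
        gammas = {m: float(g) for m, g in zip(admix, gamma_vec)}
        return _nnls_profile(model, data, gammas, gamma_edges)

    h = len(admix)
    if h == 0:
        best_g = np.zeros(0)
        best_sse, best_c = objective(best_g)
        converged = True
    else:
        starts: List[Tuple[float, ...]]
        if h <= 2:
            import itertools

            starts = list(itertools.product(_GAMMA_GRID, repeat=h))
        else:
            starts = [tuple([0.5] * h)]
            for axis in range(h):
                for g in _GAMMA_GRID:
                    vec = [0.5] * h
                    vec[axis] = g
                    starts.append(tuple(vec))
        scored = sorted(
            ((objective(np.array(s))[0], s) for s in starts),
            key=lambda t: (t[0], t[1]),
        )
        best_sse, best_g, best_c, converged = np.inf, None, None, False
        for _, start in scored[:3]:
            g_vec = np.array(start)
            sse, c = objective(g_vec)
            ok = False
            for _ in range(max_rounds):
                prev = sse
                for axis in range(h):

                    def scalar(gax: float) -> float:
                        trial = g_vec.copy()
                        trial[axis] = gax
                        return objective(trial)[0]

                    res = minimize_scalar(
                        scalar, bounds=(0.0, 1.0), method="bounded",
                        options={"xatol": 1e-10},
                    )
                    if res.fun < sse:
                        g_vec[axis] = float(res.x)
                        sse, c = objective(g_vec)
                if prev - sse < tol:
                    ok = True
                    break
            if sse < best_sse - 1e-15 or best_g is None:
                best_sse, best_g, best_c, converged = sse, g_vec, c, ok

    lengths = {e: 0.0 for e in net.graph.edges()}
    for e, c_e in zip(free, best_c):
        lengths[e] = float(c_e)
    params = DriftParams(
        lengths=lengths,
        gammas={m: float(g) for m, g in zip(admix, best_g)},
        gamma_edges={m: gamma_edges[m] for m in admix},
    )
    from .drift import expected_f2

    y = expected_f2(net, params)
    ll = log_likelihood(data, y)
    raw, scaled = residuals(data, y)
    return FitResult(
        params=params,
        loglik=ll,
        converged=bool(converged),
        residuals=raw,
        scaled_residuals=scaled,
        labeling=labeling,
    )


@dataclass
class ScoreTable:
    """Per-labeling fit results for one network topology."""

    results: List[FitResult]

    @property
    def best(self) -> FitResult:
        best = self.results[0]
        for r in self.results[1:]:
            if r.loglik > best.loglik:
                best = r
        return best


def score_graph(
    net: DirectedNetwork,
    data: F2Dataset,
    convention: str = "treemix",
) -> Tuple[FitResult, ScoreTable]:
    """Best fit over all tree-based labelings (single fit for admixturegraph).

    Returns the max-likelihood result (first in enumeration order on
    ties) together with the full per-labeling score table.
    """
    if convention == "admixturegraph":
        res = fit_params(net, None, convention, data)
        return res, ScoreTable([res])
    labelings = enumerate_labelings(net)
    if not labelings:
        raise ValueError("no tree-based labeling exists for this network")
    results = [fit_params(net, lab, convention, data) for lab in labelings]
    best = results[0]
    for r in results[1:]:
        if r.loglik > best.loglik:
            best = r
    return best, ScoreTable(results)
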