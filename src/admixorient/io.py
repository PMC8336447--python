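"""File formats: f2 tables, graph edge lists, extended Newick.

Two f2 dialects are supported: a *pairs* TSV with columns
``popA  popB  f2  se`` (one row per unordered pair) and a square
*matrix* TSV whose header row and first column carry population names
(storing f2 values, with a constant standard error supplied by the
caller or a companion column convention).

Graphs are stored as edge-list TSVs with columns
``child  parent  edge_type  length  weight``; an admixture node appears
as the child in exactly two rows (``edge_type`` ``admixture``), carrying
its inheritance weight γ / 1−γ.  Leaves are named by their populations;
internal vertices get stable ``v<k>`` names so read/write round-trips.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .drift import DriftParams, F2Dataset, default_gamma_edges, leaf_pairs
from .network import DirectedNetwork, Edge, validate_directed

_NAME_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")

PathLike = Union[str, Path]


def _check_names(names) -> None:
    for n in names:
        if not _NAME_RE.match(str(n)):
            raise ValueError(f"population name {n!r} not in [A-Za-z0-9_.-]+")


# -- f2 datasets ---------------------------------------------------------


def read_f2(path: PathLike, dialect: str = "pairs", se: Optional[float] = None) -> F2Dataset:
    """Read an f2 dataset from a pairs TSV or a square-matrix TSV."""
    if dialect == "pairs":
        df = pd.read_csv(
            path, sep="\t", dtype={"popA": str, "popB": str},
            float_precision="round_trip",
        )
        required = {"popA", "popB", "f2", "se"}
        if not required.issubset(df.columns):
            raise ValueError(f"pairs file must have columns {sorted(required)}")
        _check_names(pd.concat([df.popA, df.popB]))
        pairs = [tuple(sorted((a, b))) for a, b in zip(df.popA, df.popB)]
        if len(set(pairs)) != len(pairs):
            dup = [p for p in pairs if pairs.count(p) > 1][0]
            raise ValueError(f"duplicate pair {dup}")
        pops = sorted({p for pair in pairs for p in pair})
        missing = set(leaf_pairs(pops)) - set(pairs)
        if missing:
            raise ValueError(f"missing pair {sorted(missing)[0]}")
        if (df.se <= 0).any():
            raise ValueError("non-positive standard error")
        ds = F2Dataset(pairs, df.f2.to_numpy(float), df.se.to_numpy(float))
        return ds.reordered()
    if dialect == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        pops = [str(c) for c in df.columns]
        _check_names(pops)
        if list(df.index.astype(str)) != pops:
            raise ValueError("matrix rows and columns must list the same populations")
        mat = df.to_numpy(float)
        if not np.allclose(mat, mat.T, atol=1e-12, rtol=0.0):
            raise ValueError("matrix dialect requires symmetry within 1e-12")
        if se is None:
            raise ValueError("matrix dialect needs a constant standard error")
        pairs = leaf_pairs(pops)
        x = np.array([mat[pops.index(a), pops.index(b)] for a, b in pairs])
        return F2Dataset(pairs, x, np.full(len(pairs), float(se)))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_f2(path: PathLike, data: F2Dataset, dialect: str = "pairs") -> None:
    data = data.reordered()
    if dialect == "pairs":
        df = pd.DataFrame(
            {
                "popA": [a for a, _ in data.pairs],
                "popB": [b for _, b in data.pairs],
                "f2": data.x,
                "se": data.se,
            }
        )
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect == "matrix":
        pops = data.populations
        mat = np.zeros((len(pops), len(pops)))
        for (a, b), v in zip(data.pairs, data.x):
            i, j = pops.index(a), pops.index(b)
            mat[i, j] = mat[j, i] = v
        pd.DataFrame(mat, index=pops, columns=pops).to_csv(
            path, sep="\t", float_format="%.17g"
        )
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# -- graphs --------------------------------------------------------------


def _vertex_names(net: DirectedNetwork) -> Dict[int, str]:
    names = {}
    for v in sorted(net.graph.nodes):
        names[v] = net.labels.get(v, f"v{v}")
    return names


def write_graph(
    path: PathLike,
    net: DirectedNetwork,
    params: Optional[DriftParams] = None,
) -> None:
    """Edge-list TSV: child, parent, edge_type, length, weight."""
    names = _vertex_names(net)
    admix = set(net.admixture_nodes)
    gamma_edges = params.gamma_edges if params is not None else {}
    rows = []
    for u, v in net.edges():
        etype = "admixture" if v in admix else "tree"
        length = params.lengths[(u, v)] if params is not None else 0.0
        if v in admix and params is not None:
            g = params.gammas[v]
            weight = g if gamma_edges.get(v) == (u, v) else 1.0 - g
        else:
            weight = 1.0
        rows.append(
            {
                "child": names[v],
                "parent": names[u],
                "edge_type": etype,
                "length": length,
                "weight": weight,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_graph(path: PathLike) -> Tuple[DirectedNetwork, DriftParams]:
    df = pd.read_csv(
        path, sep="\t", dtype={"child": str, "parent": str},
        float_precision="round_trip",
    )
    required = {"child", "parent", "edge_type", "length", "weight"}
    unknown = set(df.columns) - required
    if unknown:
        raise ValueError(f"unknown columns {sorted(unknown)}")
    if not required.issubset(df.columns):
        raise ValueError(f"graph file must have columns {sorted(required)}")
    names = sorted(set(df.child) | set(df.parent))
    ids = {n: i for i, n in enumerate(names)}
    import networkx as nx

    g = nx.DiGraph()
    for _, row in df.iterrows():
        u, v = ids[row["parent"]], ids[row["child"]]
        if g.has_edge(u, v):
            raise ValueError(f"duplicate edge {row['parent']}->{row['child']}")
        g.add_edge(u, v)
    labels = {
        ids[n]: n for n in names if g.out_degree(ids[n]) == 0
    }
    net = DirectedNetwork(g, labels)
    report = validate_directed(net)
    if not report.ok:
        raise ValueError(f"invalid graph file: {report.violations}")
    admix = set(net.admixture_nodes)
    lengths: Dict[Edge, float] = {}
    weights: Dict[Edge, float] = {}
    for _, row in df.iterrows():
        e = (ids[row["parent"]], ids[row["child"]])
        lengths[e] = float(row["length"])
        weights[e] = float(row["weight"])
        declared = row["edge_type"]
        actual = "admixture" if e[1] in admix else "tree"
        if declared != actual:
            raise ValueError(f"edge_type mismatch on {row['parent']}->{row['child']}")
    gamma_edges = default_gamma_edges(net)
    gammas = {m: weights[gamma_edges[m]] for m in admix}
    params = DriftParams(lengths=lengths, gammas=gammas, gamma_edges=gamma_edges)
    params.validate(net)
    return net, params


# -- extended Newick -----------------------------------------------------


def to_extended_newick(
    net: DirectedNetwork, params: Optional[DriftParams] = None
) -> str:
    """Extended-Newick string with #H tags for admixture nodes.

    The base structure follows one incoming edge per admixture node (the
    lexicographically smaller); the other parent refers to the node via
    its ``#H`` label.
    """
    admix = net.admixture_nodes
    hybrid_tag = {m: f"#H{k + 1}" for k, m in enumerate(admix)}
    primary_in = {m: sorted(net.graph.in_edges(m))[0] for m in admix}

    def length_suffix(edge: Edge) -> str:
        if params is None:
            return ""
        return f":{params.lengths[edge]:g}"

    def render(v: int, in_edge: Optional[Edge]) -> str:
        if in_edge is not None and in_edge[1] in hybrid_tag:
            m = in_edge[1]
            if in_edge != primary_in[m]:
                return f"{hybrid_tag[m]}{length_suffix(in_edge)}"
            inner = render_children(m)
            return f"{inner}{hybrid_tag[m]}{length_suffix(in_edge)}"
        if net.graph.out_degree(v) == 0:
            return f"{net.labels[v]}{length_suffix(in_edge) if in_edge else ''}"
        inner = render_children(v)
        return f"{inner}{length_suffix(in_edge) if in_edge else ''}"

    def render_children(v: int) -> str:
        if net.graph.out_degree(v) == 0:
            return net.labels[v]
        parts = [render(c, (v, c)) for c in sorted(net.graph.successors(v))]
        return "(" + ",".join(parts) + ")"

    return render(net.root, None) + ";"


# -- run logs ------------------------------------------------------------


def write_run_log(path: PathLike, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
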