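"""Weighted global and nodal graph measures.

All measures operate on symmetric weight matrices with entries in [0, 1]
(absolute partial correlations) using the reciprocal-weight distance
transform l_ij = 1/w_ij: strong connections are short.  Global measures
are characteristic path length, mean clustering coefficient, global
efficiency, and (mean) betweenness centrality; nodal measures are
strength, average shortest path length, clustering, local efficiency and
betweenness.  On 0/1 weights every measure reduces to its classical
binary counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "GraphMeasureSet",
    "shortest_path_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficients",
    "betweenness",
    "node_strength",
    "compute_measures",
    "global_measures",
]

GLOBAL_MEASURES = (
    "characteristic_path_length",
    "clustering_coefficient",
    "global_efficiency",
    "betweenness_centrality",
)

CLUSTERING_FAMILIES = ("onnela", "zhang")


@dataclass
class GraphMeasureSet:
    """Raw global and nodal graph measures for one weighted graph."""

    global_measures: dict[str, float]
    nodal: pd.DataFrame  # index: node label; columns: strength, path_length, ...
    n_infinite_pairs: int = 0
    clustering_family: str = "onnela"
    normalized: dict[str, float] = field(default_factory=dict)
    null_summary: dict[str, tuple[float, float]] = field(default_factory=dict)


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_matrix(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest weighted path distances under l = 1/w.

    Absent edges (w = 0) have infinite length; disconnected pairs keep
    distance inf.  The diagonal is 0.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    i, j = np.nonzero(np.triu(weights, 1))
    lengths = csr_matrix((1.0 / weights[i, j], (i, j)), shape=(n, n))
    return dijkstra(lengths, directed=False)


def characteristic_path_length(distances: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Characteristic path length L and nodal averages L_i.

    L_i is the mean of the finite distances from node i to all other nodes;
    L is the mean of the defined L_i.  Infinite (disconnected) pairs are
    excluded and counted; a fully isolated node has undefined (NaN) L_i and
    is excluded from L with a warning.
    """
    n = distances.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(distances) & off
    n_inf = int((off & ~np.isfinite(distances)).sum())
    with np.errstate(invalid="ignore"):
        sums = np.where(finite, distances, 0.0).sum(axis=1)
        counts = finite.sum(axis=1)
        nodal = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.isnan(nodal).any():
        warnings.warn(
            f"{int(np.isnan(nodal).sum())} isolated node(s) excluded from "
            "characteristic path length",
            stacklevel=2,
        )
    return float(np.nanmean(nodal)), nodal, n_inf


def global_efficiency(distances: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs (0 for inf)."""
    n = distances.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(distances) & (distances > 0), 1.0 / distances, 0.0)
    return float(inv[off].mean())


def local_efficiency(weights: np.ndarray) -> np.ndarray:
    """Nodal local efficiency: global efficiency of each node's
    neighborhood subgraph (neighbors = nonzero-weight contacts), with the
    original weights and the same 1/w distance transform."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(weights[i])[0]
        if nbrs.size < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        eff[i] = global_efficiency(shortest_path_matrix(sub))
    return eff


def clustering_coefficients(
    weights: np.ndarray, family: str = "onnela"
) -> tuple[np.ndarray, float]:
    """Weighted nodal clustering c_i and the global mean C.

    ``onnela`` (default): geometric-mean triangle intensity,
    c_i = sum_{j,k} (w'_ij w'_jk w'_ki)^(1/3) / (k_i (k_i - 1)) with weights
    rescaled by the network maximum (w' = w / max w) and k_i the number of
    nonzero-weight neighbors.

    ``zhang``: fully weight-based normalization,
    c_i = sum_{j,k} w'_ij w'_jk w'_ki / ((sum_j w'_ij)^2 - sum_j w'_ij^2),
    which never references the binary degree.

    Both reduce to the classical binary clustering coefficient on 0/1
    weights; c_i = 0 for nodes with fewer than two neighbors.
    """
    if family not in CLUSTERING_FAMILIES:
        raise ValueError(f"unknown clustering family {family!r}; choose from {CLUSTERING_FAMILIES}")
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    w = weights / wmax
    if family == "onnela":
        cube = np.cbrt(w)
        closed = np.diag(cube @ cube @ cube)  # ordered-pair triangle sum per node
        k = (weights > 0).sum(axis=1)
        denom = k * (k - 1)
    else:  # zhang
        closed = np.diag(w @ w @ w)
        s = w.sum(axis=1)
        denom = s**2 - (w**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, closed / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def betweenness(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal betweenness (Brandes counting over ordered pairs under
    l = 1/w) and the global value (mean over nodes)."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(weights, 1))
    g.add_weighted_edges_from(
        zip(i.tolist(), j.tolist(), (1.0 / weights[i, j]).tolist()), weight="length"
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    # networkx counts unordered source-target pairs for undirected graphs;
    # double to count ordered pairs.
    b = 2.0 * np.array([bc[i] for i in range(n)])
    return b, float(b.mean())


def node_strength(weights: np.ndarray) -> np.ndarray:
    """Sum of edge weights incident to each node."""
    return np.asarray(weights, dtype=float).sum(axis=1)


def compute_measures(weights: np.ndarray, clustering_family: str = "onnela",
                     node_labels: list[str] | None = None) -> GraphMeasureSet:
    """All global and nodal measures of one weighted graph."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    d = shortest_path_matrix(weights)
    cpl, nodal_path, n_inf = characteristic_path_length(d)
    c_nodal, c_global = clustering_coefficients(weights, clustering_family)
    b_nodal, b_global = betweenness(weights)
    labels = node_labels if node_labels is not None else [f"node{i:02d}" for i in range(n)]
    nodal = pd.DataFrame(
        {
            "strength": node_strength(weights),
            "path_length": nodal_path,
            "clustering": c_nodal,
            "local_efficiency": local_efficiency(weights),
            "betweenness": b_nodal,
        },
        index=pd.Index(labels, name="node"),
    )
    global_dict = {
        "characteristic_path_length": cpl,
        "clustering_coefficient": c_global,
        "global_efficiency": global_efficiency(d),
        "betweenness_centrality": b_global,
    }
    return GraphMeasureSet(global_dict, nodal, n_inf, clustering_family)


def global_measures(weights: np.ndarray, clustering_family: str = "onnela") -> dict[str, float]:
    """Only the four global measures (fast path used by the null ensemble)."""
    d = shortest_path_matrix(weights)
    cpl, _, _ = characteristic_path_length(d)
    _, c_global = clustering_coefficients(weights, clustering_family)
    _, b_global = betweenness(weights)
    return {
        "characteristic_path_length": cpl,
        "clustering_coefficient": c_global,
        "global_efficiency": global_efficiency(d),
        "betweenness_centrality": b_global,
    }
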