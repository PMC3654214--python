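"""Node-level and graph-level measures on binary undirected graphs.

Conventions for fragmented graphs (which arise at high correlation
thresholds): path-length averages run over *finite* distances only,
global efficiency scores unreachable pairs as 0, and nodes with fewer
than two neighbours have clustering and local efficiency 0.  Betweenness
uses the normalisation 1/((N-1)(N-2)) over ordered source-target pairs
and is computed by Brandes' pair-dependency accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp

from .graph import BinaryGraph


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path edge counts; unreachable pairs hold +inf.

    ``+inf`` is the explicit unreachable sentinel and is excluded from
    every average taken downstream.
    """

    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]

    def reachable(self) -> np.ndarray:
        """Boolean mask of finite off-diagonal entries."""
        m = np.isfinite(self.lengths)
        np.fill_diagonal(m, False)
        return m


def shortest_path_lengths(g: BinaryGraph) -> DistanceMatrix:
    """Breadth-first all-pairs distances in edge counts."""
    a = csr_matrix(g.adjacency.astype(np.int8))
    d = _sp(a, method="D", unweighted=True, directed=False)
    return DistanceMatrix(d)


def degrees(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node degree D_i and graph mean D."""
    d = g.degree_vector()
    return d, float(d.mean())


def characteristic_path_length(
    g: BinaryGraph, dist: DistanceMatrix | None = None
) -> tuple[float, np.ndarray, bool]:
    """Characteristic path length L and per-node means L_i.

    L_i averages the finite distances from node i; nodes with no reachable
    partner get NaN.  L is the mean of L_i over nodes with at least one
    reachable partner.  Returns ``(L, L_i, defined)``; on an edgeless
    graph the result is flagged undefined (``defined=False``, L=NaN).
    """
    if dist is None:
        dist = shortest_path_lengths(g)
    d = dist.lengths
    mask = dist.reachable()
    counts = mask.sum(axis=1)
    sums = np.where(mask, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        l_i = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.any(counts > 0):
        return math.nan, l_i, False
    return float(np.nanmean(l_i)), l_i, True


def global_efficiency(g: BinaryGraph, dist: DistanceMatrix | None = None) -> float:
    """Mean inverse shortest path over ordered pairs; unreachable pairs score 0."""
    n = g.n_nodes
    if n < 2:
        return 0.0
    if dist is None:
        dist = shortest_path_lengths(g)
    mask = dist.reachable()
    inv = np.where(mask, 1.0 / np.where(mask, dist.lengths, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficients(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """C_i = R_i / (D_i (D_i - 1) / 2) with R_i = adjacent neighbour pairs.

    C_i = 0 for nodes with fewer than two neighbours (the denominator
    vanishes).  Also returns the graph mean C.
    """
    a = g.adjacency.astype(np.float64)
    deg = g.degree_vector().astype(float)
    # (A^3)_ii counts closed 2-walks through i twice per triangle
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def local_efficiency(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Global efficiency of each node's neighbour-induced subgraph.

    E_i_loc = mean over ordered neighbour pairs of the inverse shortest
    path *within* the subgraph induced by the neighbours of i; 0 when the
    node has fewer than two neighbours.
    """
    n = g.n_nodes
    e = np.zeros(n)
    for i in range(n):
        nbrs = g.neighbors(i)
        k = nbrs.size
        if k < 2:
            continue
        sub = g.adjacency[np.ix_(nbrs, nbrs)]
        d = _sp(csr_matrix(sub.astype(np.int8)), method="D", unweighted=True,
                directed=False)
        mask = np.isfinite(d)
        np.fill_diagonal(mask, False)
        inv = np.where(mask, 1.0 / np.where(mask, d, 1.0), 0.0)
        e[i] = inv.sum() / (k * (k - 1))
    return e, float(e.mean())


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Normalised betweenness X_i over ordered source-target pairs.

    X_i = 1/((N-1)(N-2)) * sum over ordered pairs (f, j), f != j != i, of
    the fraction of shortest f-j paths passing through i.  Unreachable
    pairs contribute 0.  Brandes' accumulation gives each node's total
    pair dependency in O(N * E).
    """
    n = g.n_nodes
    if n < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    adj = [g.neighbors(v) for v in range(n)]
    delta_total = np.zeros(n)
    for s in range(n):
        # BFS from s building the shortest-path DAG
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = [s]
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    order.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # back-propagate pair dependencies
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                delta_total[w] += delta[w]
    # accumulating over every source counts each ordered (f, j) pair once
    return delta_total / ((n - 1) * (n - 2))


def identify_hubs(g: BinaryGraph, method: str = "degree", k: int = 1) -> list[int]:
    """Top-k nodes by degree or betweenness; ties break by node order."""
    if not (1 <= k <= g.n_nodes):
        raise ValueError(f"k must lie in [1, {g.n_nodes}]")
    if method == "degree":
        score = g.degree_vector().astype(float)
    elif method == "betweenness":
        score = betweenness_centrality(g)
    else:
        raise ValueError("method must be 'degree' or 'betweenness'")
    order = np.lexsort((np.arange(g.n_nodes), -score))
    return order[:k].tolist()


def degree_distribution(g: BinaryGraph, bin_edges) -> np.ndarray:
    """Histogram of node degrees over the given bin edges; counts sum to N."""
    d = g.degree_vector()
    edges = np.asarray(bin_edges, dtype=float)
    if d.min() < edges[0] or d.max() > edges[-1]:
        raise ValueError("degrees fall outside the provided bins")
    counts, _ = np.histogram(d, bins=edges)
    return counts


GRAPH_MEASURES = (
    "degree", "path_length", "global_efficiency", "clustering", "local_efficiency",
)
NODE_MEASURES = (
    "degree", "path_length", "clustering", "local_efficiency", "betweenness",
)


@dataclass
class MetricTable:
    """Every measure at one threshold for one subject-session graph."""

    subject: str
    session: str
    threshold_r: float | None
    node_labels: tuple[str, ...]
    node_values: dict  # measure -> (n_nodes,) array
    graph_values: dict  # measure -> float

    def to_long(self) -> pd.DataFrame:
        rows = []
        for measure, vec in self.node_values.items():
            for label, val in zip(self.node_labels, vec):
                rows.append((self.subject, self.session, self.threshold_r,
                             label, measure, float(val)))
        for measure, val in self.graph_values.items():
            rows.append((self.subject, self.session, self.threshold_r,
                         None, measure, float(val)))
        return pd.DataFrame(
            rows, columns=["subject", "session", "threshold", "node", "measure", "value"]
        )


def compute_metric_table(
    g: BinaryGraph,
    subject: str = "",
    session: str = "",
    strength: np.ndarray | None = None,
) -> MetricTable:
    """All per-node and graph-level measures of one binary graph.

    ``strength`` (from the complete weighted matrix) is attached if given;
    it is the one measure not derived from the thresholded graph.
    """
    dist = shortest_path_lengths(g)
    deg, deg_mean = degrees(g)
    l_graph, l_i, l_defined = characteristic_path_length(g, dist)
    eff = global_efficiency(g, dist)
    clus, clus_mean = clustering_coefficients(g)
    loc, loc_mean = local_efficiency(g)
    btw = betweenness_centrality(g) if g.n_nodes >= 3 else np.zeros(g.n_nodes)
    labels = g.labels or tuple(str(i) for i in range(g.n_nodes))
    node_values = {
        "degree": deg.astype(float),
        "path_length": l_i,
        "clustering": clus,
        "local_efficiency": loc,
        "betweenness": btw,
    }
    graph_values = {
        "degree": deg_mean,
        "path_length": l_graph if l_defined else math.nan,
        "global_efficiency": eff,
        "clustering": clus_mean,
        "local_efficiency": loc_mean,
    }
    if strength is not None:
        node_values["strength"] = np.asarray(strength, dtype=float)
        graph_values["strength"] = float(np.mean(strength))
    return MetricTable(
        subject=subject,
        session=session,
        threshold_r=g.threshold_r,
        node_labels=labels,
        node_values=node_values,
        graph_values=graph_values,
    )
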