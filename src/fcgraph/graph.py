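"""Undirected binary graph container used throughout the pipeline.

Graphs obtained by thresholding a correlation matrix are unweighted and
undirected, with no self-loops.  The adjacency matrix is the canonical
representation; node identity is positional (0..n-1), with optional
string labels carried along for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph without self-loops.

    Parameters
    ----------
    adjacency
        Boolean (n, n) matrix; must be symmetric with a zero diagonal.
    labels
        Optional node labels in node order.
    threshold_r
        Correlation threshold the graph was built at, or ``None`` for
        fixtures and generated graphs.
    """

    adjacency: np.ndarray
    labels: tuple[str, ...] | None = None
    threshold_r: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        object.__setattr__(self, "adjacency", a)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != a.shape[0]:
                raise ValueError("labels length must match node count")
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
            object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Edge list as sorted (i, j) pairs with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def degree_vector(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def neighbors(self, node: int) -> np.ndarray:
        return np.nonzero(self.adjacency[node])[0]

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges,
        labels=None,
        threshold_r: float | None = None,
    ) -> "BinaryGraph":
        a = np.zeros((n_nodes, n_nodes), dtype=bool)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"edge ({i},{j}) outside node range")
            a[i, j] = a[j, i] = True
        return cls(a, labels=labels, threshold_r=threshold_r)

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (for interop/plot tools)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_nodes={self.n_nodes}")
            if self.threshold_r is not None:
                fh.write(f" threshold_r={self.threshold_r}")
            fh.write("\n")
            for i, j in self.edges():
                fh.write(f"{i}\t{j}\n")

    def write_graphml(self, path) -> None:
        import networkx as nx

        g = self.to_networkx()
        if self.labels is not None:
            nx.set_node_attributes(
                g, {i: lab for i, lab in enumerate(self.labels)}, "label"
            )
        if self.threshold_r is not None:
            g.graph["threshold_r"] = self.threshold_r
        nx.write_graphml(g, path)
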