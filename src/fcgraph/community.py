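"""Modularity Q, Louvain community detection, and participation coefficients.

Q for a partition P of a binary graph with adjacency A and edge count
alpha is (1/2*alpha) * sum over modules of sum over node pairs (i, j) in
the module of (A_ij - k_i*k_j / (2*alpha)).  The Louvain optimiser is the
greedy two-phase scheme: local node moves to the neighbouring module with
the largest Q gain, then aggregation of modules into super-nodes, repeated
until no gain remains.  Node-visit order is a seeded shuffle per pass and
ties in gain break toward the lowest module id, so results are
deterministic under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .graph import BinaryGraph


@dataclass(frozen=True)
class Partition:
    """Module assignment with its modularity score."""

    module_of: np.ndarray  # node -> module id, contiguous from 0
    q: float

    def __post_init__(self) -> None:
        m = np.asarray(self.module_of, dtype=int)
        ids = np.unique(m)
        if not np.array_equal(ids, np.arange(ids.size)):
            raise ValueError("module ids must be contiguous from 0")
        object.__setattr__(self, "module_of", m)

    @property
    def n_modules(self) -> int:
        return int(self.module_of.max()) + 1 if self.module_of.size else 0

    def members(self) -> list[list[int]]:
        return [np.nonzero(self.module_of == c)[0].tolist()
                for c in range(self.n_modules)]

    def write_tsv(self, path, labels=None) -> None:
        with open(path, "w") as fh:
            fh.write("node\tmodule\n")
            for i, c in enumerate(self.module_of):
                name = labels[i] if labels is not None else i
                fh.write(f"{name}\t{c}\n")

    def write_json(self, path, labels=None) -> None:
        mods = self.members()
        if labels is not None:
            mods = [[labels[i] for i in mod] for mod in mods]
        with open(path, "w") as fh:
            json.dump({"q": self.q, "modules": mods}, fh, indent=1)


def _as_assignment(g: BinaryGraph, partition) -> np.ndarray:
    m = np.asarray(partition, dtype=int)
    if m.shape != (g.n_nodes,):
        raise ValueError("partition must assign every node exactly one module")
    return m


def modularity_q(g: BinaryGraph, partition) -> float:
    """Evaluate Q for a given node -> module assignment."""
    m = _as_assignment(g, partition)
    alpha = g.n_edges
    if alpha < 1:
        raise ValueError("modularity requires at least one edge")
    a = g.adjacency.astype(float)
    k = g.degree_vector().astype(float)
    same = m[:, None] == m[None, :]
    two_alpha = 2.0 * alpha
    return float(((a - np.outer(k, k) / two_alpha) * same).sum() / two_alpha)


def _relabel(comm: np.ndarray) -> np.ndarray:
    """Contiguous ids from 0 in order of first appearance."""
    _, inv = np.unique(comm, return_inverse=True)
    first = {}
    out = np.empty_like(comm)
    nxt = 0
    for i, c in enumerate(comm):
        if c not in first:
            first[c] = nxt
            nxt += 1
        out[i] = first[c]
    return out


def _one_level(nbrs, weights, k, m2, rng):
    """One local-move phase; returns the community vector and move count."""
    n = len(nbrs)
    comm = np.arange(n)
    sig_tot = k.copy()
    total_moves = 0
    while True:
        moves = 0
        for i in rng.permutation(n):
            ci = comm[i]
            links: dict[int, float] = {}
            for j, w in zip(nbrs[i], weights[i]):
                if j != i:
                    cj = comm[j]
                    links[cj] = links.get(cj, 0.0) + w
            sig_tot[ci] -= k[i]
            best_c, best_gain = ci, links.get(ci, 0.0) - sig_tot[ci] * k[i] / m2
            for c in sorted(links):
                gain = links[c] - sig_tot[c] * k[i] / m2
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            sig_tot[best_c] += k[i]
            if best_c != ci:
                comm[i] = best_c
                moves += 1
        total_moves += moves
        if moves == 0:
            return comm, total_moves


def _aggregate(nbrs, weights, comm):
    """Collapse communities into super-nodes with summed edge weights."""
    labels = _relabel(comm)
    nc = labels.max() + 1
    agg: list[dict[int, float]] = [dict() for _ in range(nc)]
    for i in range(len(nbrs)):
        ci = labels[i]
        for j, w in zip(nbrs[i], weights[i]):
            cj = labels[j]
            agg[ci][cj] = agg[ci].get(cj, 0.0) + w
    new_nbrs = [np.array(sorted(d), dtype=int) for d in agg]
    new_weights = [np.array([d[j] for j in sorted(d)]) for d in agg]
    return new_nbrs, new_weights, labels


def _louvain_once(g: BinaryGraph, rng) -> np.ndarray:
    a = g.adjacency
    nbrs = [np.nonzero(a[i])[0] for i in range(g.n_nodes)]
    weights = [np.ones(len(x)) for x in nbrs]
    m2 = float(sum(w.sum() for w in weights))  # = 2 * alpha for a simple graph
    node_comm = np.arange(g.n_nodes)
    while True:
        # k includes aggregated self-loop weight: a super-node's strength is
        # the summed degree of its members, keeping m2 constant across levels
        k = np.array([w.sum() for w in weights])
        comm, moves = _one_level(nbrs, weights, k, m2, rng)
        if moves == 0:
            break
        nbrs, weights, labels = _aggregate(nbrs, weights, comm)
        node_comm = labels[node_comm]
    return _relabel(node_comm)


def louvain_partition(g: BinaryGraph, seed: int = 0, n_restarts: int = 10) -> Partition:
    """Best-of-n_restarts Louvain partition with its modularity score.

    Louvain is sensitive to node-visit order, so each restart shuffles
    with an independent substream of ``seed`` and the partition with the
    highest Q is returned.
    """
    if g.n_edges < 1:
        raise ValueError("Louvain requires at least one edge")
    best: Partition | None = None
    for ss in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(ss)
        assignment = _louvain_once(g, rng)
        q = modularity_q(g, assignment)
        if best is None or q > best.q + 1e-15:
            best = Partition(_relabel(assignment), q)
    assert best is not None
    return best


@dataclass(frozen=True)
class ParticipationResult:
    """Participation coefficients and the per-module link tallies behind them."""

    omega: np.ndarray  # per node, in [0, 1)
    link_counts: np.ndarray  # (n_nodes, n_modules) edges into each module
    degree: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.link_counts.sum(axis=1), self.degree):
            raise ValueError("module link counts must sum to the degree")


def participation_coefficients(g: BinaryGraph, partition) -> ParticipationResult:
    """Omega_j = 1 - sum_c (beta_jc / beta_j)^2 per node.

    beta_jc counts node j's edges into module c and beta_j is its degree.
    A node whose edges all stay inside its own module scores 0; isolated
    nodes score 0 by convention.
    """
    if isinstance(partition, Partition):
        m = partition.module_of
    else:
        m = _as_assignment(g, partition)
    n_modules = int(m.max()) + 1
    counts = np.zeros((g.n_nodes, n_modules))
    for i in range(g.n_nodes):
        for j in g.neighbors(i):
            counts[i, m[j]] += 1
    deg = g.degree_vector().astype(float)
    safe = np.maximum(deg, 1.0)
    omega = np.where(deg > 0, 1.0 - ((counts / safe[:, None]) ** 2).sum(axis=1), 0.0)
    return ParticipationResult(omega=omega, link_counts=counts, degree=deg)
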