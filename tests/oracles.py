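"""Independent brute-force implementations used only to check the package.

Everything here is deliberately naive — Floyd-Warshall distances,
exhaustive shortest-path enumeration for betweenness, double loops over
the modularity formula — so that agreement with the fast implementations
is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = math.inf


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[a.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(a: np.ndarray):
    """(L, L_i) averaging finite off-diagonal distances only."""
    d = floyd_warshall(a)
    n = a.shape[0]
    l_i = []
    for i in range(n):
        row = [d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])]
        l_i.append(sum(row) / len(row) if row else math.nan)
    finite = [x for x in l_i if not math.isnan(x)]
    return (sum(finite) / len(finite) if finite else math.nan), np.array(l_i)


def global_eff(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    if n < 2:
        return 0.0
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(
            1 for x, y in itertools.combinations(nbrs, 2) if a[x, y]
        )
        out[i] = closed / (k * (k - 1) / 2)
    return out


def local_eff(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = global_eff(sub)
    return out


def _all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path, by breadth-first enumeration."""
    if s == t:
        return [(s,)]
    n = a.shape[0]
    best: dict[int, int] = {s: 0}
    frontier = [(s,)]
    found: list[tuple[int, ...]] = []
    while frontier and not found:
        nxt = []
        for path in frontier:
            v = path[-1]
            for w in range(n):
                if not a[v, w]:
                    continue
                depth = len(path)
                if w in best and best[w] < depth:
                    continue
                best[w] = depth
                new = path + (w,)
                if w == t:
                    found.append(new)
                else:
                    nxt.append(new)
        frontier = nxt
    return found


def betweenness(a: np.ndarray) -> np.ndarray:
    """Normalised betweenness by exhaustive shortest-path counting."""
    n = a.shape[0]
    out = np.zeros(n)
    for f in range(n):
        for j in range(n):
            if f == j:
                continue
            paths = _all_shortest_paths(a, f, j)
            if not paths:
                continue
            for i in range(n):
                if i in (f, j):
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                out[i] += through / len(paths)
    return out / ((n - 1) * (n - 2))


def modularity(a: np.ndarray, module_of) -> float:
    n = a.shape[0]
    m = np.asarray(module_of)
    alpha = a.sum() / 2
    k = a.sum(axis=1)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if m[i] == m[j]:
                total += a[i, j] - k[i] * k[j] / (2 * alpha)
    return total / (2 * alpha)


def participation(a: np.ndarray, module_of) -> np.ndarray:
    n = a.shape[0]
    m = np.asarray(module_of)
    out = np.zeros(n)
    for i in range(n):
        deg = a[i].sum()
        if deg == 0:
            continue
        acc = 0.0
        for c in np.unique(m):
            beta_c = sum(a[i, j] for j in range(n) if m[j] == c)
            acc += (beta_c / deg) ** 2
        out[i] = 1.0 - acc
    return out


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return (a | a.T).astype(bool)
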