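"""Markov Cluster Algorithm (MCL) on small weighted graphs.

Flow-based community detection by alternating expansion (matrix squaring) and
inflation (elementwise power followed by column renormalization) on the
column-stochastic transition matrix of the graph, with self-loops added.
The dense-matrix implementation here targets the graph sizes this package
produces (thousands of nodes at most); it is deterministic for a fixed input.
"""

from __future__ import annotations

from collections.abc import Hashable, Iterable

import numpy as np


def markov_cluster(
    edges: Iterable[tuple[Hashable, Hashable, float]],
    nodes: Iterable[Hashable] = (),
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune: float = 1e-7,
) -> list[set]:
    """Cluster an undirected weighted graph with MCL.

    Parameters
    ----------
    edges:
        ``(u, v, weight)`` triples; weights must be positive.
    nodes:
        Optional extra nodes; isolated ones come back as singleton clusters.
    inflation:
        Inflation exponent; larger values give finer clusters.

    Returns
    -------
    List of node sets (clusters), sorted by size then lexicographically for
    determinism.  Every node appears in exactly one cluster.
    """
    edge_list = list(edges)
    index: dict[Hashable, int] = {}
    for u, v, _w in edge_list:
        index.setdefault(u, len(index))
        index.setdefault(v, len(index))
    for n in nodes:
        index.setdefault(n, len(index))
    n = len(index)
    if n == 0:
        return []
    M = np.zeros((n, n))
    for u, v, w in edge_list:
        if w <= 0:
            raise ValueError(f"non-positive edge weight {w} on ({u}, {v})")
        i, j = index[u], index[v]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    # Self-loops at the column maximum (1.0 for isolated nodes) stabilize flow.
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = np.power(M, inflation)  # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    # Attractors are rows with positive diagonal mass; each attractor's row
    # support is one cluster.  Overlapping supports are merged.
    names = {i: node for node, i in index.items()}
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    attractors = [i for i in range(n) if M[i, i] > tol]
    for a in attractors:
        members = np.nonzero(M[a] > tol)[0]
        for m in members:
            union(int(m), a)
    clusters: dict[int, set] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(names[i])
    return sorted(clusters.values(),
                  key=lambda s: (-len(s), sorted(map(str, s))))
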