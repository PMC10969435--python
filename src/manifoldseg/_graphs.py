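"""Compiled all-pairs shortest-path kernels.

Both kernels operate on symmetric weighted graphs and return dense
``(n, n)`` distance matrices with ``inf`` marking unreachable pairs.
They are deliberately independent implementations so each can serve as
a cross-check for the other.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["floyd_warshall_kernel", "dijkstra_kernel"]


@njit(cache=True)
def _fw_inplace(dist):  # pragma: no cover - exercised through wrapper
    n = dist.shape[0]
    for k in range(n):
        for i in range(n):
            dik = dist[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                alt = dik + dist[k, j]
                if alt < dist[i, j]:
                    dist[i, j] = alt


def floyd_warshall_kernel(adjacency_dense: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the Floyd-Warshall recurrence.

    ``adjacency_dense`` holds edge weights, ``inf`` for absent edges and
    0 on the diagonal.  O(n^3) time, O(n^2) memory; intended for graphs
    of a few hundred nodes.
    """
    dist = np.array(adjacency_dense, dtype=np.float64, copy=True)
    np.fill_diagonal(dist, 0.0)
    _fw_inplace(dist)
    return dist


@njit(cache=True)
def _dijkstra_all(indptr, indices, weights, n):  # pragma: no cover
    out = np.full((n, n), np.inf)
    visited = np.empty(n, np.bool_)
    for s in range(n):
        dist = out[s]
        dist[s] = 0.0
        visited[:] = False
        for _ in range(n):
            # linear scan for the closest unvisited node; O(n^2) per
            # source but branch-cheap and cache friendly at our sizes
            u = -1
            best = np.inf
            for v in range(n):
                if not visited[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u < 0:
                break
            visited[u] = True
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                alt = best + weights[e]
                if alt < dist[v]:
                    dist[v] = alt
    return out


def dijkstra_kernel(indptr: np.ndarray, indices: np.ndarray,
                    weights: np.ndarray, n: int) -> np.ndarray:
    """All-pairs shortest paths by repeated single-source Dijkstra.

    Takes the CSR arrays of a symmetric adjacency matrix.  Non-negative
    weights are assumed (Euclidean edge lengths always are).
    """
    return _dijkstra_all(
        indptr.astype(np.int64),
        indices.astype(np.int64),
        weights.astype(np.float64),
        n,
    )
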