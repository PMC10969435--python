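"""Manifold-learning core: k-NN graphs, geodesics, classical MDS, Isomap, LLE.

All solvers here are written against plain numpy/scipy arrays so that the
imaging layers can hand in any feature matrix (voxels x channels, points x
coordinates).  Eigenvector sign is made deterministic everywhere: the
largest-magnitude entry of each embedding column is forced positive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph
import scipy.sparse.linalg
from scipy.spatial.distance import squareform, pdist

from ._graphs import dijkstra_kernel, floyd_warshall_kernel

__all__ = [
    "NeighborGraph",
    "GeodesicDistanceMatrix",
    "Embedding",
    "LleWeights",
    "build_knn_graph",
    "connect_components",
    "geodesic_floyd_warshall",
    "geodesic_dijkstra",
    "select_geodesic_backend",
    "geodesic_distances",
    "classical_mds",
    "isomap",
    "lle_weights",
    "lle_embed",
    "lle",
    "lle_embedding_cost",
]

#: default node-count threshold below which Floyd-Warshall is preferred
FLOYD_WARSHALL_MAX_N = 500
#: node count below which dense eigensolvers are used
DENSE_EIGEN_MAX_N = 800


@dataclass
class NeighborGraph:
    """Symmetric weighted k-nearest-neighbour graph over N samples."""

    adjacency: sp.csr_matrix  # weights = Euclidean distances
    k: int
    symmetrize: str = "union"

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GeodesicDistanceMatrix:
    """All-pairs graph shortest-path lengths; ``inf`` = unreachable."""

    values: np.ndarray
    connected: bool
    backend: str = ""


@dataclass
class Embedding:
    """Low-dimensional coordinates, one row per input sample.

    Rows excluded from the embedding (samples outside the largest
    connected component of the neighbour graph) are NaN and flagged in
    ``included``.
    """

    values: np.ndarray  # (n, d)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    included: np.ndarray | None = None  # bool mask, None = all included

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def included_mask(self) -> np.ndarray:
        if self.included is None:
            return np.ones(self.values.shape[0], dtype=bool)
        return self.included


@dataclass
class LleWeights:
    """Row-stochastic barycentric reconstruction weights on a k-NN graph."""

    values: sp.csr_matrix
    regularization: float


def _validate_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D (samples x features)")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def build_knn_graph(X: np.ndarray, k: int, symmetrize: str = "union") -> NeighborGraph:
    """Euclidean k-nearest-neighbour graph, symmetrized.

    Parameters
    ----------
    X
        (n, D) feature matrix.
    k
        neighbourhood size; must satisfy ``1 <= k < n``.
    symmetrize
        ``"union"`` keeps an edge if either endpoint selects it (the
        common Isomap convention, guarantees degree >= k); ``"mutual"``
        keeps it only if both do.

    Ties in distance are broken by the lower sample index.  Exact
    duplicate points produce edges whose weight is machine epsilon so
    the graph stays interpretable as a positively weighted graph.
    """
    X = _validate_features(X)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n; got k={k}, n={n}")
    if symmetrize not in ("union", "mutual"):
        raise ValueError("symmetrize must be 'union' or 'mutual'")

    dists = squareform(pdist(X))
    np.fill_diagonal(dists, np.inf)
    # stable argsort => ties resolved toward the lower index
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    w = np.take_along_axis(dists, order, axis=1)
    eps = np.finfo(np.float64).eps
    w = np.maximum(w, eps)

    rows = np.repeat(np.arange(n), k)
    directed = sp.csr_matrix((w.ravel(), (rows, order.ravel())), shape=(n, n))
    if symmetrize == "union":
        adjacency = directed.maximum(directed.T)
    else:
        pattern = directed.copy()
        pattern.data[:] = 1.0
        both = pattern.minimum(pattern.T)
        adjacency = directed.multiply(both).maximum(directed.T.multiply(both))
        adjacency = sp.csr_matrix(adjacency)
    adjacency.eliminate_zeros()
    return NeighborGraph(adjacency=sp.csr_matrix(adjacency), k=k, symmetrize=symmetrize)


def connect_components(graph: NeighborGraph, X: np.ndarray) -> NeighborGraph:
    """Bridge a disconnected k-NN graph with minimal Euclidean edges.

    Distinct tissue clusters can sit farther apart in feature space than
    any within-cluster spacing, in which case even generous
    neighbourhood sizes leave the k-NN graph disconnected.  This adds,
    per component pair in a minimum-spanning-tree over components, the
    single edge joining their closest two points, so geodesics remain
    meaningful (each bridge has its true Euclidean length) and every
    sample stays embeddable.
    """
    X = _validate_features(X)
    n_comp, labels = sp.csgraph.connected_components(graph.adjacency,
                                                     directed=False)
    if n_comp == 1:
        return graph
    dists = squareform(pdist(X))
    comp_d = np.full((n_comp, n_comp), np.inf)
    comp_pair = np.zeros((n_comp, n_comp, 2), dtype=np.int64)
    for a in range(n_comp):
        ia = np.flatnonzero(labels == a)
        for b in range(a + 1, n_comp):
            ib = np.flatnonzero(labels == b)
            block = dists[np.ix_(ia, ib)]
            r, c = np.unravel_index(np.argmin(block), block.shape)
            comp_d[a, b] = comp_d[b, a] = block[r, c]
            comp_pair[a, b] = comp_pair[b, a] = (ia[r], ib[c])
    mst = sp.csgraph.minimum_spanning_tree(sp.csr_matrix(comp_d)).tocoo()
    adj = graph.adjacency.tolil()
    for a, b in zip(mst.row, mst.col):
        i, j = comp_pair[a, b]
        w = max(dists[i, j], np.finfo(np.float64).eps)
        adj[i, j] = w
        adj[j, i] = w
    return NeighborGraph(adjacency=sp.csr_matrix(adj), k=graph.k,
                         symmetrize=graph.symmetrize)


def select_geodesic_backend(graph: NeighborGraph, threshold: int = FLOYD_WARSHALL_MAX_N,
                            override: str | None = None) -> str:
    """Pick the shortest-path algorithm for a graph.

    Small dense problems favour the simple Floyd-Warshall recurrence;
    larger sparse graphs favour repeated Dijkstra.  ``override`` forces
    a backend regardless of size.
    """
    if override is not None:
        if override not in ("floyd_warshall", "dijkstra"):
            raise ValueError(f"unknown backend {override!r}")
        return override
    return "floyd_warshall" if graph.n_nodes <= threshold else "dijkstra"


def geodesic_floyd_warshall(graph: NeighborGraph) -> GeodesicDistanceMatrix:
    """All-pairs geodesics via the Floyd-Warshall recurrence."""
    a = graph.adjacency.toarray()
    dense = np.where(a > 0, a, np.inf)
    np.fill_diagonal(dense, 0.0)
    values = floyd_warshall_kernel(dense)
    connected = bool(np.all(np.isfinite(values)))
    return GeodesicDistanceMatrix(values=values, connected=connected,
                                  backend="floyd_warshall")


def geodesic_dijkstra(graph: NeighborGraph) -> GeodesicDistanceMatrix:
    """All-pairs geodesics via repeated single-source Dijkstra."""
    adj = graph.adjacency.tocsr()
    values = dijkstra_kernel(adj.indptr, adj.indices, adj.data, graph.n_nodes)
    connected = bool(np.all(np.isfinite(values)))
    return GeodesicDistanceMatrix(values=values, connected=connected,
                                  backend="dijkstra")


def geodesic_distances(graph: NeighborGraph, backend: str = "auto",
                       threshold: int = FLOYD_WARSHALL_MAX_N) -> GeodesicDistanceMatrix:
    """Dispatch to a shortest-path backend (``auto`` selects by size)."""
    if backend == "auto":
        backend = select_geodesic_backend(graph, threshold=threshold)
    if backend == "floyd_warshall":
        return geodesic_floyd_warshall(graph)
    if backend == "dijkstra":
        return geodesic_dijkstra(graph)
    raise ValueError(f"unknown backend {backend!r}")


def _fix_signs(Y: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude entry of each column positive."""
    for j in range(Y.shape[1]):
        col = Y[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            Y[:, j] = -col
    return Y


def _seeded_v0(n: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).standard_normal(n)


def classical_mds(dmat: np.ndarray, d: int, seed: int = 0) -> Embedding:
    """Classical (Torgerson) multidimensional scaling.

    The squared-distance matrix is double-centred into the Gram matrix
    ``B = -1/2 J D^2 J`` and the embedding is the top-``d`` eigenvector
    columns of ``B`` scaled by the square root of their eigenvalues.
    Negative eigenvalues (non-Euclidean distance data) are truncated at
    zero.
    """
    D = np.asarray(dmat, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"target dimension d={d} out of range for n={n}")
    if not np.all(np.isfinite(D)):
        raise ValueError(
            "distance matrix has non-finite entries (disconnected graph); "
            "restrict to the largest connected component first")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")

    D2 = D ** 2
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    B = -0.5 * (D2 - row - col + D2.mean())
    B = 0.5 * (B + B.T)

    if n <= DENSE_EIGEN_MAX_N:
        evals, evecs = scipy.linalg.eigh(B, subset_by_index=[n - d, n - 1])
        evals, evecs = evals[::-1], evecs[:, ::-1]
    else:
        evals, evecs = sp.linalg.eigsh(B, k=d, which="LA", v0=_seeded_v0(n, seed))
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]

    lam = np.clip(evals, 0.0, None)
    Y = evecs * np.sqrt(lam)[np.newaxis, :]
    return Embedding(values=_fix_signs(Y), eigenvalues=evals)


def _largest_component(adjacency: sp.csr_matrix) -> np.ndarray:
    n_comp, labels = sp.csgraph.connected_components(adjacency, directed=False)
    if n_comp == 1:
        return np.ones(adjacency.shape[0], dtype=bool)
    sizes = np.bincount(labels)
    return labels == int(np.argmax(sizes))  # ties -> lowest label


def _embed_with_fallback(X, graph, embed_component, d):
    """Run ``embed_component`` on the largest connected component.

    Samples outside it are flagged (NaN rows).  ``embed_component`` maps
    (X_sub, graph_sub) -> Embedding.
    """
    keep = _largest_component(graph.adjacency)
    if keep.all():
        return embed_component(X, graph)
    warnings.warn(
        f"neighbour graph disconnected; embedding largest component "
        f"({int(keep.sum())}/{keep.size} samples)", stacklevel=3)
    sub_adj = graph.adjacency[keep][:, keep]
    sub_graph = NeighborGraph(adjacency=sp.csr_matrix(sub_adj), k=graph.k,
                              symmetrize=graph.symmetrize)
    sub = embed_component(X[keep], sub_graph)
    values = np.full((keep.size, d), np.nan)
    values[keep] = sub.values
    return Embedding(values=values, eigenvalues=sub.eigenvalues, included=keep)


def isomap(X: np.ndarray, k: int, d: int, backend: str = "auto",
           symmetrize: str = "union", seed: int = 0,
           fw_threshold: int = FLOYD_WARSHALL_MAX_N) -> Embedding:
    """Isometric feature mapping.

    Builds the Euclidean k-NN graph, computes all-pairs geodesic
    distances on it, and applies classical MDS to the geodesic distance
    matrix.  If the graph is disconnected the largest component is
    embedded and the remaining samples are flagged.
    """
    X = _validate_features(X)
    graph = build_knn_graph(X, k, symmetrize=symmetrize)

    def embed(_X_sub, graph_sub):
        geo = geodesic_distances(graph_sub, backend=backend, threshold=fw_threshold)
        return classical_mds(geo.values, d, seed=seed)

    return _embed_with_fallback(X, graph, embed, d)


def lle_weights(X: np.ndarray, graph: NeighborGraph,
                regularization: float = 1e-3) -> LleWeights:
    """Barycentric reconstruction weights for LLE.

    Each sample is reconstructed as a convex-affine combination of its
    graph neighbours by solving the local Gram system; a ridge term
    ``regularization * trace(G_local) / k`` keeps the system well-posed
    when the neighbourhood size exceeds the ambient dimension (always
    the case for 4-channel MRI with K ~ 100).  Rows sum to exactly 1.
    """
    X = _validate_features(X)
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    adj = graph.adjacency.tocsr()
    n = X.shape[0]
    rows, cols, vals = [], [], []
    for i in range(n):
        nbrs = adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
        if nbrs.size == 0:
            raise ValueError(f"sample {i} has no neighbours")
        Z = X[nbrs] - X[i]
        G = Z @ Z.T
        trace = np.trace(G)
        ridge = regularization * (trace / nbrs.size if trace > 0 else 1.0)
        try:
            w = scipy.linalg.solve(G + ridge * np.eye(nbrs.size),
                                   np.ones(nbrs.size), assume_a="pos")
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as err:
            raise np.linalg.LinAlgError(
                f"singular local Gram matrix at sample {i}; "
                "use regularization > 0") from err
        s = w.sum()
        if s == 0 or not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError(
                f"degenerate local solve at sample {i}; "
                "use regularization > 0")
        w = w / s
        rows.append(np.full(nbrs.size, i))
        cols.append(nbrs)
        vals.append(w)
    W = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return LleWeights(values=W, regularization=regularization)


def lle_embed(weights: LleWeights, d: int, seed: int = 0) -> Embedding:
    """Embedding step of LLE.

    Solves for the eigenvectors of ``M = (I - W)^T (I - W)`` with the
    ``d`` smallest non-zero eigenvalues, discarding the constant
    (zero-eigenvalue) vector, and scales to unit covariance.
    """
    W = weights.values
    n = W.shape[0]
    if not 1 <= d <= n - 2:
        raise ValueError(f"target dimension d={d} requires n >= d + 2")
    I_W = sp.eye(n, format="csr") - W
    M = (I_W.T @ I_W).tocsr()

    n_small = d + 1
    if n <= max(DENSE_EIGEN_MAX_N, 2500):
        evals, evecs = scipy.linalg.eigh(M.toarray(), subset_by_index=[0, n_small - 1])
    else:
        # shift-invert around a slightly negative value: M is PSD with a
        # zero eigenvalue, so factorizing M + eps*I is safe
        evals, evecs = sp.linalg.eigsh(M, k=n_small, sigma=-1e-6, which="LM",
                                       v0=_seeded_v0(n, seed))
        idx = np.argsort(evals)
        evals, evecs = evals[idx], evecs[:, idx]

    # the number of exactly-zero eigenvalues equals the number of
    # connected components of the weight graph; magnitude thresholds are
    # unreliable because genuine LLE eigenvalues can be ~1e-12
    pattern = W.copy()
    pattern.data = np.ones_like(pattern.data)
    n_comp, _ = sp.csgraph.connected_components(pattern.maximum(pattern.T),
                                                directed=False)
    if n_comp > 1:
        raise ValueError(
            f"weight graph has {n_comp} connected components; embed each "
            "component separately (d would exceed the non-zero eigenvalues)")
    Y = evecs[:, 1:d + 1] * np.sqrt(n)
    return Embedding(values=_fix_signs(Y), eigenvalues=evals[1:d + 1])


def lle(X: np.ndarray, k: int, d: int, regularization: float = 1e-3,
        symmetrize: str = "union", seed: int = 0) -> Embedding:
    """Locally linear embedding: weights step + eigen embedding step.

    Disconnected graphs are handled as in :func:`isomap` (largest
    component embedded, the rest flagged).
    """
    X = _validate_features(X)
    graph = build_knn_graph(X, k, symmetrize=symmetrize)

    def embed(X_sub, graph_sub):
        W = lle_weights(X_sub, graph_sub, regularization=regularization)
        return lle_embed(W, d, seed=seed)

    return _embed_with_fallback(X, graph, embed, d)


def lle_embedding_cost(weights: LleWeights, Y: np.ndarray) -> float:
    """Embedding cost phi(Y) = sum_i ||y_i - sum_j w_ij y_j||^2."""
    R = Y - weights.values @ Y
    return float(np.sum(R * R))
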