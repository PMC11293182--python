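"""Adaptive k-nearest-neighbor graph construction and SNN reweighting.

The central idea: instead of connecting every cell to a fixed number k of
nearest neighbors, each cell i gets its own k_i read off its local distance
distribution.  Given the sorted distances d_i1 <= ... <= d_iKmax to the K_max
nearest neighbors, a per-cell distance cutoff

    cutoff_i = ( sum_l sqrt(d_il) / (K_max - 1 - delta) )^2

is computed (the closed-form solution of an assignment objective under
Karush-Kuhn-Tucker conditions), and cell i keeps exactly the neighbors closer
than cutoff_i.  The hyperparameter delta <= 0 tunes sensitivity to local
distance change: more negative delta shrinks the cutoff, giving fewer
neighbors.  Cells in tight rare clusters, whose distance profile jumps
sharply once their few true neighbors are exhausted, automatically get small
k_i; cells inside abundant clusters with slowly growing distances keep
k_i = K_max.  The directed adaptive graph is then reweighted by the Jaccard
similarity of neighbor sets (shared-nearest-neighbor graph) for robustness to
noise, and pruned at a small threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .preprocess import EmbeddingMatrix

__all__ = [
    "NeighborTable",
    "AdaptiveGraphConfig",
    "AdaptiveKNNGraph",
    "SNNGraph",
    "compute_neighbor_table",
    "cutoff_distance",
    "adaptive_k",
    "build_adaptive_graph",
    "build_fixed_graph",
    "snn_jaccard",
]

DEFAULT_PRUNE = 1.0 / 15.0  # Seurat SNN pruning convention


@dataclass
class NeighborTable:
    """Per-cell K_max nearest neighbors with ascending Euclidean distances."""

    indices: np.ndarray  # (n_cells, K_max) int
    distances: np.ndarray  # (n_cells, K_max), rows non-decreasing
    K_max: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=float)
        n, k = self.indices.shape
        if self.distances.shape != (n, k) or k != self.K_max:
            raise ValueError("indices/distances shape mismatch with K_max")
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("a cell appears in its own neighbor row")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise ValueError("distances rows must be non-decreasing")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class AdaptiveGraphConfig:
    """Hyperparameters of the adaptive graph.

    delta (default -0.5) controls sensitivity to local distance change; the
    pruning threshold (default 1/15) removes weak SNN edges.
    """

    K_max: int = 20
    delta: float = -0.5
    prune: float = DEFAULT_PRUNE

    def __post_init__(self) -> None:
        if self.delta > 0:
            raise ValueError("delta must be <= 0")
        if self.K_max < 2:
            raise ValueError("K_max must be >= 2")
        if not (0.0 <= self.prune < 1.0):
            raise ValueError("prune must lie in [0, 1)")


@dataclass
class AdaptiveKNNGraph:
    """Directed graph: cell i -> its k_i chosen nearest neighbors."""

    adjacency: sp.csr_matrix  # binary, directed
    k_per_cell: np.ndarray
    config: Optional[AdaptiveGraphConfig] = None

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SNNGraph:
    """Symmetric weighted graph of Jaccard neighbor-set overlaps."""

    weights: sp.csr_matrix  # symmetric, weights in (prune, 1], zero diagonal
    prune: float = DEFAULT_PRUNE

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


def compute_neighbor_table(
    embedding: EmbeddingMatrix, K_max: int = 20, chunk_size: int = 1024
) -> NeighborTable:
    """Exact Euclidean K_max-nearest neighbors for every cell.

    Brute-force pairwise distances, processed in row chunks; the self-distance
    is masked out and ties are broken by the smaller cell index (stable sort),
    so the result is fully deterministic even with duplicated coordinates.
    """
    X = embedding.coords
    n = X.shape[0]
    if K_max >= n:
        raise ValueError(f"K_max={K_max} must be < n_cells={n}")
    indices = np.empty((n, K_max), dtype=np.int64)
    distances = np.empty((n, K_max), dtype=float)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        D = cdist(X[start:stop], X)
        D[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(D, axis=1, kind="stable")[:, :K_max]
        indices[start:stop] = order
        distances[start:stop] = np.take_along_axis(D, order, axis=1)
    return NeighborTable(indices=indices, distances=distances, K_max=K_max)


def cutoff_distance(sorted_distances: np.ndarray, delta: float) -> float:
    """Closed-form per-cell distance cutoff.

    cutoff = ( sum_l sqrt(d_l) / (K_max - 1 - delta) )^2 over the cell's
    K_max sorted neighbor distances; strictly increasing in delta (toward 0).
    """
    d = np.asarray(sorted_distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if delta > 0:
        raise ValueError("delta must be <= 0")
    k_max = d.shape[-1]
    return float((np.sqrt(d).sum() / (k_max - 1 - delta)) ** 2)


def adaptive_k(sorted_distances: np.ndarray, delta: float) -> int:
    """Per-cell neighbor count: how many sorted distances fall below cutoff.

    Equivalent, on sorted distances, to the piecewise rule "k = K_max if
    d_Kmax < cutoff, else the largest j with d_j < cutoff and
    d_{j+1} >= cutoff".  When even the nearest neighbor is at or beyond the
    cutoff the count is floored at 1 so no cell is isolated.
    """
    d = np.asarray(sorted_distances, dtype=float)
    cut = cutoff_distance(d, delta)
    k = int((d < cut).sum())
    return max(1, min(k, d.shape[-1]))


def _adaptive_k_vector(distances: np.ndarray, delta: float) -> np.ndarray:
    """Vectorized adaptive_k over a (n_cells, K_max) distance matrix."""
    if np.any(distances < 0):
        raise ValueError("distances must be non-negative")
    k_max = distances.shape[1]
    cut = (np.sqrt(distances).sum(axis=1) / (k_max - 1 - delta)) ** 2
    k = (distances < cut[:, None]).sum(axis=1)
    return np.clip(k, 1, k_max).astype(np.int64)


def _graph_from_k(table: NeighborTable, k_per_cell: np.ndarray) -> sp.csr_matrix:
    n, k_max = table.indices.shape
    keep = np.arange(k_max)[None, :] < k_per_cell[:, None]
    rows = np.repeat(np.arange(n), k_per_cell)
    cols = table.indices[keep]
    data = np.ones(cols.shape[0], dtype=np.int8)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_adaptive_graph(
    table: NeighborTable, config: Optional[AdaptiveGraphConfig] = None
) -> AdaptiveKNNGraph:
    """Keep, for each cell, its k_i = adaptive_k(distances_i, delta) nearest
    neighbors."""
    config = config or AdaptiveGraphConfig(K_max=table.K_max)
    if config.K_max != table.K_max:
        raise ValueError(
            f"config.K_max={config.K_max} does not match table.K_max={table.K_max}"
        )
    k_per_cell = _adaptive_k_vector(table.distances, config.delta)
    return AdaptiveKNNGraph(
        adjacency=_graph_from_k(table, k_per_cell),
        k_per_cell=k_per_cell,
        config=config,
    )


def build_fixed_graph(table: NeighborTable, k: int = 20) -> AdaptiveKNNGraph:
    """Traditional fixed-k KNN graph: every cell keeps exactly k neighbors."""
    if k > table.K_max:
        raise ValueError(f"k={k} exceeds table K_max={table.K_max}")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_per_cell = np.full(table.n_cells, k, dtype=np.int64)
    return AdaptiveKNNGraph(
        adjacency=_graph_from_k(table, k_per_cell),
        k_per_cell=k_per_cell,
        config=None,
    )


def snn_jaccard(graph: AdaptiveKNNGraph, prune: float = DEFAULT_PRUNE) -> SNNGraph:
    """Shared-nearest-neighbor reweighting of a directed KNN graph.

    For every pair (i, j) connected in the union of directed edges, the weight
    is the Jaccard similarity |N(i) & N(j)| / |N(i) | N(j)| of the retained
    neighbor sets, each set including the cell itself.  Edges with weight
    <= prune are removed; the result is symmetric with zero diagonal.
    """
    if not (0.0 <= prune < 1.0):
        raise ValueError("prune must lie in [0, 1)")
    n = graph.n_cells
    A = (graph.adjacency + sp.eye(n, format="csr", dtype=np.int8)).astype(np.int8)
    A.data[:] = 1
    sizes = np.asarray(A.sum(axis=1)).ravel()

    # candidate pairs: union of directed edges, symmetrized, no self-loops
    mask = graph.adjacency + graph.adjacency.T
    mask.setdiag(0)
    mask.eliminate_zeros()
    mask = (mask > 0).tocoo()

    inter = (A @ A.T).tocsr()
    vals = np.asarray(inter[mask.row, mask.col]).ravel()
    union = sizes[mask.row] + sizes[mask.col] - vals
    jac = vals / union

    keep = jac > prune
    W = sp.csr_matrix(
        (jac[keep], (mask.row[keep], mask.col[keep])), shape=(n, n)
    )
    return SNNGraph(weights=W, prune=prune)
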