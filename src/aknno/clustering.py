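"""Louvain community detection on the SNN graph, grid-search optimization of
the delta hyperparameter, and the end-to-end clustering pipeline.

Delta optimization walks a descending grid of delta values.  At each value
the full adaptive-graph -> SNN -> Louvain chain is run and the number of
communities recorded.  Making delta more negative shrinks every cell's
neighbor cutoff; at some point the graph fragments and the community count
jumps sharply — the signature of overclustering.  The search stops at the
first such jump and returns the delta just before it, balancing sensitivity
(small enough cutoffs to split off rare populations) against specificity
(not shattering abundant populations).
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import numpy as np

from .preprocess import CountMatrix, EmbeddingMatrix, embed_counts
from .graph import (
    DEFAULT_PRUNE,
    AdaptiveGraphConfig,
    NeighborTable,
    SNNGraph,
    build_adaptive_graph,
    build_fixed_graph,
    compute_neighbor_table,
    snn_jaccard,
)

logger = logging.getLogger("aknno")

__all__ = [
    "ClusteringResult",
    "DeltaSearchTrace",
    "DEFAULT_DELTA_GRID",
    "louvain_cluster",
    "find_jump",
    "optimize_delta",
    "run_aknno",
]

#: default delta search grid: 0.0, -0.5, ..., -5.0
DEFAULT_DELTA_GRID = tuple(-0.5 * i for i in range(11))


@dataclass
class ClusteringResult:
    """Cell -> community assignment plus the configuration that produced it."""

    labels: np.ndarray  # community id per cell, 0..n_communities-1
    resolution: float
    delta_used: Optional[float]  # None for the fixed-k baseline
    seed: int
    n_communities: int
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """Deterministic serialized form (sorted keys, labels inline)."""
        payload = {
            "labels": [int(x) for x in self.labels],
            "resolution": self.resolution,
            "delta_used": self.delta_used,
            "seed": self.seed,
            "n_communities": self.n_communities,
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, default=str)


@dataclass
class DeltaSearchTrace:
    """Record of the delta grid search up to the stopping point."""

    grid: list  # delta values actually evaluated, descending
    n_communities_per_delta: list
    chosen_delta: float
    jump_index: Optional[int]  # position where the stop rule fired

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.n_communities_per_delta):
            raise ValueError("trace lists must have equal length")


def _contiguous_labels(membership: Sequence[int]) -> np.ndarray:
    """Relabel community ids to 0..C-1 in order of first occurrence."""
    out = np.empty(len(membership), dtype=np.int64)
    mapping: dict = {}
    for i, c in enumerate(membership):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def louvain_cluster(
    snn: SNNGraph, resolution: float = 0.8, seed: int = 0
) -> ClusteringResult:
    """Louvain modularity clustering of the weighted SNN graph.

    Maximizes resolution-parameterized modularity (Reichardt-Bornholdt
    configuration null model).  The run is seeded and single-threaded, so the
    same (graph, resolution, seed) always yields identical labels; isolated
    vertices become singleton communities.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = snn.n_cells
    if n == 0:
        raise ValueError("empty graph")
    coo = snn.weights.tocoo()
    upper = coo.row < coo.col
    edges = list(zip(coo.row[upper].tolist(), coo.col[upper].tolist()))
    weights = coo.data[upper].tolist()
    g = ig.Graph(n=n, edges=edges)

    state = random.getstate()
    random.seed(seed)
    try:
        part = g.community_multilevel(
            weights=weights if edges else None, resolution=resolution
        )
    finally:
        random.setstate(state)

    labels = _contiguous_labels(part.membership)
    return ClusteringResult(
        labels=labels,
        resolution=resolution,
        delta_used=None,
        seed=seed,
        n_communities=int(labels.max()) + 1,
        provenance={"prune": snn.prune},
    )


def find_jump(
    n_communities: Sequence[int], min_abs: int = 5, min_ratio: float = 1.5
) -> Optional[int]:
    """First index t where the community count jumps rapidly.

    Fires when the increase over the previous grid point is at least
    ``min_abs`` communities AND at least a factor ``min_ratio`` — both an
    absolute and a proportional criterion, so the rule behaves sensibly on
    small and large datasets alike.  Returns None if no jump occurs.
    """
    for t in range(1, len(n_communities)):
        prev, cur = n_communities[t - 1], n_communities[t]
        if cur - prev >= min_abs and cur / max(prev, 1) >= min_ratio:
            return t
    return None


def optimize_delta(
    table: NeighborTable,
    grid: Sequence[float] = DEFAULT_DELTA_GRID,
    resolution: float = 0.8,
    prune: float = DEFAULT_PRUNE,
    seed: int = 0,
    jump_min_abs: int = 5,
    jump_min_ratio: float = 1.5,
) -> DeltaSearchTrace:
    """Grid-search delta: stop just before the community count explodes.

    Evaluates delta values in the given strictly decreasing order, running
    adaptive graph -> SNN -> Louvain at each, and returns the delta preceding
    the first rapid increase in community count.  If no jump fires, the most
    negative grid value is chosen; a single-element grid returns that value.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty delta grid")
    if any(d > 0 for d in grid):
        raise ValueError("all grid values must be <= 0")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly decreasing")

    counts: list = []
    evaluated: list = []
    jump_index: Optional[int] = None
    for t, delta in enumerate(grid):
        cfg = AdaptiveGraphConfig(K_max=table.K_max, delta=delta, prune=prune)
        snn = snn_jaccard(build_adaptive_graph(table, cfg), prune)
        res = louvain_cluster(snn, resolution, seed)
        evaluated.append(delta)
        counts.append(res.n_communities)
        logger.info("delta=%.3g -> %d communities", delta, res.n_communities)
        if t >= 1 and find_jump(counts[t - 1 : t + 1], jump_min_abs, jump_min_ratio):
            jump_index = t
            break

    if jump_index is not None:
        chosen = grid[jump_index - 1]
    else:
        chosen = grid[len(evaluated) - 1]
    return DeltaSearchTrace(
        grid=evaluated,
        n_communities_per_delta=counts,
        chosen_delta=chosen,
        jump_index=jump_index,
    )


def run_aknno(
    counts: Optional[CountMatrix] = None,
    embedding: Optional[EmbeddingMatrix] = None,
    config: Optional[AdaptiveGraphConfig] = None,
    resolution: float = 0.8,
    optimize: bool = False,
    seed: int = 0,
    grid: Sequence[float] = DEFAULT_DELTA_GRID,
    fixed_k: Optional[int] = None,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    min_spot_fraction: Optional[float] = None,
    scale_total: float = 1e4,
    n_hvg: int = 2000,
    n_pcs: int = 50,
) -> ClusteringResult:
    """End-to-end clustering: preprocessing (if raw counts are given),
    neighbor search, optional delta optimization, adaptive (or fixed-k
    baseline) graph, SNN reweighting, and Louvain community detection.

    Exactly one of ``counts`` / ``embedding`` must be supplied.  With
    ``fixed_k`` set, the traditional fixed-k KNN baseline graph is used
    instead of the adaptive one and ``delta_used`` is None.  Reruns with the
    same inputs and seed reproduce the labels exactly.
    """
    if (counts is None) == (embedding is None):
        raise ValueError("supply exactly one of counts or embedding")
    config = config or AdaptiveGraphConfig()
    provenance: dict = {
        "resolution": resolution,
        "seed": seed,
        "K_max": config.K_max,
        "prune": config.prune,
        "mode": "fixed_knn" if fixed_k is not None else "aknno",
    }

    if counts is not None:
        logger.info("preprocess: %d cells x %d genes", counts.n_cells, counts.n_genes)
        try:
            embedding = embed_counts(
                counts,
                min_genes_per_cell=min_genes_per_cell,
                min_cells_per_gene=min_cells_per_gene,
                min_spot_fraction=min_spot_fraction,
                scale_total=scale_total,
                n_hvg=n_hvg,
                n_pcs=n_pcs,
            )
        except Exception as exc:
            raise RuntimeError(f"preprocess stage failed: {exc}") from exc
        provenance["preprocess"] = embedding.provenance.get("pca", {})

    try:
        table = compute_neighbor_table(embedding, config.K_max)
    except Exception as exc:
        raise RuntimeError(f"neighbor stage failed: {exc}") from exc
    logger.info("neighbor table: %d cells, K_max=%d", table.n_cells, table.K_max)

    if fixed_k is not None:
        knn = build_fixed_graph(table, fixed_k)
        delta_used: Optional[float] = None
        provenance["fixed_k"] = fixed_k
    else:
        delta_used = config.delta
        if optimize:
            trace = optimize_delta(
                table, grid, resolution, config.prune, seed
            )
            delta_used = trace.chosen_delta
            provenance["delta_search"] = {
                "grid": trace.grid,
                "n_communities": trace.n_communities_per_delta,
                "jump_index": trace.jump_index,
            }
        cfg = AdaptiveGraphConfig(
            K_max=config.K_max, delta=delta_used, prune=config.prune
        )
        knn = build_adaptive_graph(table, cfg)
        provenance["k_per_cell_mean"] = float(knn.k_per_cell.mean())

    snn = snn_jaccard(knn, config.prune)
    result = louvain_cluster(snn, resolution, seed)
    logger.info("louvain: %d communities at r=%.2f", result.n_communities, resolution)
    result.delta_used = delta_used
    provenance.update(result.provenance)
    result.provenance = provenance
    result.provenance["cell_ids"] = list(map(str, embedding.cell_ids))
    return result
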