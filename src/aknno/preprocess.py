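"""Expression preprocessing: QC filtering, library-size normalization,
highly-variable-gene selection and PCA embedding.

The pipeline mirrors the standard Seurat-style workflow for UMI count data:
cells expressing fewer than ``min_genes_per_cell`` genes and genes detected in
fewer than ``min_cells_per_gene`` cells are removed, counts are scaled to a
common library size (default 10,000) and log1p-transformed, the most variable
genes are chosen by a variance-stabilizing (vst) mean-variance fit on the raw
counts, and cells are embedded by PCA on the per-gene standardized,
clipped log-normalized data.  All downstream neighbor distances are Euclidean
in this embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "CountMatrix",
    "EmbeddingMatrix",
    "filter_cells_genes",
    "normalize_log",
    "select_hvg_vst",
    "pca_embed",
    "embed_counts",
]


@dataclass
class CountMatrix:
    """A cells x genes expression matrix with identifiers.

    ``values`` holds raw (or, after :func:`normalize_log`, log-normalized)
    non-negative expression; ``labels`` optionally carries a per-cell
    ground-truth type annotation, e.g. for simulated data.
    """

    values: np.ndarray  # (n_cells, n_genes), non-negative
    cell_ids: np.ndarray  # (n_cells,) unique strings
    gene_ids: np.ndarray  # (n_genes,) unique strings
    labels: Optional[np.ndarray] = None  # (n_cells,) cell-type annotation
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match row count")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match column count")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != n_cells:
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Return a copy restricted to the given boolean/index masks."""
        cell_mask = slice(None) if cell_mask is None else cell_mask
        gene_mask = slice(None) if gene_mask is None else gene_mask
        return CountMatrix(
            values=self.values[cell_mask][:, gene_mask],
            cell_ids=self.cell_ids[cell_mask],
            gene_ids=self.gene_ids[gene_mask],
            labels=None if self.labels is None else self.labels[cell_mask],
            provenance=dict(self.provenance),
        )


@dataclass
class EmbeddingMatrix:
    """A cells x components real-valued embedding (PCA coordinates)."""

    coords: np.ndarray  # (n_cells, n_components)
    cell_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding needs at least 2 components")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match embedding rows")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def filter_cells_genes(
    counts: CountMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    min_spot_fraction: Optional[float] = None,
) -> CountMatrix:
    """Remove low-complexity cells, then rarely detected genes.

    A cell is kept iff it expresses (count > 0) at least ``min_genes_per_cell``
    genes; a gene is kept iff it is detected in at least ``min_cells_per_gene``
    of the retained cells and, when ``min_spot_fraction`` is given (spatial
    data), in at least that fraction of retained spots.  Both thresholds are
    inclusive (>=), i.e. strictly fewer detections mean removal.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("filter thresholds must be >= 0")
    if min_spot_fraction is not None and not (0.0 <= min_spot_fraction <= 1.0):
        raise ValueError("min_spot_fraction must lie in [0, 1]")

    detected = counts.values > 0
    cell_mask = detected.sum(axis=1) >= min_genes_per_cell
    if not cell_mask.any():
        raise ValueError("no cells survive filters")

    detected = detected[cell_mask]
    gene_mask = detected.sum(axis=0) >= min_cells_per_gene
    if min_spot_fraction is not None:
        frac = detected.sum(axis=0) / detected.shape[0]
        gene_mask &= frac >= min_spot_fraction
    if not gene_mask.any():
        raise ValueError("no genes survive filters")

    out = counts.subset(cell_mask, gene_mask)
    out.provenance["filter"] = {
        "min_genes_per_cell": min_genes_per_cell,
        "min_cells_per_gene": min_cells_per_gene,
        "min_spot_fraction": min_spot_fraction,
        "order": "cells_then_genes",
        "n_cells_kept": int(cell_mask.sum()),
        "n_genes_kept": int(gene_mask.sum()),
    }
    return out


def normalize_log(counts: CountMatrix, scale_total: float = 1e4) -> CountMatrix:
    """Library-size normalize each cell to ``scale_total`` then log1p.

    Each cell's counts are divided by its total and multiplied by
    ``scale_total``, so pre-log per-cell sums all equal ``scale_total``.
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = counts.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell '{counts.cell_ids[zero[0]]}' has zero total counts; "
            "filter cells before normalizing"
        )
    scaled = counts.values / totals[:, None] * scale_total
    out = CountMatrix(
        values=np.log1p(scaled),
        cell_ids=counts.cell_ids,
        gene_ids=counts.gene_ids,
        labels=counts.labels,
        provenance=dict(counts.provenance),
    )
    out.provenance["normalize"] = {"scale_total": scale_total, "log1p": True}
    return out


def _vst_standardized_variance(raw: np.ndarray, loess_span: float = 0.3) -> np.ndarray:
    """Per-gene standardized variance from the vst mean-variance trend.

    Fits expected log10(variance) as a smooth function of log10(mean) on raw
    counts (local linear regression, span 0.3), standardizes each gene by the
    fitted standard deviation with per-value clipping at sqrt(n_cells), and
    returns the variance of the clipped standardized values.  Zero-variance
    genes get standardized variance 0 so they always rank last.
    """
    n_cells = raw.shape[0]
    mean = raw.mean(axis=0)
    var = raw.var(axis=0, ddof=1)
    std_var = np.zeros(raw.shape[1])
    usable = (var > 0) & (mean > 0)
    if not usable.any():
        return std_var

    lx = np.log10(mean[usable])
    ly = np.log10(var[usable])
    if np.unique(lx).size < 2:
        fitted = ly  # degenerate trend: expected variance = observed
    else:
        fitted = lowess(ly, lx, frac=loess_span, return_sorted=False)
    sd_expected = np.sqrt(10.0 ** fitted)

    clip = np.sqrt(n_cells)
    z = (raw[:, usable] - mean[usable]) / sd_expected
    np.minimum(z, clip, out=z)
    # Seurat convention: variance of clipped z-scores about the (zero) mean.
    std_var[usable] = (z ** 2).sum(axis=0) / (n_cells - 1)
    return std_var


def select_hvg_vst(counts: CountMatrix, n_hvg: int = 2000) -> list:
    """Return the ``n_hvg`` most highly variable gene ids (vst method).

    ``counts`` must hold raw counts — the mean-variance trend is defined on
    the raw scale.  Ties are broken by gene order for determinism.
    """
    if n_hvg > counts.n_genes:
        raise ValueError(
            f"n_hvg={n_hvg} exceeds gene count {counts.n_genes}"
        )
    std_var = _vst_standardized_variance(counts.values)
    order = np.argsort(-std_var, kind="stable")
    return [counts.gene_ids[i] for i in order[:n_hvg]]


def pca_embed(
    counts: CountMatrix,
    hvg: Sequence,
    n_pcs: int = 50,
    clip: float = 10.0,
) -> EmbeddingMatrix:
    """Project cells onto the top ``n_pcs`` principal components.

    Genes are restricted to ``hvg``, each centered and scaled to unit
    variance with values clipped at ``+clip`` (Seurat scaling convention),
    then decomposed by SVD.  The sign of each component is fixed so that its
    largest-magnitude gene loading is positive, making the embedding
    deterministic and invariant to cell-order permutation up to row order.
    """
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in hvg if g not in gene_pos]
    if missing:
        raise ValueError(f"hvg genes not present in matrix: {missing[:5]}")
    idx = [gene_pos[g] for g in hvg]
    if n_pcs > min(counts.n_cells, len(idx)):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_cells={counts.n_cells}, n_hvg={len(idx)})"
        )

    X = counts.values[:, idx]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    np.minimum(Z, clip, out=Z)

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = S.max() * max(Z.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    k = min(n_pcs, rank)
    degenerate = k < n_pcs
    if degenerate:
        warnings.warn(
            f"requested {n_pcs} components but matrix rank is {rank}; "
            f"returning {k}",
            RuntimeWarning,
        )

    coords = U[:, :k] * S[:k]
    # deterministic sign: largest-|loading| of each component made positive
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            coords[:, j] = -coords[:, j]

    prov = dict(counts.provenance)
    prov["pca"] = {
        "n_pcs": k,
        "n_pcs_requested": n_pcs,
        "rank_deficient": degenerate,
        "n_hvg": len(idx),
        "clip": clip,
    }
    return EmbeddingMatrix(coords=coords, cell_ids=counts.cell_ids, provenance=prov)


def embed_counts(
    counts: CountMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    min_spot_fraction: Optional[float] = None,
    scale_total: float = 1e4,
    n_hvg: int = 2000,
    n_pcs: int = 50,
) -> EmbeddingMatrix:
    """Full raw-counts -> PCA-embedding pipeline.

    Convenience composition of filtering, normalization, vst HVG selection
    (on the filtered raw counts) and PCA; ``n_hvg``/``n_pcs`` are clamped to
    the post-filter matrix dimensions.
    """
    filtered = filter_cells_genes(
        counts, min_genes_per_cell, min_cells_per_gene, min_spot_fraction
    )
    hvg = select_hvg_vst(filtered, min(n_hvg, filtered.n_genes))
    normed = normalize_log(filtered, scale_total)
    n_pcs = min(n_pcs, normed.n_cells - 1, len(hvg))
    emb = pca_embed(normed, hvg, n_pcs)
    emb.provenance["labels"] = (
        None if filtered.labels is None else list(filtered.labels)
    )
    return emb
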