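"""Readers and writers for the formats the pipeline touches.

Count matrices come in as 10x Genomics MatrixMarket triplets
(matrix.mtx[.gz] + features.tsv/genes.tsv + barcodes.tsv, genes as rows per
the 10x convention, transposed on load) or dense CSV/TSV (cells x genes,
header row = gene ids, first column = cell ids).  Embeddings, cluster
labels, delta-search traces and graphs round-trip through plain-text CSV/TSV,
edge lists and MatrixMarket.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import CountMatrix, EmbeddingMatrix
from .graph import AdaptiveKNNGraph, SNNGraph
from .clustering import ClusteringResult, DeltaSearchTrace

__all__ = [
    "read_10x_mtx",
    "read_dense",
    "read_counts",
    "write_10x_mtx",
    "read_embedding_csv",
    "write_embedding_csv",
    "write_labels_tsv",
    "read_labels_tsv",
    "write_snn_edges",
    "write_k_per_cell",
    "write_trace_tsv",
]

PathLike = Union[str, Path]


def _find(directory: Path, names) -> Path:
    for name in names:
        for candidate in (directory / name, directory / f"{name}.gz"):
            if candidate.exists():
                return candidate
    raise FileNotFoundError(f"none of {names} found in {directory}")


def _read_tsv_column(path: Path, column: int = 0) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return np.array(
            [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()],
            dtype=object,
        )


def read_10x_mtx(directory: PathLike) -> CountMatrix:
    """Load a 10x MatrixMarket triplet directory as a cells x genes matrix."""
    directory = Path(directory)
    mtx = _find(directory, ["matrix.mtx"])
    features = _find(directory, ["features.tsv", "genes.tsv"])
    barcodes = _find(directory, ["barcodes.tsv"])

    m = scipy.io.mmread(str(mtx))  # genes x cells per 10x convention
    values = np.asarray(sp.csr_matrix(m).T.todense(), dtype=float)
    gene_ids = _read_tsv_column(features, column=0)
    cell_ids = _read_tsv_column(barcodes, column=0)
    return CountMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)


def read_dense(path: PathLike, sep: Optional[str] = None) -> CountMatrix:
    """Load a dense cells x genes CSV/TSV (header = gene ids, col 0 = cell ids)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        values=df.to_numpy(dtype=float),
        cell_ids=df.index.to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
    )


def read_counts(path: PathLike) -> CountMatrix:
    """Dispatch: a directory is read as a 10x triplet, a file as dense CSV/TSV."""
    path = Path(path)
    return read_10x_mtx(path) if path.is_dir() else read_dense(path)


def write_10x_mtx(counts: CountMatrix, directory: PathLike) -> None:
    """Write a 10x-style triplet (genes x cells mtx, features, barcodes);
    truth labels, when present, go to truth.tsv alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.values.T)  # genes as rows
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat)
    with open(directory / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(map(str, counts.cell_ids)) + "\n")
    if counts.labels is not None:
        pd.DataFrame(
            {"cell": counts.cell_ids, "label": counts.labels}
        ).to_csv(directory / "truth.tsv", sep="\t", index=False)


def read_embedding_csv(path: PathLike) -> EmbeddingMatrix:
    df = pd.read_csv(path, index_col=0)
    return EmbeddingMatrix(
        coords=df.to_numpy(dtype=float), cell_ids=df.index.to_numpy(dtype=object)
    )


def write_embedding_csv(embedding: EmbeddingMatrix, path: PathLike) -> None:
    pd.DataFrame(
        embedding.coords,
        index=pd.Index(embedding.cell_ids, name="cell"),
        columns=[f"PC{i + 1}" for i in range(embedding.n_components)],
    ).to_csv(path)


def write_labels_tsv(
    result: ClusteringResult, cell_ids, path: PathLike, sidecar: bool = True
) -> None:
    """Write (cell id, cluster) TSV plus a JSON provenance sidecar."""
    path = Path(path)
    pd.DataFrame({"cell": list(cell_ids), "cluster": result.labels}).to_csv(
        path, sep="\t", index=False
    )
    if sidecar:
        meta = {
            "resolution": result.resolution,
            "delta_used": result.delta_used,
            "seed": result.seed,
            "n_communities": result.n_communities,
            "provenance": result.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str)
        )


def read_labels_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snn_edges(snn: SNNGraph, path: PathLike) -> None:
    """Whitespace-delimited weighted edge list (i, j, weight), i < j."""
    coo = snn.weights.tocoo()
    with open(path, "w") as fh:
        for i, j, w in zip(coo.row, coo.col, coo.data):
            if i < j:
                fh.write(f"{i} {j} {w:.10g}\n")


def write_k_per_cell(graph: AdaptiveKNNGraph, cell_ids, path: PathLike) -> None:
    pd.DataFrame({"cell": list(cell_ids), "k": graph.k_per_cell}).to_csv(
        path, sep="\t", index=False
    )


def write_trace_tsv(trace: DeltaSearchTrace, path: PathLike) -> None:
    df = pd.DataFrame(
        {"delta": trace.grid, "n_communities": trace.n_communities_per_delta}
    )
    df["chosen"] = [d == trace.chosen_delta for d in trace.grid]
    df.to_csv(path, sep="\t", index=False)
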