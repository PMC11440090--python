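"""Readers and writers for the delimited / MatrixMarket artifact formats.

All files the pipeline emits can be re-read by the stage that consumes them.
Identity travels by name: expression matrices carry a header of gene names
and a first column of cell ids; label files are two-column (cell id, label);
edge lists are STRING-export-style TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cell_graph import CellAdjacency
from .cluster_metrics import Partition
from .gene_embedding import GeneEmbeddings
from .preprocess import ProcessedExpression, RawExpression

__all__ = [
    "read_expression",
    "write_expression",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_labels",
    "write_labels",
    "write_edges",
    "read_adjacency",
    "write_adjacency",
    "read_gene_embeddings",
    "write_gene_embeddings",
    "read_processed",
    "write_processed",
    "read_history",
    "write_history",
    "write_json",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path: str | Path, labels_path: str | Path | None = None) -> RawExpression:
    """Delimited matrix: header of gene names, first column cell ids."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found")
    raw = RawExpression(
        counts=df.to_numpy(dtype=np.float64),
        gene_names=[str(c) for c in df.columns],
        cell_ids=[str(i) for i in df.index],
        labels=None,
    )
    if labels_path is not None:
        raw.labels = read_labels(labels_path, raw.cell_ids)
    return raw


def write_expression(path: str | Path, raw: RawExpression | ProcessedExpression) -> None:
    if isinstance(raw, ProcessedExpression):
        df = pd.DataFrame(raw.X_c, index=raw.cell_ids, columns=raw.hvg_names)
    else:
        df = pd.DataFrame(raw.counts, index=raw.cell_ids, columns=raw.gene_names)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path | None = None,
) -> RawExpression:
    """MatrixMarket matrix (cells × genes) with one-name-per-line sidecars."""
    mat = spio.mmread(str(mtx_path))
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
    genes = Path(genes_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    raw = RawExpression(counts=counts, gene_names=genes, cell_ids=barcodes, labels=None)
    if labels_path is not None:
        raw.labels = read_labels(labels_path, raw.cell_ids)
    return raw


def write_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    raw: RawExpression,
) -> None:
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(raw.counts))
    Path(genes_path).write_text("\n".join(raw.gene_names) + "\n")
    Path(barcodes_path).write_text("\n".join(raw.cell_ids) + "\n")


def read_labels(path: str | Path, cell_ids: list[str]) -> np.ndarray:
    """Two-column file (cell id, integer label), any order, must cover all cells."""
    path = Path(path)
    mapping: dict[str, int] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 columns")
        if ln == 1 and parts[1].lower() in {"label", "cluster"}:
            continue
        mapping[parts[0]] = int(parts[1])
    known = set(cell_ids)
    unknown = [c for c in mapping if c not in known]
    if unknown:
        raise ValueError(f"{path}: labels for unknown cell ids: {unknown[:5]}")
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"{path}: missing labels for cells: {missing[:5]}")
    return np.array([mapping[c] for c in cell_ids], dtype=np.int64)


def write_labels(path: str | Path, partition: Partition | np.ndarray,
                 cell_ids: list[str]) -> None:
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    with open(path, "w") as fh:
        fh.write("cell_id\tlabel\n")
        for c, l in zip(cell_ids, labels):
            fh.write(f"{c}\t{int(l)}\n")


def write_edges(path: str | Path, edges: list[tuple]) -> None:
    """STRING-style TSV: protein1, protein2, combined_score (0-1 scale)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for row in edges:
            if len(row) == 2:
                fh.write(f"{row[0]}\t{row[1]}\n")
            else:
                fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\n")


def write_adjacency(path: str | Path, adj: CellAdjacency) -> None:
    spio.mmwrite(str(path), sparse.csr_matrix(adj.A_c), field="integer")


def read_adjacency(path: str | Path, k: int = 0) -> CellAdjacency:
    mat = spio.mmread(str(path))
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
    return CellAdjacency(A_c=dense, k=k)


def write_gene_embeddings(path: str | Path, emb: GeneEmbeddings) -> None:
    df = pd.DataFrame(emb.X_g, index=emb.hvg_names)
    df.insert(0, "matched", emb.matched_mask.astype(int))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_embeddings(path: str | Path) -> GeneEmbeddings:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    matched = df.pop("matched").to_numpy(dtype=bool)
    return GeneEmbeddings(
        X_g=df.to_numpy(dtype=np.float64),
        hvg_names=[str(i) for i in df.index],
        matched_mask=matched,
    )


def write_processed(path: str | Path, x: ProcessedExpression) -> None:
    write_expression(path, x)


def read_processed(path: str | Path, labels_path: str | Path | None = None) -> ProcessedExpression:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    x = ProcessedExpression(
        X_c=df.to_numpy(dtype=np.float64),
        hvg_names=[str(c) for c in df.columns],
        cell_ids=[str(i) for i in df.index],
    )
    if labels_path is not None:
        x.labels = read_labels(labels_path, x.cell_ids)
    return x


def write_history(path: str | Path, history) -> None:
    n = history.n_epochs
    df = pd.DataFrame(
        {
            "epoch": np.arange(n),
            "phase": history.phase,
            "L_r": history.L_r,
            "L_c": history.L_c,
            "L_total": history.L_total,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_history(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
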