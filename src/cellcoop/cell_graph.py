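"""Pearson-correlation KNN graph over cells."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ProcessedExpression

__all__ = ["CorrelationMatrix", "CellAdjacency", "pearson_matrix", "knn_adjacency"]


@dataclass
class CorrelationMatrix:
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        n, m = self.P.shape
        if n != m:
            raise ValueError("correlation matrix must be square")

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class CellAdjacency:
    """Binary symmetric KNN adjacency with zero diagonal."""

    A_c: np.ndarray
    k: int

    def __post_init__(self):
        self.A_c = np.asarray(self.A_c, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.A_c.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.A_c[i])


def pearson_matrix(x: ProcessedExpression | np.ndarray) -> CorrelationMatrix:
    """Pairwise Pearson correlation between cell rows."""
    mat = x.X_c if isinstance(x, ProcessedExpression) else np.asarray(x, dtype=np.float64)
    sd = mat.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        if isinstance(x, ProcessedExpression):
            names = [x.cell_ids[i] for i in flat]
        else:
            names = flat.tolist()
        raise ValueError(f"zero-variance cells (correlation undefined): {names}")
    P = np.corrcoef(mat)
    np.fill_diagonal(P, 1.0)
    return CorrelationMatrix(P=np.clip(P, -1.0, 1.0))


def knn_adjacency(p: CorrelationMatrix, k: int = 15) -> CellAdjacency:
    """Connect each cell to its k most correlated cells, symmetrized by union.

    Ties in correlation break toward the lower cell index. Self-edges are
    never created.
    """
    n = p.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    A = np.zeros((n, n))
    sim = p.P.copy()
    np.fill_diagonal(sim, -np.inf)
    for i in range(n):
        # stable sort on -sim -> equal correlations resolve to lower index
        order = np.argsort(-sim[i], kind="stable")
        A[i, order[:k]] = 1.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return CellAdjacency(A_c=A, k=k)
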