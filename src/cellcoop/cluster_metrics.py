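"""Final k-means assignment and label-based evaluation (ARI / NMI)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

__all__ = ["Partition", "KMeansResult", "kmeans_cluster", "ari", "nmi"]


@dataclass
class Partition:
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a nonempty 1-D vector")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k_observed(self) -> int:
        return np.unique(self.labels).size


@dataclass
class KMeansResult:
    partition: Partition
    centers: np.ndarray
    inertia: float
    inertia_trace: list[float]


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300,
           tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # repair empty clusters: steal the point farthest from its center
        for j in range(k):
            if not np.any(labels == j):
                far = d2[np.arange(X.shape[0]), labels].argmax()
                labels[far] = j
                d2[far, :] = np.inf
                d2[far, j] = 0.0
        inertia = float(d2[np.arange(X.shape[0]), labels].sum())
        trace.append(inertia)
        new_centers = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
        shift = float(((new_centers - centers) ** 2).sum())
        centers = new_centers
        if shift <= tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    trace.append(inertia)
    return labels, centers, inertia, trace


def kmeans_cluster(Z: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 20) -> KMeansResult:
    """Lloyd's algorithm with k-means++ seeding; best of ``n_restarts``."""
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} points")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(n_restarts):
        init = _kmeanspp(Z, k, rng)
        labels, centers, inertia, trace = _lloyd(Z, init)
        if best is None or inertia < best.inertia:
            best = KMeansResult(
                partition=Partition(labels=labels),
                centers=centers,
                inertia=inertia,
                inertia_trace=trace,
            )
    assert best is not None
    return best


def _contingency(truth: Partition, pred: Partition) -> np.ndarray:
    if truth.n != pred.n:
        raise ValueError(f"partition lengths differ: {truth.n} vs {pred.n}")
    _, ti = np.unique(truth.labels, return_inverse=True)
    _, pi = np.unique(pred.labels, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def ari(truth: Partition, pred: Partition) -> float:
    """Adjusted Rand index from the contingency table's pair counts."""
    table = _contingency(truth, pred)
    n = truth.n
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    pairs = comb(n, 2)
    expected = sum_a * sum_b / pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def nmi(truth: Partition, pred: Partition) -> float:
    """Normalized mutual information with the arithmetic-mean denominator.

    Natural-log entropies; both partitions constant is defined as 0.
    """
    table = _contingency(truth, pred).astype(np.float64)
    n = float(truth.n)
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    pos = pij > 0
    mi = float((pij[pos] * np.log(pij[pos] / np.outer(pi, pj)[pos])).sum())
    h_u = float(-(pi[pi > 0] * np.log(pi[pi > 0])).sum())
    h_v = float(-(pj[pj > 0] * np.log(pj[pj > 0])).sum())
    denom = (h_u + h_v) / 2.0
    if denom == 0:
        return 0.0
    return float(mi / denom)
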