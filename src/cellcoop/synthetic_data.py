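"""Synthetic fixtures: clustered counts plus a module-structured gene graph.

Genes are partitioned into modules; each cell cluster up-shifts its own
subset of modules, so modules are simultaneously co-expression blocks and
planted communities of the gene graph. Counts are rounded exp-of-Gaussian
draws with independent dropout zeroing — enough structure for end-to-end
testing without claiming a realistic count distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RawExpression

__all__ = ["SyntheticSpec", "SyntheticDataset", "simulate"]


@dataclass
class SyntheticSpec:
    n: int = 300
    k: int = 3
    d_g: int = 120
    n_gene_modules: int = 6
    separation: float = 2.0
    dropout_rate: float = 0.3
    noise_sd: float = 0.4
    base_log_mean: float = 2.0
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n < 10 * self.k:
            raise ValueError("need n >= 10*k cells")
        if not self.d_g >= self.n_gene_modules >= self.k:
            raise ValueError("require d_g >= n_gene_modules >= k")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class SyntheticDataset:
    raw: RawExpression
    gene_edges: list[tuple[str, str, float]]
    truth_means: np.ndarray  # (k, d_g), count scale
    gene_modules: np.ndarray  # module id per gene


def simulate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a seed-reproducible clustered dataset and matching gene graph."""
    rng = np.random.default_rng(spec.seed)

    gene_names = [f"G{j:04d}" for j in range(spec.d_g)]
    cell_ids = [f"C{i:04d}" for i in range(spec.n)]

    # balanced labels (within +-1), order shuffled
    labels = np.arange(spec.n) % spec.k
    rng.shuffle(labels)

    modules = np.arange(spec.d_g) % spec.n_gene_modules
    # cluster c owns the modules congruent to c mod k
    module_owner = np.arange(spec.n_gene_modules) % spec.k

    # per-gene baseline log-mean with mild variation across genes
    base = spec.base_log_mean + rng.normal(0.0, 0.25, size=spec.d_g)
    log_means = np.tile(base, (spec.k, 1))
    for c in range(spec.k):
        boosted = np.isin(modules, np.flatnonzero(module_owner == c))
        log_means[c, boosted] += spec.separation
    truth_means = np.exp(log_means)

    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n, spec.d_g))
    counts = np.rint(np.exp(log_means[labels] + noise))
    if spec.dropout_rate > 0:
        keep = rng.random((spec.n, spec.d_g)) >= spec.dropout_rate
        counts = counts * keep
    counts = np.maximum(counts, 0.0)

    # planted-partition gene graph over the modules
    edges: list[tuple[str, str, float]] = []
    for a in range(spec.d_g):
        for b in range(a + 1, spec.d_g):
            p = spec.p_in if modules[a] == modules[b] else spec.p_out
            if rng.random() < p:
                conf = float(rng.uniform(0.5, 1.0))
                edges.append((gene_names[a], gene_names[b], round(conf, 3)))

    raw = RawExpression(counts=counts, gene_names=gene_names,
                        cell_ids=cell_ids, labels=labels)
    return SyntheticDataset(raw=raw, gene_edges=edges,
                            truth_means=truth_means, gene_modules=modules)
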