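"""Quality control, normalization and highly-variable-gene selection.

Turns a raw cells × genes count matrix into the log2-scale HVG-restricted
matrix that every downstream stage consumes. The pipeline order is fixed:
quartile-fence QC on per-cell totals, duplicate-gene collapsing (means on the
count scale), median-library-size scaling + log2(x+1), then binned-dispersion
HVG ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawExpression",
    "ProcessedExpression",
    "qc_filter_cells",
    "normalize_log",
    "collapse_duplicate_genes",
    "select_hvgs",
]


@dataclass
class RawExpression:
    """A cells × genes expression matrix with identifiers.

    ``counts`` holds nonnegative values; on input these are raw counts, after
    :func:`normalize_log` they are log2-scale. ``labels`` is an optional
    integer ground-truth vector used only for evaluation.
    """

    counts: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        n, g = self.counts.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length must match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ProcessedExpression:
    """The log2-scale HVG matrix plus bookkeeping."""

    X_c: np.ndarray
    hvg_names: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X_c = np.asarray(self.X_c, dtype=np.float64)
        if len(set(self.hvg_names)) != len(self.hvg_names):
            raise ValueError("hvg_names must be unique")
        if self.X_c.shape[1] != len(self.hvg_names):
            raise ValueError("hvg_names length must match column count")

    @property
    def n(self) -> int:
        return self.X_c.shape[0]

    @property
    def d_g(self) -> int:
        return self.X_c.shape[1]


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    """Q1 and Q3 by linear interpolation between order statistics."""
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def qc_filter_cells(
    raw: RawExpression,
    upper_mult: float = 3.0,
    lower_mult: float = 1.0,
    on: str = "total",
) -> RawExpression:
    """Remove cells whose QC statistic lies outside the quartile fences.

    The statistic is the per-cell total count (``on="total"``, default) or the
    per-cell number of detected genes (``on="detected"``). With quartile
    deviation QD = (Q3 - Q1) / 2, a cell is removed when its statistic exceeds
    Q3 + upper_mult * QD or falls below Q1 - lower_mult * QD.
    """
    if raw.n_cells < 3:
        raise ValueError("need at least 3 cells to compute quartile fences")
    if on == "total":
        stat = raw.counts.sum(axis=1)
    elif on == "detected":
        stat = (raw.counts > 0).sum(axis=1).astype(np.float64)
    else:
        raise ValueError(f"unknown QC statistic {on!r}")
    q1, q3 = _quartiles(stat)
    qd = (q3 - q1) / 2.0
    upper = q3 + upper_mult * qd
    lower = q1 - lower_mult * qd
    keep = (stat <= upper) & (stat >= lower)
    if not keep.any():
        raise ValueError(
            f"QC removed every cell (lower fence {lower:.4g}, upper fence {upper:.4g})"
        )
    return RawExpression(
        counts=raw.counts[keep],
        gene_names=list(raw.gene_names),
        cell_ids=[c for c, k in zip(raw.cell_ids, keep) if k],
        labels=None if raw.labels is None else raw.labels[keep],
    )


def normalize_log(raw: RawExpression) -> RawExpression:
    """Scale each cell to the median library size, then log2(x + 1)."""
    totals = raw.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = [c for c, z in zip(raw.cell_ids, zero) if z]
        raise ValueError(f"cells with zero total counts: {bad}")
    target = float(np.median(totals))
    scaled = raw.counts * (target / totals)[:, None]
    return RawExpression(
        counts=np.log2(scaled + 1.0),
        gene_names=list(raw.gene_names),
        cell_ids=list(raw.cell_ids),
        labels=raw.labels,
    )


def collapse_duplicate_genes(raw: RawExpression) -> RawExpression:
    """Average columns that share a gene name, keeping first-occurrence order."""
    names = raw.gene_names
    if len(set(names)) == len(names):
        return raw
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, name in enumerate(names):
        if name not in groups:
            groups[name] = []
            order.append(name)
        groups[name].append(j)
    cols = [raw.counts[:, groups[name]].mean(axis=1) for name in order]
    return RawExpression(
        counts=np.column_stack(cols),
        gene_names=order,
        cell_ids=list(raw.cell_ids),
        labels=raw.labels,
    )


def dispersion_scores(x_log: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Bin-normalized dispersion per gene.

    Dispersion (variance / mean) is computed on the expm scale (2**x - 1 of
    the log2 values); genes are then grouped into ``n_bins`` equal-frequency
    mean bins and the dispersion is z-scored within each bin. Genes in bins
    with a single member or zero spread receive a score of 0; genes with zero
    mean receive -inf so they rank last.
    """
    expm = np.power(2.0, x_log) - 1.0
    mean = expm.mean(axis=0)
    var = expm.var(axis=0, ddof=1) if expm.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    scores = np.full(mean.shape, -np.inf)
    ok = np.isfinite(disp)
    if not ok.any():
        return scores
    edges = np.quantile(mean[ok], np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, mean, side="left") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        idx = np.where(ok & (bins == b))[0]
        if idx.size == 0:
            continue
        d = disp[idx]
        sd = d.std(ddof=0)
        if idx.size == 1 or sd == 0:
            scores[idx] = 0.0
        else:
            scores[idx] = (d - d.mean()) / sd
    return scores


def select_hvgs(raw: RawExpression, n_top: int = 500, n_bins: int = 20) -> ProcessedExpression:
    """Keep the ``n_top`` genes with the highest binned-dispersion z-score.

    Expects log2-scale input (i.e. :func:`normalize_log` already applied) with
    unique gene names. If fewer than ``n_top`` genes are available, all are
    kept. Retained genes appear in rank order (best first); ties break by
    original column index.
    """
    if n_top < 2:
        raise ValueError("n_top must be at least 2")
    if len(set(raw.gene_names)) != len(raw.gene_names):
        raise ValueError("duplicate gene names: run collapse_duplicate_genes first")
    scores = dispersion_scores(raw.counts, n_bins=n_bins)
    # stable sort on negated scores -> ties keep original column order
    rank = np.argsort(-scores, kind="stable")
    keep = rank[: min(n_top, len(rank))]
    return ProcessedExpression(
        X_c=raw.counts[:, keep],
        hvg_names=[raw.gene_names[j] for j in keep],
        cell_ids=list(raw.cell_ids),
        labels=raw.labels,
        provenance={"n_top": n_top, "n_bins": n_bins, "n_available": raw.n_genes},
    )


def preprocess(
    raw: RawExpression,
    upper_mult: float = 3.0,
    lower_mult: float = 1.0,
    qc_on: str = "total",
    n_top: int = 500,
    n_bins: int = 20,
) -> ProcessedExpression:
    """Full preprocessing chain: QC -> collapse duplicates -> normalize/log -> HVG."""
    n0 = raw.n_cells
    qc = qc_filter_cells(raw, upper_mult=upper_mult, lower_mult=lower_mult, on=qc_on)
    collapsed = collapse_duplicate_genes(qc)
    logged = normalize_log(collapsed)
    out = select_hvgs(logged, n_top=n_top, n_bins=n_bins)
    out.provenance.update(
        {
            "cells_in": n0,
            "cells_removed": n0 - qc.n_cells,
            "upper_mult": upper_mult,
            "lower_mult": lower_mult,
            "qc_on": qc_on,
        }
    )
    return out
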