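"""End-to-end orchestration: preprocess -> graphs -> embeddings -> training
-> k-means -> metrics, with every intermediate artifact written to a run
directory and a manifest recording config hash, seed and variant toggles.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import io as cio
from .cell_graph import knn_adjacency, pearson_matrix
from .cluster_metrics import Partition, ari, kmeans_cluster, nmi
from .config import PipelineConfig
from .coop_model import CoopModel, ModelConfig
from .gene_embedding import WalkConfig, embed_genes, parse_edge_list
from .preprocess import RawExpression, preprocess
from .synthetic_data import SyntheticDataset
from .training import TrainConfig, fit

logger = logging.getLogger("cellcoop")

__all__ = ["run_pipeline", "run_ablation_grid"]


def _walk_config(cfg: PipelineConfig) -> WalkConfig:
    w = cfg.walk
    return WalkConfig(p=w.p, q=w.q, walk_length=w.walk_length,
                      walks_per_node=w.walks_per_node, window=w.window,
                      dim=w.dim, negative_samples=w.negative_samples,
                      epochs=w.epochs, lr=w.lr, seed=cfg.seed)


def run_pipeline(
    cfg: PipelineConfig,
    raw: RawExpression,
    edges_path: str | Path | None,
    out_dir: str | Path,
    variant_name: str = "full",
) -> dict:
    """Execute all stages on an in-memory dataset; returns the metrics dict.

    ``edges_path`` may be None only when the gene branch is disabled
    (``cfg.use_gene_branch = False``), in which case a frozen seeded random
    matrix stands in for the gene embeddings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    pp = cfg.preprocess
    x = preprocess(raw, upper_mult=pp.upper_mult, lower_mult=pp.lower_mult,
                   qc_on=pp.qc_on, n_top=pp.n_top, n_bins=pp.n_bins)
    cio.write_processed(out / "processed.tsv", x)
    logger.info("preprocess: %d cells x %d HVGs (removed %s cells)",
                x.n, x.d_g, x.provenance.get("cells_removed"))

    P = pearson_matrix(x)
    adj = knn_adjacency(P, k=min(cfg.cell_graph.k, x.n - 1))
    cio.write_adjacency(out / "cell_adjacency.mtx", adj)
    logger.info("cell_graph: k=%d, %d edges", adj.k, int(adj.A_c.sum() / 2))

    wcfg = _walk_config(cfg)
    if cfg.use_gene_branch:
        if edges_path is None:
            raise ValueError("edges_path required when the gene branch is enabled")
        graph = parse_edge_list(edges_path, x.hvg_names,
                                min_confidence=cfg.walk.min_confidence,
                                case_fold=cfg.walk.case_fold)
        emb = embed_genes(graph, wcfg)
    else:
        # frozen seeded random gene matrix: same shapes, no graph information
        rng = np.random.default_rng(cfg.seed + 17)
        from .gene_embedding import GeneEmbeddings

        emb = GeneEmbeddings(
            X_g=rng.normal(0.0, 0.1, size=(x.d_g, wcfg.dim)),
            hvg_names=list(x.hvg_names),
            matched_mask=np.zeros(x.d_g, dtype=bool),
        )
    cio.write_gene_embeddings(out / "gene_embeddings.tsv", emb)
    logger.info("gene_embedding: %d/%d HVGs matched, d_e=%d",
                int(emb.matched_mask.sum()), emb.d_g, emb.d_e)

    if cfg.train.k >= 2:
        k = cfg.train.k
    elif x.labels is not None:
        k = int(np.unique(x.labels).size)
    else:
        raise ValueError("cluster count k not set and no labels to infer it from")

    mcfg = ModelConfig(d_g=x.d_g, d_e=emb.d_e, hidden=cfg.model.hidden,
                       d_m=cfg.model.d_m, slope=cfg.model.slope, seed=cfg.seed)
    model = CoopModel.init(mcfg)
    tcfg = TrainConfig(
        total_epochs=cfg.train.total_epochs,
        lr=cfg.train.lr,
        lam=cfg.train.lam if cfg.use_clustering_loss else 0.0,
        warmup_epochs=cfg.train.warmup_epochs,
        p_update_interval=cfg.train.p_update_interval,
        k=k,
        seed=cfg.seed,
    )
    model, head, history = fit(model, x.X_c, adj, emb.X_g, tcfg)
    cio.write_history(out / "history.tsv", history)
    np.savez(out / "checkpoint.npz", **{k_: v for k_, v in model.state_dict().items()
                                        if k_ != "config"})
    logger.info("training: %d epochs, final L_total=%.6g",
                history.n_epochs, history.L_total[-1])

    Z_c = model.encode_cells_t(x.X_c, adj).data
    result = kmeans_cluster(Z_c, k=k, seed=cfg.seed)
    cio.write_labels(out / "predicted_labels.tsv", result.partition, x.cell_ids)

    metrics: dict = {
        "n_cells": x.n,
        "d_g": x.d_g,
        "k": k,
        "variant": variant_name,
        "inertia": result.inertia,
        "runtime_s": round(time.time() - t0, 3),
    }
    if x.labels is not None:
        truth = Partition(x.labels)
        metrics["ari"] = ari(truth, result.partition)
        metrics["nmi"] = nmi(truth, result.partition)
        logger.info("evaluate: ARI=%.4f NMI=%.4f", metrics["ari"], metrics["nmi"])
    cio.write_json(out / "metrics.json", metrics)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "variant": variant_name,
        "use_gene_branch": cfg.use_gene_branch,
        "use_clustering_loss": cfg.use_clustering_loss,
        "config": cfg.to_dict(),
    }
    cio.write_json(out / "manifest.json", manifest)
    return metrics


def run_ablation_grid(
    cfg: PipelineConfig,
    raw: RawExpression,
    edges_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """The 2x2 (gene branch x clustering loss) variant grid.

    Writes one run directory per variant plus an ``ablation.json`` summary of
    ARI/NMI per variant.
    """
    out = Path(out_dir)
    grid = {}
    for use_gene in (False, True):
        for use_closs in (False, True):
            name = f"EG{'on' if use_gene else 'off'}_Lc{'on' if use_closs else 'off'}"
            vcfg = PipelineConfig.from_dict(cfg.to_dict())
            vcfg.use_gene_branch = use_gene
            vcfg.use_clustering_loss = use_closs
            metrics = run_pipeline(vcfg, raw, edges_path, out / name,
                                   variant_name=name)
            grid[name] = metrics
    cio.write_json(out / "ablation.json", grid)
    return grid
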