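"""Gene embeddings from biased random walks on an interaction graph.

Second-order (p, q)-biased walks are sampled on the gene graph and a
skip-gram model with negative sampling is fit to the walk corpus with plain
numpy SGD. The embedding rows are assembled in HVG order; genes without graph
support get a small seeded Gaussian row so downstream shapes never depend on
interaction-database coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "GeneGraph",
    "WalkConfig",
    "GeneEmbeddings",
    "parse_edge_list",
    "transition_distribution",
    "generate_walks",
    "train_skipgram",
    "assemble_gene_embeddings",
    "embed_genes",
]


@dataclass
class GeneGraph:
    """Simple undirected graph over a fixed gene universe.

    Every requested gene is a node even when isolated; self-edges and
    parallel edges are dropped at construction.
    """

    nodes: list[str]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        self.index = {name: i for i, name in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._adj: list[list[int]] = [[] for _ in self.nodes]
        clean = set()
        for u, v in self.edges:
            if u == v:
                continue
            clean.add((min(u, v), max(u, v)))
        self.edges = clean
        for u, v in sorted(self.edges):
            self._adj[u].append(v)
            self._adj[v].append(u)
        for lst in self._adj:
            lst.sort()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, u: int) -> list[int]:
        return self._adj[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])


@dataclass
class WalkConfig:
    """node2vec walk and skip-gram hyperparameters.

    Defaults follow the reference-implementation conventions: p=q=1,
    80-step walks, 10 per node, window 10, 128 dimensions, 5 negative
    samples.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10
    dim: int = 128
    negative_samples: int = 5
    epochs: int = 1
    lr: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.walks_per_node < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("walks_per_node, window and epochs must be >= 1")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.negative_samples < 1:
            raise ValueError("negative_samples must be >= 1")


@dataclass
class GeneEmbeddings:
    """Embedding matrix in HVG row order plus a graph-support mask."""

    X_g: np.ndarray
    hvg_names: list[str]
    matched_mask: np.ndarray

    def __post_init__(self):
        self.X_g = np.asarray(self.X_g, dtype=np.float64)
        if self.X_g.shape[0] != len(self.hvg_names):
            raise ValueError("row count must equal number of HVGs")
        if not np.all(np.isfinite(self.X_g)):
            raise ValueError("non-finite embedding entries")

    @property
    def d_g(self) -> int:
        return self.X_g.shape[0]

    @property
    def d_e(self) -> int:
        return self.X_g.shape[1]


def parse_edge_list(
    path: str | Path,
    hvg_names: list[str],
    min_confidence: float = 0.4,
    case_fold: bool = False,
) -> GeneGraph:
    """Build a :class:`GeneGraph` from a two/three-column edge-list file.

    Columns are tab- or comma-separated: gene A, gene B, optional confidence.
    Confidence is accepted on a 0-1 or 0-1000 scale (auto-detected from the
    file's maximum) and rows below ``min_confidence`` are dropped. Edges are
    kept only when both endpoints are HVGs; every HVG becomes a node even if
    isolated. A header row (non-numeric third column or 'protein'/'gene'
    prefixed names) is skipped.
    """
    path = Path(path)
    fold = (lambda s: s.casefold()) if case_fold else (lambda s: s)
    names = [fold(n) for n in hvg_names]
    graph = GeneGraph(nodes=list(names))
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ValueError(f"cannot read edge list {path}: {exc}") from exc

    rows: list[tuple[str, str, float | None]] = []
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        parts = [p.strip() for p in parts]
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected at least 2 columns")
        score: float | None = None
        if len(parts) >= 3 and parts[2] != "":
            try:
                score = float(parts[2])
            except ValueError:
                if ln == 1:
                    continue  # header
                raise ValueError(f"{path}:{ln}: bad confidence {parts[2]!r}") from None
        if ln == 1 and parts[0].lower() in {"protein1", "gene1", "source", "node1"}:
            continue
        rows.append((fold(parts[0]), fold(parts[1]), score))

    scores = [s for _, _, s in rows if s is not None]
    scale = 1000.0 if scores and max(scores) > 1.0 else 1.0
    edges = set()
    for a, b, s in rows:
        if s is not None and s / scale < min_confidence:
            continue
        if a in graph.index and b in graph.index:
            u, v = graph.index[a], graph.index[b]
            if u != v:
                edges.add((min(u, v), max(u, v)))
    if rows and not edges:
        warnings.warn(
            "no edge matched the HVG set; all genes will be isolated nodes",
            stacklevel=2,
        )
    return GeneGraph(nodes=list(names), edges=edges)


def transition_distribution(
    g: GeneGraph, prev: int, cur: int, cfg: WalkConfig
) -> dict[int, float]:
    """Second-order transition probabilities out of ``cur`` given ``prev``.

    Unnormalized weight for a neighbor v of cur: 1/p when v == prev
    (distance 0 from prev), 1 when v neighbors prev (distance 1), 1/q
    otherwise (distance 2).
    """
    nbrs = g.neighbors(cur)
    if not nbrs:
        raise ValueError(f"node {cur} is isolated; cannot step from it")
    prev_nbrs = set(g.neighbors(prev))
    weights = {}
    for v in nbrs:
        if v == prev:
            w = 1.0 / cfg.p
        elif v in prev_nbrs:
            w = 1.0
        else:
            w = 1.0 / cfg.q
        weights[v] = w
    total = sum(weights.values())
    return {v: w / total for v, w in weights.items()}


def generate_walks(g: GeneGraph, cfg: WalkConfig) -> list[list[int]]:
    """Sample ``walks_per_node`` biased walks from every non-isolated node.

    The first step is uniform over the start node's neighbors; subsequent
    steps follow :func:`transition_distribution`. Reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    walks: list[list[int]] = []
    sources = [u for u in range(g.n_nodes) if g.degree(u) > 0]
    for _ in range(cfg.walks_per_node):
        for u in sources:
            walk = [u]
            nbrs = g.neighbors(u)
            walk.append(nbrs[rng.integers(len(nbrs))])
            while len(walk) < cfg.walk_length:
                dist = transition_distribution(g, walk[-2], walk[-1], cfg)
                nodes = list(dist.keys())
                probs = np.array([dist[v] for v in nodes])
                walk.append(nodes[rng.choice(len(nodes), p=probs)])
            walks.append(walk)
    return walks


def train_skipgram(walks: list[list[int]], cfg: WalkConfig) -> dict[int, np.ndarray]:
    """Skip-gram with negative sampling on a walk corpus (numpy SGD).

    Maximizes log sigma(u_c . v_w) over observed (center, context) pairs plus
    ``negative_samples`` noise contexts drawn from the unigram^0.75
    distribution. Returns a vector per node that appears in >= 1 walk.
    """
    if not walks:
        raise ValueError("need at least one walk")
    vocab = sorted({v for w in walks for v in w})
    pos = {node: i for i, node in enumerate(vocab)}
    nv = len(vocab)
    rng = np.random.default_rng(cfg.seed + 1)

    centers: list[int] = []
    contexts: list[int] = []
    for walk in walks:
        L = len(walk)
        for i, w in enumerate(walk):
            lo = max(0, i - cfg.window)
            hi = min(L, i + cfg.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(pos[w])
                    contexts.append(pos[walk[j]])
    centers = np.array(centers, dtype=np.intp)
    contexts = np.array(contexts, dtype=np.intp)

    counts = np.bincount(contexts, minlength=nv).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()

    W_in = (rng.random((nv, cfg.dim)) - 0.5) / cfg.dim
    W_out = np.zeros((nv, cfg.dim))
    n_pairs = centers.size
    batch = 1024
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            idx = order[s : s + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(nv, size=(idx.size, cfg.negative_samples), p=noise)
            vc = W_in[c]  # (b, d)
            uo = W_out[o]  # (b, d)
            un = W_out[neg]  # (b, k, d)
            # positive pairs
            sp = expit((vc * uo).sum(axis=1))  # sigma(score)
            gp = (sp - 1.0)[:, None]  # d/dscore of -log sigma
            # negative pairs
            sn = expit(np.einsum("bd,bkd->bk", vc, un))
            grad_vc = gp * uo + np.einsum("bk,bkd->bd", sn, un)
            np.add.at(W_in, c, -cfg.lr * grad_vc)
            np.add.at(W_out, o, -cfg.lr * (gp * vc))
            grad_un = sn[:, :, None] * vc[:, None, :]
            np.add.at(W_out, neg.ravel(), -cfg.lr * grad_un.reshape(-1, cfg.dim))
    return {node: W_in[pos[node]].copy() for node in vocab}


def assemble_gene_embeddings(
    vectors: dict[int, np.ndarray],
    hvg_names: list[str],
    cfg: WalkConfig,
) -> GeneEmbeddings:
    """Stack trained vectors in HVG order; fill gaps with seeded small noise.

    ``vectors`` is keyed by node ordinal (= HVG position). Unmatched rows are
    drawn i.i.d. from N(0, 0.01^2) with a generator seeded from ``cfg.seed``,
    so the fallback is reproducible and independent of iteration order.
    """
    d_g = len(hvg_names)
    X = np.empty((d_g, cfg.dim))
    mask = np.zeros(d_g, dtype=bool)
    rng = np.random.default_rng(cfg.seed + 2)
    noise = rng.normal(0.0, 0.01, size=(d_g, cfg.dim))
    for i in range(d_g):
        vec = vectors.get(i)
        if vec is not None:
            X[i] = vec
            mask[i] = True
        else:
            X[i] = noise[i]
    return GeneEmbeddings(X_g=X, hvg_names=list(hvg_names), matched_mask=mask)


def embed_genes(g: GeneGraph, cfg: WalkConfig) -> GeneEmbeddings:
    """Walks -> skip-gram -> row assembly for the graph's node set."""
    walks = generate_walks(g, cfg)
    vectors = train_skipgram(walks, cfg) if walks else {}
    return assemble_gene_embeddings(vectors, g.nodes, cfg)
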