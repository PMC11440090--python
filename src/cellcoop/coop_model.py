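"""Attention-enhanced graph autoencoder with a cooperative gene decoder.

The cell encoder is a stack of single-head graph-attention layers over the
KNN cell graph (self-loops added for attention only); the gene mapper is a
small MLP bringing gene embeddings into the same bottleneck space. Two
decoders close the loop: a sigmoid inner-product reconstruction of the cell
adjacency and a linear product Z_c @ Z_g.T reconstructing the expression
matrix. Clustering structure is imposed with Student-t soft assignments
against trainable centers and a KL loss to a sharpened target distribution.

Plain-numpy functional forms of every operation live alongside the
autodiff-backed :class:`CoopModel`; the two routes are cross-checked in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .cell_graph import CellAdjacency

__all__ = [
    "GatParams",
    "GeneMapperParams",
    "ModelConfig",
    "LatentState",
    "ClusterHead",
    "LossBreakdown",
    "CoopModel",
    "gat_attention",
    "gat_layer",
    "encode_cells",
    "encode_genes",
    "reconstruct_adjacency",
    "cooperative_reconstruction",
    "reconstruction_loss",
    "soft_assignment",
    "target_distribution",
    "clustering_loss",
    "total_loss",
]


@dataclass
class GatParams:
    """One graph-attention layer: projection W, attention vector a."""

    W: np.ndarray  # (in_dim, out_dim)
    a: np.ndarray  # (2 * out_dim,)
    slope: float = 0.2

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.shape != (2 * self.W.shape[1],):
            raise ValueError("attention vector must have length 2*out_dim")


@dataclass
class GeneMapperParams:
    """Dense MLP weights (with biases) for the gene branch."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]


@dataclass
class ModelConfig:
    d_g: int
    d_e: int
    hidden: int = 512
    d_m: int = 256
    slope: float = 0.2
    seed: int = 0


@dataclass
class LatentState:
    """One forward pass: latents and both reconstructions."""

    Z_c: np.ndarray
    Z_g: np.ndarray
    A_hat: np.ndarray
    X_hat: np.ndarray

    @property
    def d_m(self) -> int:
        return self.Z_c.shape[1]


@dataclass
class ClusterHead:
    centers: np.ndarray  # (k, d_m)
    Q: np.ndarray  # (n, k)
    P: np.ndarray  # (n, k)

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass
class LossBreakdown:
    L_r: float
    L_c: float
    lam: float

    @property
    def L_total(self) -> float:
        return self.L_r + self.lam * self.L_c


# --------------------------------------------------------------------------
# numpy functional forms
# --------------------------------------------------------------------------

def _attention_logits(H: np.ndarray, params: GatParams) -> tuple[np.ndarray, np.ndarray]:
    S = H @ params.W
    out_dim = params.W.shape[1]
    f1 = S @ params.a[:out_dim]
    f2 = S @ params.a[out_dim:]
    E = f1[:, None] + f2[None, :]
    return S, np.where(E > 0, E, params.slope * E)


def _self_loop_mask(adj: CellAdjacency | np.ndarray) -> np.ndarray:
    A = adj.A_c if isinstance(adj, CellAdjacency) else np.asarray(adj)
    M = A > 0
    M = M | np.eye(A.shape[0], dtype=bool)
    return M


def gat_attention(H: np.ndarray, params: GatParams, adj: CellAdjacency | np.ndarray) -> np.ndarray:
    """Attention coefficients alpha: dense (n, n), zero outside N(i) + self."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[1] != params.W.shape[0]:
        raise ValueError(
            f"feature dim {H.shape[1]} does not match W input dim {params.W.shape[0]}"
        )
    _, E = _attention_logits(H, params)
    M = _self_loop_mask(adj)
    shifted = np.where(M, E, -np.inf)
    shifted = shifted - shifted.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=1, keepdims=True)


def gat_layer(
    H: np.ndarray,
    params: GatParams,
    adj: CellAdjacency | np.ndarray,
    activation: str = "elu",
) -> np.ndarray:
    """One attention layer: h_i' = act(sum_j alpha_ij W h_j)."""
    alpha = gat_attention(H, params, adj)
    out = alpha @ (np.asarray(H, dtype=np.float64) @ params.W)
    if activation == "elu":
        return np.where(out > 0, out, np.exp(np.minimum(out, 0.0)) - 1.0)
    if activation == "identity":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def encode_cells(
    X: np.ndarray, adj: CellAdjacency | np.ndarray, layers: list[GatParams]
) -> np.ndarray:
    """Stacked GAT layers: ELU between layers, identity at the bottleneck."""
    H = np.asarray(X, dtype=np.float64)
    for i, params in enumerate(layers):
        last = i == len(layers) - 1
        H = gat_layer(H, params, adj, activation="identity" if last else "elu")
    return H


def encode_genes(X_g: np.ndarray, params: GeneMapperParams) -> np.ndarray:
    """MLP on the gene embeddings: ELU hidden layers, identity output."""
    H = np.asarray(X_g, dtype=np.float64)
    n_layers = len(params.weights)
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        H = H @ W + b
        if i < n_layers - 1:
            H = np.where(H > 0, H, np.exp(np.minimum(H, 0.0)) - 1.0)
    return H


def reconstruct_adjacency(Z_c: np.ndarray) -> np.ndarray:
    """A_hat = sigmoid(Z_c @ Z_c.T); symmetric, entries in (0, 1)."""
    G = Z_c @ Z_c.T
    G = (G + G.T) / 2.0  # exact symmetry against fp round-off
    return 1.0 / (1.0 + np.exp(-G))


def cooperative_reconstruction(Z_c: np.ndarray, Z_g: np.ndarray) -> np.ndarray:
    """X_hat = Z_c @ Z_g.T (linear decoder)."""
    if Z_c.shape[1] != Z_g.shape[1]:
        raise ValueError("cell and gene latents must share the bottleneck width")
    return Z_c @ Z_g.T


def reconstruction_loss(
    A: np.ndarray, A_hat: np.ndarray, X: np.ndarray, X_hat: np.ndarray
) -> float:
    """Mean-squared error of both reconstructions, summed."""
    A, A_hat = np.asarray(A, dtype=np.float64), np.asarray(A_hat)
    X, X_hat = np.asarray(X, dtype=np.float64), np.asarray(X_hat)
    if A.shape != A_hat.shape or X.shape != X_hat.shape:
        raise ValueError("shape mismatch between targets and reconstructions")
    return float(np.mean((A - A_hat) ** 2) + np.mean((X - X_hat) ** 2))


def soft_assignment(Z_c: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Student-t (1 dof) soft assignment of each row to each center."""
    Z_c, centers = np.asarray(Z_c), np.asarray(centers)
    if not (np.all(np.isfinite(Z_c)) and np.all(np.isfinite(centers))):
        raise ValueError("non-finite embeddings or centers")
    d2 = ((Z_c[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    q = 1.0 / (1.0 + d2)
    return q / q.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target: p_ij propto q_ij^2 / column frequency."""
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    if np.any(f == 0):
        empty = np.flatnonzero(f == 0).tolist()
        raise ValueError(f"empty soft clusters (zero Q columns): {empty}")
    w = Q ** 2 / f
    return w / w.sum(axis=1, keepdims=True)


def clustering_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) with the 0*log(0/q) = 0 convention."""
    P, Q = np.asarray(P, dtype=np.float64), np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("P and Q shapes differ")
    pos = P > 0
    if np.any(pos & (Q == 0)):
        raise ValueError("infinite divergence: q=0 where p>0")
    terms = np.zeros_like(P)
    terms[pos] = P[pos] * np.log(P[pos] / Q[pos])
    return float(terms.sum())


def total_loss(L_r: float, L_c: float, lam: float = 100.0) -> float:
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return L_r + lam * L_c


# --------------------------------------------------------------------------
# trainable model (autodiff route)
# --------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class CoopModel:
    """The trainable autoencoder: parameters as autodiff leaves.

    Layer widths follow ``ModelConfig``: cell encoder d_g -> hidden -> d_m
    (two GAT layers), gene mapper d_e -> hidden -> d_m. Cluster centers are
    attached by the training loop after warm-up.
    """

    cfg: ModelConfig
    cell_layers: list[tuple[Tensor, Tensor]] = field(default_factory=list)
    gene_weights: list[Tensor] = field(default_factory=list)
    gene_biases: list[Tensor] = field(default_factory=list)
    centers: Tensor | None = None

    @classmethod
    def init(cls, cfg: ModelConfig) -> "CoopModel":
        rng = np.random.default_rng(cfg.seed)
        dims = [cfg.d_g, cfg.hidden, cfg.d_m]
        cell_layers = []
        for din, dout in zip(dims[:-1], dims[1:]):
            W = Tensor(_glorot(rng, (din, dout)), requires_grad=True)
            # attention vector kept as a (2*dout, 1) column for matmul slicing
            a = Tensor(_glorot(rng, (2 * dout, 1)) * 0.1, requires_grad=True)
            cell_layers.append((W, a))
        gdims = [cfg.d_e, cfg.hidden, cfg.d_m]
        gene_weights, gene_biases = [], []
        for din, dout in zip(gdims[:-1], gdims[1:]):
            gene_weights.append(Tensor(_glorot(rng, (din, dout)), requires_grad=True))
            gene_biases.append(Tensor(np.zeros(dout), requires_grad=True))
        return cls(cfg=cfg, cell_layers=cell_layers,
                   gene_weights=gene_weights, gene_biases=gene_biases)

    # ----------------------------------------------------------- parameters
    def parameters(self, include_centers: bool = True) -> list[Tensor]:
        ps: list[Tensor] = []
        for W, a in self.cell_layers:
            ps.extend([W, a])
        ps.extend(self.gene_weights)
        ps.extend(self.gene_biases)
        if include_centers and self.centers is not None:
            ps.append(self.centers)
        return ps

    def attach_centers(self, centers: np.ndarray) -> None:
        self.centers = Tensor(np.asarray(centers, dtype=np.float64), requires_grad=True)

    # -------------------------------------------------------------- forward
    def encode_cells_t(self, X: np.ndarray, adj: CellAdjacency | np.ndarray) -> Tensor:
        M = _self_loop_mask(adj)
        H = Tensor(X)
        n_layers = len(self.cell_layers)
        for i, (W, a) in enumerate(self.cell_layers):
            S = H @ W
            dout = W.shape[1]
            # slice a into its source/target halves via selector matmuls so the
            # gradient flows back into the single attention vector
            a1 = Tensor(np.eye(2 * dout)[:, :dout].T) @ a  # (dout, 1)
            a2 = Tensor(np.eye(2 * dout)[:, dout:].T) @ a
            f1 = S @ a1  # (n, 1)
            f2 = S @ a2
            E = (f1 + f2.T).leaky_relu(self.cfg.slope)  # (n, n)
            alpha = E.masked_row_softmax(M)
            H = alpha @ S
            if i < n_layers - 1:
                H = H.elu()
        return H

    def encode_genes_t(self, X_g: np.ndarray) -> Tensor:
        H = Tensor(X_g)
        n_layers = len(self.gene_weights)
        for i, (W, b) in enumerate(zip(self.gene_weights, self.gene_biases)):
            H = H @ W + b
            if i < n_layers - 1:
                H = H.elu()
        return H

    def forward(self, X: np.ndarray, adj: CellAdjacency | np.ndarray,
                X_g: np.ndarray) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Returns (Z_c, Z_g, A_hat, X_hat) as graph tensors."""
        Z_c = self.encode_cells_t(X, adj)
        Z_g = self.encode_genes_t(X_g)
        G = Z_c @ Z_c.T
        A_hat = G.sigmoid()
        X_hat = Z_c @ Z_g.T
        return Z_c, Z_g, A_hat, X_hat

    def reconstruction_loss_t(self, A: np.ndarray, A_hat: Tensor,
                              X: np.ndarray, X_hat: Tensor) -> Tensor:
        ra = (Tensor(A) - A_hat).square().sum() * (1.0 / A.size)
        rx = (Tensor(X) - X_hat).square().sum() * (1.0 / X.size)
        return ra + rx

    def soft_assignment_t(self, Z_c: Tensor) -> Tensor:
        mu = self.centers
        if mu is None:
            raise RuntimeError("centers not attached; run center initialization first")
        z2 = Z_c.square().sum(axis=1, keepdims=True)  # (n,1)
        m2 = mu.square().sum(axis=1, keepdims=True).T  # (1,k)
        d2 = z2 + m2 - (Z_c @ mu.T) * 2.0
        qu = (d2 + 1.0) ** -1.0
        return qu / qu.sum(axis=1, keepdims=True)

    def clustering_loss_t(self, P: np.ndarray, Q: Tensor) -> Tensor:
        # P is a constant (stop-gradient target)
        logq = Q.log()
        const = float(np.sum(P * np.log(np.maximum(P, 1e-300))))
        return Tensor(const) - (Tensor(P) * logq).sum()

    # --------------------------------------------------------- numpy export
    def latent_state(self, X: np.ndarray, adj: CellAdjacency | np.ndarray,
                     X_g: np.ndarray) -> LatentState:
        Z_c, Z_g, A_hat, X_hat = self.forward(X, adj, X_g)
        return LatentState(Z_c=Z_c.data.copy(), Z_g=Z_g.data.copy(),
                           A_hat=A_hat.data.copy(), X_hat=X_hat.data.copy())

    def cell_params(self) -> list[GatParams]:
        return [GatParams(W=W.data.copy(), a=a.data.ravel().copy(), slope=self.cfg.slope)
                for W, a in self.cell_layers]

    def gene_params(self) -> GeneMapperParams:
        return GeneMapperParams(
            weights=[W.data.copy() for W in self.gene_weights],
            biases=[b.data.copy() for b in self.gene_biases],
        )

    def state_dict(self) -> dict:
        out = {"config": self.cfg.__dict__.copy()}
        for i, (W, a) in enumerate(self.cell_layers):
            out[f"cell_W_{i}"] = W.data.copy()
            out[f"cell_a_{i}"] = a.data.copy()
        for i, (W, b) in enumerate(zip(self.gene_weights, self.gene_biases)):
            out[f"gene_W_{i}"] = W.data.copy()
            out[f"gene_b_{i}"] = b.data.copy()
        if self.centers is not None:
            out["centers"] = self.centers.data.copy()
        return out

    @classmethod
    def from_state_dict(cls, state: dict) -> "CoopModel":
        cfg = ModelConfig(**state["config"])
        model = cls.init(cfg)
        for i, (W, a) in enumerate(model.cell_layers):
            W.data = np.asarray(state[f"cell_W_{i}"], dtype=np.float64)
            a.data = np.asarray(state[f"cell_a_{i}"], dtype=np.float64)
        for i in range(len(model.gene_weights)):
            model.gene_weights[i].data = np.asarray(state[f"gene_W_{i}"], dtype=np.float64)
            model.gene_biases[i].data = np.asarray(state[f"gene_b_{i}"], dtype=np.float64)
        if "centers" in state:
            model.attach_centers(np.asarray(state["centers"]))
        return model
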