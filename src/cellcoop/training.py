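"""Optimization loop: reconstruction warm-up, center seeding, joint training.

The joint phase minimizes L = L_r + lambda * L_c with Adam, recomputing the
target distribution P on a fixed schedule and holding it constant (no
gradient) in between. Cluster centers are trainable parameters after their
k-means initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .cell_graph import CellAdjacency
from .cluster_metrics import Partition, ari, kmeans_cluster
from .coop_model import ClusterHead, CoopModel, target_distribution

__all__ = ["TrainConfig", "TrainHistory", "Adam", "pretrain", "init_centers", "fit"]


@dataclass
class TrainConfig:
    """Hyperparameters for the two-phase schedule.

    Reference defaults (500 epochs at lr 1e-5, lambda 100) target real-data
    sizes; :meth:`desk_profile` is a scaled-down profile for tests and small
    synthetic fixtures.
    """

    total_epochs: int = 500
    lr: float = 1e-5
    lam: float = 100.0
    warmup_epochs: int = 100
    p_update_interval: int = 1
    k: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.total_epochs:
            raise ValueError("warmup_epochs must be < total_epochs")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.p_update_interval < 1:
            raise ValueError("p_update_interval must be >= 1")

    @classmethod
    def desk_profile(cls, k: int, seed: int = 0, lam: float = 100.0) -> "TrainConfig":
        """Small-data profile: 50 warm-up + 150 joint epochs at lr 1e-3."""
        return cls(total_epochs=200, lr=1e-3, lam=lam, warmup_epochs=50,
                   p_update_interval=1, k=k, seed=seed)


@dataclass
class TrainHistory:
    L_r: list[float] = field(default_factory=list)
    L_c: list[float] = field(default_factory=list)
    L_total: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)
    ari: list[float] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.L_total)

    def joint_losses(self) -> list[float]:
        return [l for l, ph in zip(self.L_total, self.phase) if ph == "joint"]


class Adam:
    """Adam over a list of autodiff leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def pretrain(model: CoopModel, X: np.ndarray, adj: CellAdjacency,
             X_g: np.ndarray, cfg: TrainConfig,
             history: TrainHistory | None = None) -> CoopModel:
    """Warm-up: ``cfg.warmup_epochs`` Adam steps on the reconstruction loss."""
    if cfg.warmup_epochs == 0:
        return model
    A = adj.A_c if isinstance(adj, CellAdjacency) else np.asarray(adj)
    opt = Adam(model.parameters(include_centers=False), lr=cfg.lr)
    for epoch in range(cfg.warmup_epochs):
        _, _, A_hat, X_hat = model.forward(X, adj, X_g)
        loss = model.reconstruction_loss_t(A, A_hat, X, X_hat)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at warm-up epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if history is not None:
            lr_val = float(loss.data)
            history.L_r.append(lr_val)
            history.L_c.append(0.0)
            history.L_total.append(lr_val)
            history.phase.append("warmup")
    return model


def init_centers(Z_c: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seed cluster centers with k-means (k-means++, 20 restarts)."""
    result = kmeans_cluster(Z_c, k=k, seed=seed, n_restarts=20)
    return result.centers


def fit(
    model: CoopModel,
    X: np.ndarray,
    adj: CellAdjacency,
    X_g: np.ndarray,
    cfg: TrainConfig,
    labels: np.ndarray | None = None,
) -> tuple[CoopModel, ClusterHead, TrainHistory]:
    """Full schedule: warm-up, center initialization, joint optimization."""
    A = adj.A_c if isinstance(adj, CellAdjacency) else np.asarray(adj)
    history = TrainHistory()
    pretrain(model, X, adj, X_g, cfg, history=history)

    Z_c0 = model.encode_cells_t(X, adj).data
    model.attach_centers(init_centers(Z_c0, cfg.k, seed=cfg.seed))

    opt = Adam(model.parameters(include_centers=True), lr=cfg.lr)
    joint_epochs = cfg.total_epochs - cfg.warmup_epochs
    P: np.ndarray | None = None
    for epoch in range(joint_epochs):
        Z_c, Z_g, A_hat, X_hat = model.forward(X, adj, X_g)
        Q = model.soft_assignment_t(Z_c)
        if epoch % cfg.p_update_interval == 0 or P is None:
            q_np = Q.data
            col = q_np.sum(axis=0)
            dead = np.flatnonzero(col <= 1e-12)
            if dead.size:
                # reseed each dead center at the embedding farthest from all centers
                for j in dead:
                    d2 = ((Z_c.data[:, None, :] - model.centers.data[None]) ** 2
                          ).sum(axis=2).min(axis=1)
                    far = int(d2.argmax())
                    model.centers.data[j] = Z_c.data[far]
                    history.events.append(f"epoch {epoch}: reseeded empty center {j}")
                Q = model.soft_assignment_t(Z_c)
                q_np = Q.data
            P = target_distribution(q_np)
        loss_r = model.reconstruction_loss_t(A, A_hat, X, X_hat)
        loss_c = model.clustering_loss_t(P, Q)
        loss = loss_r + loss_c * cfg.lam
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at joint epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.L_r.append(float(loss_r.data))
        history.L_c.append(float(loss_c.data))
        history.L_total.append(float(loss.data))
        history.phase.append("joint")
        if labels is not None:
            pred = kmeans_cluster(Z_c.data, k=cfg.k, seed=cfg.seed, n_restarts=5)
            history.ari.append(ari(Partition(labels), pred.partition))

    Z_c, _, _, _ = model.forward(X, adj, X_g)
    Q = model.soft_assignment_t(Z_c).data
    head = ClusterHead(centers=model.centers.data.copy(), Q=Q,
                       P=target_distribution(Q))
    return model, head, history
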