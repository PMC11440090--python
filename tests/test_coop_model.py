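import numpy as np
import pytest

from cellcoop.cell_graph import CellAdjacency
from cellcoop.coop_model import (
    CoopModel,
    GatParams,
    GeneMapperParams,
    ModelConfig,
    clustering_loss,
    cooperative_reconstruction,
    encode_cells,
    encode_genes,
    gat_attention,
    gat_layer,
    reconstruct_adjacency,
    reconstruction_loss,
    soft_assignment,
    target_distribution,
    total_loss,
)

RNG = np.random.default_rng(0)


def _adj(A):
    return CellAdjacency(A_c=np.asarray(A, dtype=float), k=1)


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestGatAttention:
    def test_singleton_neighborhood(self):
        params = GatParams(W=RNG.normal(size=(3, 2)), a=RNG.normal(size=4))
        H = RNG.normal(size=(2, 3))
        alpha = gat_attention(H, params, _adj(np.zeros((2, 2))))
        assert np.allclose(np.diag(alpha), 1.0)  # only self-loops

    def test_identical_features_uniform(self):
        params = GatParams(W=RNG.normal(size=(3, 2)), a=RNG.normal(size=4))
        H = np.tile(RNG.normal(size=3), (4, 1))
        A = np.ones((4, 4)) - np.eye(4)
        alpha = gat_attention(H, params, _adj(A))
        assert np.allclose(alpha, 0.25)

    def test_manual_softmax_oracle(self):
        # 3-node path 0-1-2; attention row of the middle node by hand
        W = np.array([[0.5], [-0.25]])
        a = np.array([1.0, -2.0])
        H = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 2.0]])
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        params = GatParams(W=W, a=a, slope=0.2)
        S = H @ W
        logits = {}
        for j in [0, 1, 2]:  # N(1) + self
            e = a[0] * S[1, 0] + a[1] * S[j, 0]
            logits[j] = e if e > 0 else 0.2 * e
        ex = {j: np.exp(v) for j, v in logits.items()}
        Z = sum(ex.values())
        alpha = gat_attention(H, params, _adj(A))
        for j in [0, 1, 2]:
            assert alpha[1, j] == pytest.approx(ex[j] / Z, abs=1e-12)

    def test_rows_sum_to_one(self):
        params = GatParams(W=RNG.normal(size=(4, 3)), a=RNG.normal(size=6))
        H = RNG.normal(size=(6, 4))
        A = (RNG.random((6, 6)) < 0.4).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        alpha = gat_attention(H, params, _adj(A))
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-8)

    def test_dim_mismatch(self):
        params = GatParams(W=np.ones((3, 2)), a=np.ones(4))
        with pytest.raises(ValueError, match="dim"):
            gat_attention(np.ones((2, 5)), params, _adj(np.zeros((2, 2))))


class TestGatLayer:
    def test_identical_features_reduce_to_projection(self):
        params = GatParams(W=RNG.normal(size=(3, 2)), a=RNG.normal(size=4))
        h = RNG.normal(size=3)
        H = np.tile(h, (4, 1))
        A = np.ones((4, 4)) - np.eye(4)
        out = gat_layer(H, params, _adj(A), activation="identity")
        assert np.allclose(out, np.tile(h @ params.W, (4, 1)))

    def test_zero_features(self):
        params = GatParams(W=np.ones((3, 2)), a=np.ones(4))
        out = gat_layer(np.zeros((3, 3)), params, _adj(np.ones((3, 3)) - np.eye(3)))
        assert np.allclose(out, 0.0)

    def test_manual_sum_oracle(self):
        W = np.array([[0.5], [-0.25]])
        a = np.array([1.0, -2.0])
        H = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 2.0]])
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        params = GatParams(W=W, a=a)
        alpha = gat_attention(H, params, _adj(A))
        S = H @ W
        expected = alpha[1, 0] * S[0] + alpha[1, 1] * S[1] + alpha[1, 2] * S[2]
        out = gat_layer(H, params, _adj(A), activation="identity")
        assert np.allclose(out[1], expected)


class TestEncoders:
    def test_encode_cells_shapes(self):
        layers = [
            GatParams(W=RNG.normal(size=(5, 4)), a=RNG.normal(size=8)),
            GatParams(W=RNG.normal(size=(4, 2)), a=RNG.normal(size=4)),
        ]
        X = RNG.normal(size=(6, 5))
        A = np.ones((6, 6)) - np.eye(6)
        Z = encode_cells(X, _adj(A), layers)
        assert Z.shape == (6, 2)

    def test_single_cell_reduces_to_mlp(self):
        layers = [
            GatParams(W=RNG.normal(size=(3, 4)), a=RNG.normal(size=8)),
            GatParams(W=RNG.normal(size=(4, 2)), a=RNG.normal(size=4)),
        ]
        x = RNG.normal(size=(1, 3))
        Z = encode_cells(x, _adj(np.zeros((1, 1))), layers)
        h = x @ layers[0].W
        h = np.where(h > 0, h, np.exp(np.minimum(h, 0)) - 1)
        expected = h @ layers[1].W
        assert np.allclose(Z, expected)

    def test_encode_genes_shape_and_zero_case(self):
        params = GeneMapperParams(
            weights=[RNG.normal(size=(4, 3)), RNG.normal(size=(3, 2))],
            biases=[np.zeros(3), np.zeros(2)],
        )
        Z = encode_genes(RNG.normal(size=(7, 4)), params)
        assert Z.shape == (7, 2)
        assert np.allclose(encode_genes(np.zeros((5, 4)), params), 0.0)

    def test_gene_mapper_dense_oracle(self):
        W1, b1 = np.array([[1.0, -1.0], [0.5, 2.0]]), np.array([0.1, -0.1])
        W2, b2 = np.array([[2.0], [1.0]]), np.array([0.5])
        params = GeneMapperParams(weights=[W1, W2], biases=[b1, b2])
        x = np.array([[1.0, 2.0]])
        h = x @ W1 + b1
        h = np.where(h > 0, h, np.exp(h) - 1)
        assert np.allclose(encode_genes(x, params), h @ W2 + b2)


class TestDecoders:
    def test_zero_latent_gives_half(self):
        assert np.allclose(reconstruct_adjacency(np.zeros((3, 2))), 0.5)

    def test_orthogonal_unit_rows(self):
        Z = np.eye(3)
        A_hat = reconstruct_adjacency(Z)
        assert np.allclose(np.diag(A_hat), _sigma(1.0))
        off = A_hat[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)

    def test_sigmoid_gram_oracle_and_symmetry(self):
        Z = RNG.normal(size=(4, 3))
        A_hat = reconstruct_adjacency(Z)
        assert np.array_equal(A_hat, A_hat.T)  # exact symmetry
        assert np.allclose(A_hat, _sigma(Z @ Z.T))
        assert np.all((A_hat > 0) & (A_hat < 1))

    def test_cooperative_product_triple_loop(self):
        Zc = RNG.normal(size=(3, 2))
        Zg = RNG.normal(size=(4, 2))
        X_hat = cooperative_reconstruction(Zc, Zg)
        assert X_hat.shape == (3, 4)
        for i in range(3):
            for j in range(4):
                assert X_hat[i, j] == pytest.approx(
                    sum(Zc[i, m] * Zg[j, m] for m in range(2)), abs=1e-12
                )

    def test_basis_gene_rows_copy_coordinates(self):
        Zc = RNG.normal(size=(5, 3))
        Zg = np.eye(3)
        assert np.allclose(cooperative_reconstruction(Zc, Zg), Zc)

    def test_zero_factor(self):
        assert np.allclose(cooperative_reconstruction(np.zeros((2, 3)), RNG.normal(size=(4, 3))), 0)

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            cooperative_reconstruction(np.zeros((2, 3)), np.zeros((4, 2)))


class TestLosses:
    def test_perfect_reconstruction_zero(self):
        A = RNG.random((3, 3))
        X = RNG.random((3, 5))
        assert reconstruction_loss(A, A, X, X) == 0.0

    def test_constant_residual(self):
        A = np.zeros((2, 2))
        X = np.zeros((2, 2))
        assert reconstruction_loss(A, A, X, X + 1.0) == pytest.approx(1.0)

    def test_bruteforce_residual(self):
        A, A_hat = RNG.random((3, 3)), RNG.random((3, 3))
        X, X_hat = RNG.random((3, 4)), RNG.random((3, 4))
        expected = ((A - A_hat) ** 2).sum() / 9 + ((X - X_hat) ** 2).sum() / 12
        assert reconstruction_loss(A, A_hat, X, X_hat) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 3)),
                                np.zeros((2, 2)), np.zeros((2, 2)))

    def test_total_loss_exact(self):
        assert total_loss(2.0, 0.03, 100.0) == 5.0
        assert total_loss(1.5, 123.0, 0.0) == 1.5

    def test_total_loss_negative_lambda(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -1.0)


class TestClusterHeadMath:
    def test_equidistant_centers(self):
        z = np.zeros((1, 2))
        mu = np.array([[1.0, 0.0], [-1.0, 0.0]])
        Q = soft_assignment(z, mu)
        assert np.allclose(Q, 0.5)

    def test_scalar_oracle_08(self):
        z = np.array([[0.0, 0.0]])
        mu = np.array([[0.0, 0.0], [np.sqrt(3.0), 0.0]])  # d^2 = 0 and 3
        Q = soft_assignment(z, mu)
        assert Q[0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_rows_sum_to_one(self):
        Q = soft_assignment(RNG.normal(size=(10, 4)), RNG.normal(size=(3, 4)))
        assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(Q >= 0)

    def test_nonfinite_error(self):
        with pytest.raises(ValueError):
            soft_assignment(np.array([[np.nan, 0.0]]), np.zeros((2, 2)))

    def test_target_hard_assignment_fixed_point(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(target_distribution(Q), Q)

    def test_target_uniform_stays_uniform(self):
        Q = np.full((5, 4), 0.25)
        assert np.allclose(target_distribution(Q), 0.25)

    def test_target_hand_evaluation(self):
        Q = np.array([[0.8, 0.2], [0.6, 0.4]])
        f = np.array([1.4, 0.6])
        w = Q ** 2 / f
        expected = w / w.sum(axis=1, keepdims=True)
        assert np.allclose(target_distribution(Q), expected, atol=1e-12)
        assert np.allclose(target_distribution(Q).sum(axis=1), 1.0)

    def test_target_empty_cluster_errors(self):
        with pytest.raises(ValueError, match="empty"):
            target_distribution(np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_kl_identity(self):
        Q = soft_assignment(RNG.normal(size=(6, 3)), RNG.normal(size=(2, 3)))
        assert clustering_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_kl_closed_form(self):
        P = np.array([[1.0, 0.0]])
        Q = np.array([[0.5, 0.5]])
        assert clustering_loss(P, Q) == pytest.approx(np.log(2.0))

    def test_kl_termwise_oracle(self):
        rng = np.random.default_rng(9)
        P = rng.random((5, 3))
        P /= P.sum(axis=1, keepdims=True)
        Q = rng.random((5, 3))
        Q /= Q.sum(axis=1, keepdims=True)
        expected = sum(
            P[i, j] * np.log(P[i, j] / Q[i, j]) for i in range(5) for j in range(3)
        )
        assert clustering_loss(P, Q) == pytest.approx(expected, abs=1e-12)

    def test_kl_nonneg_and_quadratic_growth(self):
        Q = np.full((4, 2), 0.5)
        losses = []
        for eps in [0.01, 0.02, 0.04]:
            P = Q.copy()
            P[:, 0] += eps
            P[:, 1] -= eps
            losses.append(clustering_loss(P, Q))
        assert all(l > 0 for l in losses)
        # doubling eps roughly quadruples the loss
        assert losses[1] / losses[0] == pytest.approx(4.0, rel=0.1)
        assert losses[2] / losses[1] == pytest.approx(4.0, rel=0.1)

    def test_kl_infinite_divergence_errors(self):
        with pytest.raises(ValueError, match="infinite"):
            clustering_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))


class TestModelForward:
    def setup_method(self):
        self.cfg = ModelConfig(d_g=10, d_e=6, hidden=8, d_m=4, seed=0)
        self.model = CoopModel.init(self.cfg)
        self.X = RNG.normal(size=(7, 10))
        A = (RNG.random((7, 7)) < 0.5).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        self.adj = _adj(A)
        self.Xg = RNG.normal(size=(10, 6))

    def test_forward_shapes_match_annotations(self):
        Zc, Zg, A_hat, X_hat = self.model.forward(self.X, self.adj, self.Xg)
        assert Zc.data.shape == (7, 4)
        assert Zg.data.shape == (10, 4)
        assert A_hat.data.shape == (7, 7)
        assert X_hat.data.shape == (7, 10)

    def test_autodiff_matches_numpy_route(self):
        Zc, Zg, A_hat, X_hat = self.model.forward(self.X, self.adj, self.Xg)
        Zc_np = encode_cells(self.X, self.adj, self.model.cell_params())
        Zg_np = encode_genes(self.Xg, self.model.gene_params())
        assert np.allclose(Zc.data, Zc_np, atol=1e-10)
        assert np.allclose(Zg.data, Zg_np, atol=1e-10)
        assert np.allclose(A_hat.data, reconstruct_adjacency(Zc_np), atol=1e-10)
        assert np.allclose(X_hat.data, cooperative_reconstruction(Zc_np, Zg_np), atol=1e-10)

    def test_soft_assignment_routes_agree(self):
        self.model.attach_centers(RNG.normal(size=(3, 4)))
        Zc = self.model.encode_cells_t(self.X, self.adj)
        Q_t = self.model.soft_assignment_t(Zc).data
        Q_np = soft_assignment(Zc.data, self.model.centers.data)
        assert np.allclose(Q_t, Q_np, atol=1e-10)

    def test_loss_routes_agree(self):
        Zc, Zg, A_hat, X_hat = self.model.forward(self.X, self.adj, self.Xg)
        lr_t = self.model.reconstruction_loss_t(self.adj.A_c, A_hat, self.X, X_hat)
        lr_np = reconstruction_loss(self.adj.A_c, A_hat.data, self.X, X_hat.data)
        assert float(lr_t.data) == pytest.approx(lr_np, abs=1e-12)
        self.model.attach_centers(RNG.normal(size=(3, 4)))
        Q = self.model.soft_assignment_t(Zc)
        P = target_distribution(Q.data)
        lc_t = self.model.clustering_loss_t(P, Q)
        assert float(lc_t.data) == pytest.approx(clustering_loss(P, Q.data), abs=1e-10)

    def test_state_dict_round_trip(self):
        self.model.attach_centers(RNG.normal(size=(3, 4)))
        state = self.model.state_dict()
        clone = CoopModel.from_state_dict(state)
        Zc1, _, _, _ = self.model.forward(self.X, self.adj, self.Xg)
        Zc2, _, _, _ = clone.forward(self.X, self.adj, self.Xg)
        assert np.array_equal(Zc1.data, Zc2.data)
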