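"""Attention network contracts: normalisation, equivariance, oracle forward."""

import numpy as np
import pytest

from hganlda.autodiff import Tensor
from hganlda.model import (
    GraphInputs,
    HGANModel,
    ModelConfig,
    attention_coefficients,
    bce_loss,
    node_attention,
    semantic_attention,
    train_model,
)

from _oracles import forward_oracle


def _toy_inputs(rng, n_l=6, n_d=4):
    def sym_adj(n, p=0.5):
        a = (rng.random((n, n)) < p).astype(int)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 1)
        return a

    return GraphInputs(
        F_l=rng.random((n_l, n_l)),
        F_d=rng.random((n_d, n_d)),
        metapath_adj={
            "LDL": sym_adj(n_l),
            "LML": sym_adj(n_l),
            "DLD": sym_adj(n_d),
            "DMD": sym_adj(n_d),
        },
        knn_l=sym_adj(n_l),
        knn_d=sym_adj(n_d),
    )


TOY_CFG = dict(proj_dim=5, heads=2, semantic_dim=6, out_dim=7, head_hidden=4)


class TestNodeAttention:
    def test_weights_sum_to_one_over_neighbours(self, rng):
        H = Tensor(rng.random((6, 4)))
        W = Tensor(rng.standard_normal((4, 5)))
        adj = np.eye(6, dtype=int)
        adj[0, 1] = adj[1, 0] = adj[2, 4] = adj[4, 2] = 1
        a = attention_coefficients(adj, H, W)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(a[adj == 0], 0.0)

    def test_single_neighbour_gets_weight_one(self, rng):
        H = Tensor(rng.random((3, 4)))
        W = Tensor(rng.standard_normal((4, 5)))
        adj = np.eye(3, dtype=int)
        adj[0, 0] = 0
        adj[0, 2] = 1  # node 0's only neighbour is node 2
        a = attention_coefficients(adj, H, W)
        assert a[0, 2] == pytest.approx(1.0)
        z = node_attention(adj, H, [W]).data
        S = H.data @ W.data
        expected = np.where(S[2] > 0, S[2], np.expm1(S[2]))  # ELU of the neighbour
        assert np.allclose(z[0], expected, atol=1e-12)

    def test_identical_heads_equal_single_head(self, rng):
        H = Tensor(rng.random((5, 4)))
        W = Tensor(rng.standard_normal((4, 6)))
        adj = np.maximum(np.eye(5, dtype=int), (rng.random((5, 5)) < 0.5).astype(int))
        adj = np.maximum(adj, adj.T)
        one = node_attention(adj, H, [W]).data
        four = node_attention(adj, H, [W, W, W, W]).data
        assert np.allclose(one, four, atol=1e-12)

    def test_isolated_node_rejected(self, rng):
        H = Tensor(rng.random((3, 2)))
        W = Tensor(rng.standard_normal((2, 2)))
        adj = np.eye(3, dtype=int)
        adj[1, 1] = 0
        with pytest.raises(ValueError, match="isolated"):
            node_attention(adj, H, [W])


class TestSemanticAttention:
    def _params(self, rng, dim=5, sem=4):
        return (
            Tensor(rng.standard_normal((dim, sem)), requires_grad=True),
            Tensor(np.zeros(sem), requires_grad=True),
            Tensor(rng.standard_normal(sem), requires_grad=True),
        )

    def test_single_subgraph_passthrough(self, rng):
        W, b, q = self._params(rng)
        z = Tensor(rng.random((6, 5)))
        fused, omega = semantic_attention([z], W, b, q)
        assert np.allclose(fused.data, z.data)
        assert omega.tolist() == [1.0]

    def test_identical_embeddings_get_half_each(self, rng):
        W, b, q = self._params(rng)
        z = Tensor(rng.random((6, 5)))
        fused, omega = semantic_attention([z, z], W, b, q)
        assert np.allclose(omega, [0.5, 0.5], atol=1e-12)
        assert np.allclose(fused.data, z.data)

    def test_weights_form_distribution(self, rng):
        W, b, q = self._params(rng)
        zs = [Tensor(rng.standard_normal((6, 5))) for _ in range(3)]
        _, omega = semantic_attention(zs, W, b, q)
        assert omega.min() > 0
        assert omega.sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_under_ablation(self, rng):
        W, b, q = self._params(rng)
        zs = [Tensor(rng.standard_normal((6, 5))) for _ in range(3)]
        _, omega = semantic_attention(zs, W, b, q, uniform=True)
        assert np.allclose(omega, 1.0 / 3.0)

    def test_empty_list_rejected(self, rng):
        W, b, q = self._params(rng)
        with pytest.raises(ValueError):
            semantic_attention([], W, b, q)


class TestPredictionAndLoss:
    def test_zero_head_gives_half_scores(self, rng):
        inputs = _toy_inputs(rng)
        model = HGANModel(ModelConfig(**TOY_CFG), 6, 4, rng=rng)
        for name in ("head_w2", "head_b2"):
            model.params[name].data[...] = 0.0
        probs = model.forward(inputs, [[0, 0], [5, 3]]).data
        assert np.allclose(probs, 0.5)

    def test_scores_strictly_inside_unit_interval(self, rng):
        inputs = _toy_inputs(rng)
        model = HGANModel(ModelConfig(**TOY_CFG), 6, 4, rng=rng)
        pairs = [[i, j] for i in range(6) for j in range(4)]
        probs = model.forward(inputs, pairs).data
        assert (probs > 0).all() and (probs < 1).all()

    def test_pair_index_out_of_range(self, rng):
        inputs = _toy_inputs(rng)
        model = HGANModel(ModelConfig(**TOY_CFG), 6, 4, rng=rng)
        with pytest.raises(IndexError):
            model.forward(inputs, [[0, 99]])

    def test_bce_at_half_is_ln2(self):
        probs = Tensor(np.full(10, 0.5))
        labels = np.array([0, 1] * 5)
        assert float(bce_loss(probs, labels).data) == pytest.approx(np.log(2), abs=1e-12)

    def test_bce_perfect_prediction_near_zero(self):
        labels = np.array([0, 1, 1, 0])
        probs = Tensor(labels.astype(float))
        assert float(bce_loss(probs, labels).data) < 1e-10

    def test_bce_matches_direct_summation(self, rng):
        p = rng.uniform(0.05, 0.95, size=20)
        y = rng.integers(0, 2, size=20)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert float(bce_loss(Tensor(p), y).data) == pytest.approx(expected, abs=1e-12)


class TestForwardPass:
    @pytest.mark.parametrize("variant", ["full", "na", "nho", "sum-branch"])
    def test_matches_loop_oracle(self, rng, variant):
        cfg = ModelConfig(
            **TOY_CFG,
            ablation_na=(variant == "na"),
            ablation_nho=(variant == "nho"),
            branch_combine="sum" if variant == "sum-branch" else "concat",
        )
        inputs = _toy_inputs(rng)
        model = HGANModel(cfg, 6, 4, rng=rng)
        pairs = [[i, j] for i in range(6) for j in range(4)]
        got = model.forward(inputs, pairs).data
        expected = forward_oracle(model, inputs, pairs)
        assert np.allclose(got, expected, atol=1e-5)

    def test_node_permutation_equivariance(self, rng):
        cfg = ModelConfig(**TOY_CFG)
        inputs = _toy_inputs(rng)
        model = HGANModel(cfg, 6, 4, rng=rng)
        perm = rng.permutation(6)
        permuted = GraphInputs(
            F_l=inputs.F_l[perm],
            F_d=inputs.F_d,
            metapath_adj={
                "LDL": inputs.metapath_adj["LDL"][np.ix_(perm, perm)],
                "LML": inputs.metapath_adj["LML"][np.ix_(perm, perm)],
                "DLD": inputs.metapath_adj["DLD"],
                "DMD": inputs.metapath_adj["DMD"],
            },
            knn_l=inputs.knn_l[np.ix_(perm, perm)],
            knn_d=inputs.knn_d,
        )
        base = model.embeddings(inputs)["Z_lnc"].data
        moved = model.embeddings(permuted)["Z_lnc"].data
        assert np.allclose(moved, base[perm], atol=1e-8)

    def test_nho_embedding_has_single_branch_width(self, rng):
        cfg = ModelConfig(**TOY_CFG, ablation_nho=True)
        inputs = _toy_inputs(rng)
        model = HGANModel(cfg, 6, 4, rng=rng)
        emb = model.embeddings(inputs)
        assert emb["Z_lnc"].shape == (6, cfg.out_dim)
        full = HGANModel(ModelConfig(**TOY_CFG), 6, 4, rng=rng)
        assert full.embeddings(inputs)["Z_lnc"].shape == (6, 2 * cfg.out_dim)

    def test_state_dict_roundtrip(self, rng):
        cfg = ModelConfig(**TOY_CFG)
        inputs = _toy_inputs(rng)
        m1 = HGANModel(cfg, 6, 4, rng=np.random.default_rng(0))
        m2 = HGANModel(cfg, 6, 4, rng=np.random.default_rng(99))
        m2.load_state_dict(m1.state_dict())
        pairs = [[0, 1], [3, 2]]
        assert np.allclose(
            m1.forward(inputs, pairs).data, m2.forward(inputs, pairs).data
        )


def test_training_reduces_loss(rng):
    inputs = _toy_inputs(rng, n_l=8, n_d=6)
    cfg = ModelConfig(**TOY_CFG, lr=5e-3)
    model = HGANModel(cfg, 8, 6, rng=rng)
    pairs = np.array([[i, j] for i in range(8) for j in range(6)])
    labels = (rng.random(len(pairs)) < 0.5).astype(int)
    losses = train_model(model, inputs, pairs, labels, max_epochs=30)
    assert len(losses) == 30
    assert losses[-1] < losses[0]
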