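"""Hierarchical graph attention network for lncRNA-disease scoring.

Architecture, per node type (lncRNA / disease):

1. **Projection** — fused-similarity feature rows are mapped into a
   shared ``proj_dim`` space by a learned linear map.
2. **Node-level attention** — on each metapath subgraph, per head h the
   projected features are transformed (``S = H @ W_h``), neighbour
   scores ``LeakyReLU(S_u . S_v)`` are softmax-normalised over each
   node's neighbour set, neighbours aggregated and passed through ELU;
   heads are averaged.
3. **Semantic attention** — one scalar score per metapath subgraph,
   ``mean_u q . tanh(W_G Z_u + b)``, softmaxed across subgraph types to
   weigh the subgraph embeddings into one heterogeneous embedding.
4. **Homogeneous branch** — the same node-level attention on the KNN
   similarity graph; the two branch embeddings are concatenated (or
   summed) per node.
5. **Prediction head** — each pair embedding is combined additively
   through learned per-type transforms, passed through an ELU hidden
   layer and a sigmoid to give an association probability. The hidden
   layer is essential: a purely additive score would rank every lncRNA
   identically for every disease.

Training minimises mean binary cross-entropy with Adam (coupled weight
decay), full batch.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Adam, Tensor, concat, glorot, take_rows
from .graphs import MetapathSubgraph

__all__ = [
    "ModelConfig",
    "GraphInputs",
    "HGANModel",
    "node_attention",
    "semantic_attention",
    "bce_loss",
    "TrainingDivergedError",
]

logger = logging.getLogger(__name__)

LNC_METAPATHS = ("LDL", "LML")
DIS_METAPATHS = ("DLD", "DMD")


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class ModelConfig:
    """Hyperparameters of the hierarchical attention network.

    Defaults follow the reference configuration: 64-dimensional
    projection, 4 attention heads, 128-dimensional semantic attention
    vector and output embeddings, LeakyReLU slope 0.2, KNN k=20, Adam
    with learning rate 1e-3 and weight decay 5e-3, at most 500 epochs.
    ``ablation_nho`` drops the homogeneous (KNN) branch; ``ablation_na``
    freezes the semantic weights at the uniform value 1/GN.
    """

    proj_dim: int = 64
    heads: int = 4
    semantic_dim: int = 128
    out_dim: int = 128
    head_hidden: int = 64
    leaky_slope: float = 0.2
    alpha: float = 0.5
    knn_k: int = 20
    lr: float = 1e-3
    weight_decay: float = 5e-3
    max_epochs: int = 500
    branch_combine: str = "concat"
    ablation_nho: bool = False
    ablation_na: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("proj_dim", "heads", "semantic_dim", "out_dim", "head_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.branch_combine not in ("concat", "sum"):
            raise ValueError("branch_combine must be 'concat' or 'sum'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GraphInputs:
    """Everything one forward pass needs, as plain arrays."""

    F_l: np.ndarray
    F_d: np.ndarray
    metapath_adj: Mapping[str, np.ndarray]
    knn_l: np.ndarray | None = None
    knn_d: np.ndarray | None = None


def _check_adjacency(adjacency) -> np.ndarray:
    if isinstance(adjacency, MetapathSubgraph):
        adjacency = adjacency.adjacency
    adjacency = np.asarray(adjacency)
    if (adjacency.sum(axis=1) == 0).any():
        raise ValueError(
            "adjacency has an isolated node without self-loop: softmax undefined"
        )
    return adjacency


def _head_attention(mask: np.ndarray, H: Tensor, W: Tensor, slope: float):
    """One attention head: (neighbour weights a, transformed features S)."""
    S = H @ W
    phi = (S @ S.T).leaky_relu(slope)
    # numerically stable masked softmax; the shift is a constant
    neg_inf = np.where(mask > 0, 0.0, -np.inf)
    shift = np.max(phi.data + neg_inf, axis=1, keepdims=True)
    e = (phi - shift).exp() * mask
    a = e / e.sum(axis=1, keepdims=True)
    return a, S


def attention_coefficients(
    adjacency, H: Tensor | np.ndarray, W: Tensor | np.ndarray, slope: float = 0.2
) -> np.ndarray:
    """Neighbour attention weights of one head, as a plain array."""
    mask = (_check_adjacency(adjacency) > 0).astype(float)
    a, _ = _head_attention(mask, Tensor.as_tensor(H), Tensor.as_tensor(W), slope)
    return a.data


def node_attention(
    adjacency: np.ndarray | MetapathSubgraph,
    H: Tensor,
    head_weights: Sequence[Tensor],
    slope: float = 0.2,
) -> Tensor:
    """Multihead dot-product graph attention over one subgraph.

    Per head, neighbour logits are the LeakyReLU of inner products of
    the head-transformed features, normalised by softmax over each
    node's neighbour set; aggregated neighbours pass through ELU and
    heads are averaged.
    """
    mask = (_check_adjacency(adjacency) > 0).astype(float)
    head_sum: Tensor | None = None
    for W in head_weights:
        a, S = _head_attention(mask, H, W, slope)
        z = (a @ S).elu()
        head_sum = z if head_sum is None else head_sum + z
    assert head_sum is not None
    return head_sum / float(len(head_weights))


def semantic_attention(
    embeddings: Sequence[Tensor],
    W_G: Tensor,
    b: Tensor,
    q: Tensor,
    uniform: bool = False,
) -> tuple[Tensor, np.ndarray]:
    """Fuse per-subgraph embeddings with metapath-level attention.

    Each subgraph receives the scalar score ``mean_u q . tanh(W_G Z_u + b)``;
    scores are softmaxed across subgraph types and used as mixture
    weights. With ``uniform`` the weights are fixed at ``1/GN``
    (no-attention ablation). Returns the fused embedding and the weights.
    """
    if not embeddings:
        raise ValueError("semantic attention requires at least one embedding")
    gn = len(embeddings)
    if uniform or gn == 1:
        weights = np.full(gn, 1.0 / gn)
        fused = embeddings[0] * weights[0]
        for w, z in zip(weights[1:], embeddings[1:]):
            fused = fused + z * w
        return fused, weights
    scores = [((z @ W_G + b).tanh() @ q).mean() for z in embeddings]
    shift = max(float(s.data) for s in scores)
    exps = [(s - shift).exp() for s in scores]
    total = exps[0]
    for e in exps[1:]:
        total = total + e
    omegas = [e / total for e in exps]
    fused = embeddings[0] * omegas[0]
    for om, z in zip(omegas[1:], embeddings[1:]):
        fused = fused + z * om
    return fused, np.array([float(om.data) for om in omegas])


def bce_loss(probs: Tensor, labels: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped away from {0, 1}."""
    y = np.asarray(labels, dtype=float).reshape(-1)
    if ((probs.data <= eps) | (probs.data >= 1 - eps)).any():
        logger.debug("BCE input clamped to [%g, %g]", eps, 1 - eps)
    p = probs.reshape(-1).clip(eps, 1.0 - eps)
    return -(p.log() * y + (1.0 - p).log() * (1.0 - y)).mean()


class HGANModel:
    """Hierarchical attention model with all trainable parameters."""

    def __init__(self, cfg: ModelConfig, n_feat_l: int, n_feat_d: int, rng=None):
        self.cfg = cfg
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
            cfg.seed if rng is None else rng
        )
        p: dict[str, Tensor] = {}
        p["W_l"] = glorot(rng, n_feat_l, cfg.proj_dim)
        p["W_d"] = glorot(rng, n_feat_d, cfg.proj_dim)
        for path in LNC_METAPATHS + DIS_METAPATHS:
            for h in range(cfg.heads):
                p[f"att_{path}_h{h}"] = glorot(rng, cfg.proj_dim, cfg.out_dim)
        if not cfg.ablation_nho:
            for branch in ("knn_l", "knn_d"):
                for h in range(cfg.heads):
                    p[f"att_{branch}_h{h}"] = glorot(rng, cfg.proj_dim, cfg.out_dim)
        for kind in ("lnc", "dis"):
            p[f"sem_W_{kind}"] = glorot(rng, cfg.out_dim, cfg.semantic_dim)
            p[f"sem_b_{kind}"] = Tensor(np.zeros(cfg.semantic_dim), requires_grad=True)
            p[f"sem_q_{kind}"] = glorot(rng, cfg.semantic_dim)
        emb_dim = cfg.out_dim
        if not cfg.ablation_nho and cfg.branch_combine == "concat":
            emb_dim = 2 * cfg.out_dim
        self.embedding_dim = emb_dim
        p["head_W_l"] = glorot(rng, emb_dim, cfg.head_hidden)
        p["head_W_d"] = glorot(rng, emb_dim, cfg.head_hidden)
        p["head_b1"] = Tensor(np.zeros(cfg.head_hidden), requires_grad=True)
        p["head_w2"] = glorot(rng, cfg.head_hidden, 1)
        p["head_b2"] = Tensor(np.zeros(1), requires_grad=True)
        self.params = p

    # -- forward ----------------------------------------------------------
    def _heads(self, prefix: str) -> list[Tensor]:
        return [self.params[f"att_{prefix}_h{h}"] for h in range(self.cfg.heads)]

    def embeddings(self, inputs: GraphInputs) -> dict:
        """Per-node embeddings for both types plus the semantic weights."""
        cfg = self.cfg
        H_l = Tensor(inputs.F_l) @ self.params["W_l"]
        H_d = Tensor(inputs.F_d) @ self.params["W_d"]
        out: dict = {}
        for kind, H, paths in (
            ("lnc", H_l, LNC_METAPATHS),
            ("dis", H_d, DIS_METAPATHS),
        ):
            sub_embeddings = [
                node_attention(
                    inputs.metapath_adj[path], H, self._heads(path), cfg.leaky_slope
                )
                for path in paths
            ]
            z_het, omega = semantic_attention(
                sub_embeddings,
                self.params[f"sem_W_{kind}"],
                self.params[f"sem_b_{kind}"],
                self.params[f"sem_q_{kind}"],
                uniform=cfg.ablation_na,
            )
            out[f"omega_{kind}"] = omega
            if cfg.ablation_nho:
                out[f"Z_{kind}"] = z_het
                continue
            knn_adj = inputs.knn_l if kind == "lnc" else inputs.knn_d
            if knn_adj is None:
                raise ValueError("homogeneous branch enabled but KNN adjacency missing")
            prefix = "knn_l" if kind == "lnc" else "knn_d"
            z_homog = node_attention(knn_adj, H, self._heads(prefix), cfg.leaky_slope)
            if cfg.branch_combine == "concat":
                out[f"Z_{kind}"] = concat([z_het, z_homog], axis=1)
            else:
                out[f"Z_{kind}"] = z_het + z_homog
        return out

    def forward(self, inputs: GraphInputs, pairs: np.ndarray) -> Tensor:
        """Association probabilities for (lncRNA, disease) index pairs."""
        emb = self.embeddings(inputs)
        return self.predict_scores(emb["Z_lnc"], emb["Z_dis"], pairs)

    def predict_scores(self, Z_lnc: Tensor, Z_dis: Tensor, pairs: np.ndarray) -> Tensor:
        """Sigmoid pair scores from the final embeddings."""
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        n_l, n_d = Z_lnc.shape[0], Z_dis.shape[0]
        if pairs.size and (
            pairs[:, 0].min() < 0
            or pairs[:, 0].max() >= n_l
            or pairs[:, 1].min() < 0
            or pairs[:, 1].max() >= n_d
        ):
            raise IndexError("pair index out of range")
        zi = take_rows(Z_lnc, pairs[:, 0])
        zj = take_rows(Z_dis, pairs[:, 1])
        hidden = (
            zi @ self.params["head_W_l"]
            + zj @ self.params["head_W_d"]
            + self.params["head_b1"]
        ).elu()
        logits = hidden @ self.params["head_w2"] + self.params["head_b2"]
        return logits.reshape(-1).sigmoid()

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: np.array(t.data) for name, t in self.params.items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for name, tensor in self.params.items():
            tensor.data = np.asarray(state[name], dtype=float).reshape(tensor.shape)


def train_model(
    model: HGANModel,
    inputs: GraphInputs,
    pairs: np.ndarray,
    labels: np.ndarray,
    max_epochs: int | None = None,
) -> list[float]:
    """Full-batch Adam training; returns the per-epoch loss trace."""
    cfg = model.cfg
    epochs = cfg.max_epochs if max_epochs is None else max_epochs
    opt = Adam(model.params.values(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    losses: list[float] = []
    for epoch in range(epochs):
        opt.zero_grad()
        probs = model.forward(inputs, pairs)
        loss = bce_loss(probs, labels)
        value = float(loss.data)
        if not np.isfinite(value):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch} (lr={cfg.lr})"
            )
        loss.backward()
        opt.step()
        losses.append(value)
    return losses
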