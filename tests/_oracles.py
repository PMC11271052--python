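"""Independent reference implementations used as test oracles.

Everything here is deliberately written in the most literal way
possible (memoized recursion, explicit path enumeration, pairwise
counting, plain loops) and shares no code with the package.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def edit_distance_oracle(a: str, b: str, sub: int = 2, indel: int = 1) -> int:
    """Weighted edit distance by memoized recursion."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == 0:
            return j * indel
        if j == 0:
            return i * indel
        best = go(i - 1, j - 1) + (0 if a[i - 1] == b[j - 1] else sub)
        best = min(best, go(i - 1, j) + indel, go(i, j - 1) + indel)
        return best

    return go(len(a), len(b))


def semantic_contribution_oracle(
    parents: dict[str, list[str]], disease: str, decay: float = 0.5
) -> dict[str, float]:
    """Max decayed contribution over every explicit ancestor path."""
    contrib: dict[str, float] = {}

    def walk(node: str, value: float) -> None:
        if value > contrib.get(node, 0.0):
            contrib[node] = value
        for parent in parents.get(node, []):
            walk(parent, value * decay)

    walk(disease, 1.0)
    return contrib


def dss_oracle(parents: dict[str, list[str]], d1: str, d2: str) -> float:
    """Wang similarity via explicit path enumeration for both diseases."""
    c1 = semantic_contribution_oracle(parents, d1)
    c2 = semantic_contribution_oracle(parents, d2)
    common = set(c1) & set(c2)
    if not common:
        return 0.0
    num = sum(c1[t] + c2[t] for t in common)
    return num / (sum(c1.values()) + sum(c2.values()))


def gip_oracle(profiles: np.ndarray) -> np.ndarray:
    """GIP kernel recomputed entry by entry from the printed formula."""
    profiles = np.asarray(profiles, float)
    n = profiles.shape[0]
    xi = 1.0 / (np.mean([np.linalg.norm(profiles[i]) ** 2 for i in range(n)]))
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.exp(-xi * np.linalg.norm(profiles[i] - profiles[j]) ** 2)
    return out


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive pairwise comparison (ties count half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def forward_oracle(model, inputs, pairs) -> np.ndarray:
    """Straight-line, loop-based recomputation of the full forward pass.

    Reads the trained parameter arrays from ``model`` and re-derives the
    pair probabilities with explicit per-node loops (projection, per-head
    dot-product attention with neighbour softmax, head averaging,
    metapath-level attention, KNN branch, additive ELU prediction head).
    """
    cfg = model.cfg
    P = {k: np.array(v.data) for k, v in model.params.items()}

    def leaky(x):
        return np.where(x > 0, x, cfg.leaky_slope * x)

    def elu(x):
        return np.where(x > 0, x, np.expm1(x))

    def one_subgraph(adj, H, prefix):
        n = H.shape[0]
        z_heads = []
        for h in range(cfg.heads):
            S = H @ P[f"att_{prefix}_h{h}"]
            Z = np.zeros_like(S)
            for u in range(n):
                nbrs = [v for v in range(n) if adj[u, v]]
                phi = np.array([leaky(S[u] @ S[v]) for v in nbrs])
                e = np.exp(phi - phi.max())
                a = e / e.sum()
                agg = np.zeros(S.shape[1])
                for w, v in zip(a, nbrs):
                    agg += w * S[v]
                Z[u] = elu(agg)
            z_heads.append(Z)
        return sum(z_heads) / cfg.heads

    def semantic(zs, kind):
        gn = len(zs)
        if cfg.ablation_na:
            omega = np.full(gn, 1.0 / gn)
        else:
            scores = []
            for Z in zs:
                vals = [
                    P[f"sem_q_{kind}"]
                    @ np.tanh(P[f"sem_W_{kind}"].T @ Z[u] + P[f"sem_b_{kind}"])
                    for u in range(Z.shape[0])
                ]
                scores.append(np.mean(vals))
            scores = np.array(scores)
            e = np.exp(scores - scores.max())
            omega = e / e.sum()
        return sum(w * Z for w, Z in zip(omega, zs))

    H_l = inputs.F_l @ P["W_l"]
    H_d = inputs.F_d @ P["W_d"]
    z_l = semantic(
        [one_subgraph(inputs.metapath_adj[p], H_l, p) for p in ("LDL", "LML")], "lnc"
    )
    z_d = semantic(
        [one_subgraph(inputs.metapath_adj[p], H_d, p) for p in ("DLD", "DMD")], "dis"
    )
    if not cfg.ablation_nho:
        zo_l = one_subgraph(inputs.knn_l, H_l, "knn_l")
        zo_d = one_subgraph(inputs.knn_d, H_d, "knn_d")
        if cfg.branch_combine == "concat":
            z_l = np.hstack([z_l, zo_l])
            z_d = np.hstack([z_d, zo_d])
        else:
            z_l = z_l + zo_l
            z_d = z_d + zo_d
    probs = []
    for i, j in np.asarray(pairs, int):
        hidden = elu(P["head_W_l"].T @ z_l[i] + P["head_W_d"].T @ z_d[j] + P["head_b1"])
        logit = float(P["head_w2"][:, 0] @ hidden + P["head_b2"][0])
        probs.append(1.0 / (1.0 + np.exp(-logit)))
    return np.array(probs)
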