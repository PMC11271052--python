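"""Cross-validation protocol, metrics and candidate ranking.

Known lncRNA-disease associations are split into five folds; per fold
the test positives are masked out of the association matrix before GIP
similarities, fused node features and metapath subgraphs are rebuilt
(so no test edge leaks into the graph structure), negatives are sampled
balanced and disjoint between train and test, and the model is trained
full batch. Reported metrics are AUC, AUPR and thresholded accuracy /
precision / recall / F1, per fold and averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graphs import (
    HeteroGraph,
    LabeledPairs,
    ParameterError,
    assemble_node_features,
    knn_graph,
    metapath_subgraph,
)
from .model import GraphInputs, HGANModel, ModelConfig, train_model
from .similarity import (
    FusionConfig,
    SimilarityMatrix,
    fuse_similarities,
    gip_kernel_similarity,
)

__all__ = [
    "FoldSplit",
    "EvalReport",
    "RankedCandidates",
    "make_folds",
    "build_inputs",
    "evaluate",
    "cross_validate",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "aupr", "accuracy", "precision", "recall", "f1")


@dataclass
class FoldSplit:
    """One cross-validation fold with balanced train and test samples."""

    fold_id: int
    train: LabeledPairs
    test: LabeledPairs


def make_folds(E_ld: np.ndarray, n_folds: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Partition positives into folds and draw disjoint balanced negatives.

    Positives are shuffled and split into near-equal folds; a single
    permutation of zero entries supplies the negatives, chunked in step
    with the positive folds so train and test negatives never overlap.
    """
    E_ld = np.asarray(E_ld)
    positives = np.argwhere(E_ld == 1)
    if n_folds < 2:
        raise ParameterError("n_folds must be at least 2")
    if n_folds > len(positives):
        raise ParameterError(
            f"cannot make {n_folds} folds from {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    positives = positives[rng.permutation(len(positives))]
    zeros = np.argwhere(E_ld == 0)
    if len(zeros) < len(positives):
        raise ParameterError("fewer unknown pairs than known associations")
    negatives = zeros[rng.choice(len(zeros), size=len(positives), replace=False)]
    pos_chunks = np.array_split(positives, n_folds)
    neg_chunks = np.array_split(negatives, n_folds)
    folds = []
    for f in range(n_folds):
        test_pos, test_neg = pos_chunks[f], neg_chunks[f]
        train_pos = np.vstack([pos_chunks[i] for i in range(n_folds) if i != f])
        train_neg = np.vstack([neg_chunks[i] for i in range(n_folds) if i != f])
        train = LabeledPairs(
            np.vstack([train_pos, train_neg]),
            np.concatenate([np.ones(len(train_pos), int), np.zeros(len(train_neg), int)]),
        )
        test = LabeledPairs(
            np.vstack([test_pos, test_neg]),
            np.concatenate([np.ones(len(test_pos), int), np.zeros(len(test_neg), int)]),
        )
        folds.append(FoldSplit(f + 1, train, test))
    return folds


def build_inputs(
    hetero: HeteroGraph,
    lss: SimilarityMatrix,
    dss: SimilarityMatrix,
    fusion: FusionConfig | None = None,
    knn_k: int = 20,
    with_knn: bool = True,
) -> GraphInputs:
    """Derive features and adjacencies from an association graph state.

    GIP kernels, fused features, metapath subgraphs and KNN graphs are
    all computed from the matrices in ``hetero`` — pass a test-masked
    graph to keep held-out edges out of every derived quantity.
    """
    fusion = fusion or FusionConfig()
    lgs = gip_kernel_similarity(hetero.E_ld, "rows")
    dgs = gip_kernel_similarity(hetero.E_ld, "columns")
    lsm = fuse_similarities(lss, lgs, fusion)
    dsm = fuse_similarities(dss, dgs, fusion)
    features = assemble_node_features(lsm, dsm)
    adj = {p: metapath_subgraph(hetero, p).adjacency for p in ("LDL", "LML", "DLD", "DMD")}
    knn_l = knn_d = None
    if with_knn:
        knn_l = knn_graph(lsm, min(knn_k, hetero.n_lnc))
        knn_d = knn_graph(dsm, min(knn_k, hetero.n_dis))
    return GraphInputs(
        F_l=features.lnc_features,
        F_d=features.dis_features,
        metapath_adj=adj,
        knn_l=knn_l,
        knn_d=knn_d,
    )


def evaluate(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """AUC, AUPR and thresholded classification metrics for one fold."""
    probs = np.asarray(probs, float).reshape(-1)
    labels = np.asarray(labels, int).reshape(-1)
    if len(probs) != len(labels):
        raise ValueError("probs and labels must have equal length")
    row: dict = {"threshold": threshold}
    if labels.min() == labels.max():
        warnings.warn("labels contain a single class; AUC/AUPR undefined", stacklevel=2)
        row["auc"] = row["aupr"] = float("nan")
    else:
        row["auc"] = float(roc_auc_score(labels, probs))
        row["aupr"] = float(average_precision_score(labels, probs))
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    row["accuracy"] = (tp + tn) / len(labels)
    row["precision"] = tp / (tp + fp) if tp + fp else 0.0
    row["recall"] = tp / (tp + fn) if tp + fn else 0.0
    pr, rc = row["precision"], row["recall"]
    row["f1"] = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    return row


@dataclass
class EvalReport:
    """Per-fold and mean metrics of one cross-validation run."""

    fold_rows: list[dict]
    threshold: float = 0.5
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            vals = [row[name] for row in self.fold_rows]
            out[name] = float(np.nanmean(vals)) if vals else float("nan")
        return out

    def to_frame(self):
        import pandas as pd

        rows = [dict(row, fold=i + 1) for i, row in enumerate(self.fold_rows)]
        rows.append(dict(self.mean, fold="mean", threshold=self.threshold))
        return pd.DataFrame(rows).set_index("fold")


def cross_validate(
    hetero: HeteroGraph,
    lss: SimilarityMatrix,
    dss: SimilarityMatrix,
    cfg: ModelConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    fusion: FusionConfig | None = None,
    threshold: float = 0.5,
    mask_test_edges: bool = True,
    gip_per_fold: bool = True,
    max_epochs: int | None = None,
) -> EvalReport:
    """Run the fold protocol end to end and collect the metric table.

    ``mask_test_edges`` removes each fold's test positives from the
    association matrix before subgraphs are built; ``gip_per_fold``
    recomputes the GIP kernels from the masked matrix as well (both on
    by default to avoid information leakage from held-out links).
    """
    cfg = cfg or ModelConfig()
    folds = make_folds(hetero.E_ld, n_folds=n_folds, seed=seed)
    full_inputs = None
    if not (mask_test_edges and gip_per_fold):
        full_inputs = build_inputs(
            hetero, lss, dss, fusion, cfg.knn_k, with_knn=not cfg.ablation_nho
        )
    rows, scores = [], []
    for fold in folds:
        if mask_test_edges:
            g_fold = hetero.with_masked_ld(fold.test.positives)
            inputs = build_inputs(
                g_fold, lss, dss, fusion, cfg.knn_k, with_knn=not cfg.ablation_nho
            )
        else:
            inputs = full_inputs
        model = HGANModel(
            cfg,
            inputs.F_l.shape[1],
            inputs.F_d.shape[1],
            rng=np.random.default_rng([seed, fold.fold_id]),
        )
        losses = train_model(model, inputs, fold.train.pairs, fold.train.labels, max_epochs)
        probs = model.forward(inputs, fold.test.pairs).data
        row = evaluate(probs, fold.test.labels, threshold)
        row["final_loss"] = losses[-1] if losses else float("nan")
        rows.append(row)
        scores.append((probs, fold.test.labels.copy()))
        logger.info(
            "fold %d: auc=%.4f aupr=%.4f loss=%.4f",
            fold.fold_id,
            row["auc"],
            row["aupr"],
            row["final_loss"],
        )
    return EvalReport(rows, threshold=threshold, fold_scores=scores)


@dataclass
class RankedCandidates:
    """Descending candidate lncRNAs for one query disease."""

    disease_id: str
    ranking: list[tuple[str, float]]


def rank_candidates(
    hetero: HeteroGraph,
    lss: SimilarityMatrix,
    dss: SimilarityMatrix,
    disease_id: str,
    cfg: ModelConfig | None = None,
    top_n: int = 15,
    seed: int = 0,
    fusion: FusionConfig | None = None,
    max_epochs: int | None = None,
) -> RankedCandidates:
    """Case-study ranking: hold out one disease, train, score all lncRNAs.

    The query disease's known associations are removed before training;
    the remaining associations (plus an equal number of sampled
    negatives, never drawn from the query column) form the training set.
    """
    cfg = cfg or ModelConfig()
    try:
        j = hetero.dis_ids.index(disease_id)
    except ValueError:
        raise LookupError(f"unknown disease id {disease_id!r}") from None
    E = hetero.E_ld.copy()
    E[:, j] = 0
    g = HeteroGraph(hetero.lnc_ids, hetero.dis_ids, hetero.mir_ids, E, hetero.E_lm, hetero.E_md)
    inputs = build_inputs(g, lss, dss, fusion, cfg.knn_k, with_knn=not cfg.ablation_nho)
    rng = np.random.default_rng([seed, j])
    positives = np.argwhere(E == 1)
    zeros = np.argwhere((E == 0) & (np.arange(E.shape[1])[None, :] != j))
    chosen = zeros[rng.choice(len(zeros), size=len(positives), replace=False)]
    pairs = np.vstack([positives, chosen])
    labels = np.concatenate([np.ones(len(positives), int), np.zeros(len(chosen), int)])
    model = HGANModel(cfg, inputs.F_l.shape[1], inputs.F_d.shape[1], rng=rng)
    train_model(model, inputs, pairs, labels, max_epochs)
    query = np.column_stack(
        [np.arange(g.n_lnc), np.full(g.n_lnc, j)]
    )
    scores = model.forward(inputs, query).data
    order = np.lexsort((np.arange(g.n_lnc), -scores))
    ranking = [(g.lnc_ids[i], float(scores[i])) for i in order[:top_n]]
    return RankedCandidates(disease_id, ranking)
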