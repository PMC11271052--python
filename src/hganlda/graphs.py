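"""Heterogeneous graph assembly, metapath subgraphs and KNN homogeneous graphs.

The ternary lncRNA-miRNA-disease graph is held as three binary
association matrices. Four length-3 metapaths (L-D-L, L-M-L, D-L-D,
D-M-D) each induce a homogeneous subgraph over their endpoint node type:
two same-type nodes are joined when at least one intermediate node links
to both. Two additional homogeneous graphs come from the k nearest
neighbours of the fused similarity matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "PATH_TYPES",
    "HeteroGraph",
    "MetapathSubgraph",
    "LabeledPairs",
    "NodeFeatures",
    "DimensionError",
    "InfeasibleSamplingError",
    "ParameterError",
    "build_hetero_graph",
    "sample_negatives",
    "metapath_subgraph",
    "knn_graph",
    "assemble_node_features",
]

logger = logging.getLogger(__name__)

#: the four supported metapath types (endpoint node type - intermediate - endpoint)
PATH_TYPES = ("LDL", "LML", "DLD", "DMD")


class DimensionError(ValueError):
    """Association matrix shapes are mutually inconsistent."""


class InfeasibleSamplingError(ValueError):
    """Too few unknown pairs to draw the requested negative sample."""


class ParameterError(ValueError):
    """A graph-construction parameter is out of range."""


def _check_binary(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise DimensionError(f"{name} must be a 2-D matrix")
    if not np.isin(mat, (0, 1)).all():
        raise DimensionError(f"{name} must be binary")
    return mat.astype(np.int8)


@dataclass
class HeteroGraph:
    """Ternary heterogeneous graph over lncRNA, disease and miRNA nodes.

    ``E_ld`` is (N_lnc x N_dis), ``E_lm`` is (N_lnc x N_mir) and ``E_md``
    is (N_mir x N_dis), matching the dataset convention in which miRNA-
    disease associations are listed miRNA-first.
    """

    lnc_ids: tuple[str, ...]
    dis_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]
    E_ld: np.ndarray
    E_lm: np.ndarray
    E_md: np.ndarray

    def __post_init__(self) -> None:
        self.lnc_ids = tuple(self.lnc_ids)
        self.dis_ids = tuple(self.dis_ids)
        self.mir_ids = tuple(self.mir_ids)
        self.E_ld = _check_binary(self.E_ld, "E_ld")
        self.E_lm = _check_binary(self.E_lm, "E_lm")
        self.E_md = _check_binary(self.E_md, "E_md")
        nl, nd, nm = len(self.lnc_ids), len(self.dis_ids), len(self.mir_ids)
        if self.E_ld.shape != (nl, nd):
            raise DimensionError(
                f"E_ld has shape {self.E_ld.shape}, expected ({nl}, {nd})"
            )
        if self.E_lm.shape != (nl, nm):
            raise DimensionError(
                f"E_lm has shape {self.E_lm.shape}, expected ({nl}, {nm})"
            )
        if self.E_md.shape != (nm, nd):
            raise DimensionError(
                f"E_md has shape {self.E_md.shape}, expected ({nm}, {nd})"
            )

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_ids)

    @property
    def n_dis(self) -> int:
        return len(self.dis_ids)

    @property
    def n_mir(self) -> int:
        return len(self.mir_ids)

    def block_matrix(self) -> np.ndarray:
        """Symmetric block adjacency over all node types.

        Node order is lncRNAs, then diseases, then miRNAs; diagonal
        blocks are zero. The miRNA-disease matrix enters transposed in
        the (disease, miRNA) block so the result is shape-consistent.
        """
        nl, nd, nm = self.n_lnc, self.n_dis, self.n_mir
        zl = np.zeros((nl, nl), dtype=np.int8)
        zd = np.zeros((nd, nd), dtype=np.int8)
        zm = np.zeros((nm, nm), dtype=np.int8)
        return np.block(
            [
                [zl, self.E_ld, self.E_lm],
                [self.E_ld.T, zd, self.E_md.T],
                [self.E_lm.T, self.E_md, zm],
            ]
        )

    def with_masked_ld(self, pairs: np.ndarray) -> "HeteroGraph":
        """Copy of the graph with the given lncRNA-disease edges removed."""
        E = self.E_ld.copy()
        pairs = np.asarray(pairs, dtype=int)
        if pairs.size:
            E[pairs[:, 0], pairs[:, 1]] = 0
        return HeteroGraph(self.lnc_ids, self.dis_ids, self.mir_ids, E, self.E_lm, self.E_md)


def build_hetero_graph(
    E_ld: np.ndarray,
    E_lm: np.ndarray,
    E_md: np.ndarray,
    lnc_ids=None,
    dis_ids=None,
    mir_ids=None,
) -> HeteroGraph:
    """Assemble a :class:`HeteroGraph`, generating ids when none are given."""
    E_ld = np.asarray(E_ld)
    E_lm = np.asarray(E_lm)
    E_md = np.asarray(E_md)
    nl, nd = E_ld.shape
    nm = E_md.shape[0] if E_md.ndim == 2 else 0
    lnc_ids = lnc_ids or [f"l{i}" for i in range(nl)]
    dis_ids = dis_ids or [f"d{i}" for i in range(nd)]
    mir_ids = mir_ids or [f"m{i}" for i in range(nm)]
    return HeteroGraph(lnc_ids, dis_ids, mir_ids, E_ld, E_lm, E_md)


@dataclass
class LabeledPairs:
    """(lncRNA index, disease index) pairs with binary association labels."""

    pairs: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must have equal length")
        seen = {tuple(p) for p in self.pairs}
        if len(seen) != len(self.pairs):
            raise ValueError("duplicate pairs in labeled sample")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def positives(self) -> np.ndarray:
        return self.pairs[self.labels == 1]

    @property
    def negatives(self) -> np.ndarray:
        return self.pairs[self.labels == 0]


def sample_negatives(
    E_ld: np.ndarray,
    seed: int | np.random.Generator,
    n_negatives: int | None = None,
) -> LabeledPairs:
    """Balanced labeled sample: all known associations plus uniform negatives.

    Negatives are drawn uniformly without replacement from the zero
    entries of ``E_ld``; by default as many as there are positives.
    """
    E_ld = _check_binary(np.asarray(E_ld), "E_ld")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positives = np.argwhere(E_ld == 1)
    zeros = np.argwhere(E_ld == 0)
    n_neg = len(positives) if n_negatives is None else int(n_negatives)
    if n_neg > len(zeros):
        raise InfeasibleSamplingError(
            f"requested {n_neg} negatives but only {len(zeros)} unknown pairs exist"
        )
    chosen = zeros[rng.choice(len(zeros), size=n_neg, replace=False)]
    pairs = np.vstack([positives, chosen])
    labels = np.concatenate([np.ones(len(positives), int), np.zeros(n_neg, int)])
    return LabeledPairs(pairs, labels)


@dataclass
class MetapathSubgraph:
    """Homogeneous adjacency induced by one metapath type (with self-loops)."""

    path_type: str
    node_type: str
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        if self.path_type not in PATH_TYPES:
            raise ParameterError(f"unknown metapath type {self.path_type!r}")
        self.adjacency = _check_binary(self.adjacency, "adjacency")
        if (self.adjacency != self.adjacency.T).any():
            raise ValueError("metapath adjacency must be symmetric")
        if (self.adjacency.sum(axis=1) == 0).any():
            raise ValueError("every node must keep at least a self-loop")


def metapath_subgraph(g: HeteroGraph, path_type: str) -> MetapathSubgraph:
    """Extract the homogeneous subgraph of one metapath type.

    Two endpoint nodes are adjacent when some intermediate node of the
    path's middle type links to both (multiple shared intermediates
    still give a single binary edge); every node then receives a
    self-loop so attention over neighbours is always well defined.
    """
    if path_type == "LDL":
        product, node_type = g.E_ld @ g.E_ld.T, "lnc"
    elif path_type == "LML":
        product, node_type = g.E_lm @ g.E_lm.T, "lnc"
    elif path_type == "DLD":
        product, node_type = g.E_ld.T @ g.E_ld, "dis"
    elif path_type == "DMD":
        product, node_type = g.E_md.T @ g.E_md, "dis"
    else:
        raise ParameterError(f"unknown metapath type {path_type!r}")
    adjacency = (product > 0).astype(np.int8)
    np.fill_diagonal(adjacency, 1)
    return MetapathSubgraph(path_type, node_type, adjacency)


def knn_graph(
    sim: SimilarityMatrix | np.ndarray, k: int, symmetrize: bool = True
) -> np.ndarray:
    """Binary adjacency of the k most similar nodes per row (self included).

    Each node's neighbour set contains itself plus its ``k - 1`` most
    similar other nodes; ties at the cut are broken by ascending node
    index. When ``symmetrize`` is set the directed selection is closed
    under union, giving an undirected graph.
    """
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    n = values.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k must lie in [1, {n}], got {k}")
    adj = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # sort by similarity descending, then index ascending (tie rule)
        order = others[np.lexsort((others, -values[i, others]))]
        adj[i, i] = 1
        adj[i, order[: k - 1]] = 1
    if symmetrize:
        adj = np.maximum(adj, adj.T)
    return adj


@dataclass
class NodeFeatures:
    """Initial node features: rows of the fused similarity matrices."""

    lnc_features: np.ndarray
    dis_features: np.ndarray
    lnc_ids: tuple[str, ...] = field(default=())
    dis_ids: tuple[str, ...] = field(default=())


def assemble_node_features(
    lsm: SimilarityMatrix, dsm: SimilarityMatrix
) -> NodeFeatures:
    """Use fused similarity rows directly as node feature vectors."""
    return NodeFeatures(
        lnc_features=np.array(lsm.values, dtype=float),
        dis_features=np.array(dsm.values, dtype=float),
        lnc_ids=lsm.node_ids,
        dis_ids=dsm.node_ids,
    )
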