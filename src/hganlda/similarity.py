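"""Node similarity measures for lncRNAs and diseases.

Four similarity matrices feed the model's node features:

* **LSS** — lncRNA sequence similarity from a weighted edit distance
  (substitution cost 2, insertion/deletion cost 1), normalised by the
  summed sequence lengths.
* **DSS** — disease semantic similarity computed on a MeSH-style disease
  ontology DAG with the Wang decay method (decay factor 0.5).
* **LGS / DGS** — Gaussian interaction profile (GIP) kernel similarity
  of the binary lncRNA-disease association profiles (rows for lncRNAs,
  columns for diseases).

The sequence and GIP similarities are linearly fused per node type,
``(alpha * semantic + (1 - alpha) * gip) / divisor``, yielding the
combined matrices LSM and DSM whose rows serve as node features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from numba import njit

__all__ = [
    "SequenceRecord",
    "SimilarityMatrix",
    "DiseaseDAG",
    "FusionConfig",
    "InvalidInputError",
    "DegenerateInputError",
    "InvalidDAGError",
    "AlignmentError",
    "weighted_edit_distance",
    "lncrna_sequence_similarity",
    "disease_semantic_similarity",
    "gip_kernel_similarity",
    "fuse_similarities",
]

RNA_ALPHABET = frozenset("ACGTU")

#: decay applied per edge when walking from a disease up to its ancestors
SEMANTIC_DECAY = 0.5


class InvalidInputError(ValueError):
    """An input violates a precondition (e.g. two empty sequences in a pair)."""


class DegenerateInputError(ValueError):
    """An input is degenerate for the requested operation (e.g. all-zero GIP)."""


class InvalidDAGError(ValueError):
    """The disease ontology is not a valid DAG."""


class AlignmentError(ValueError):
    """Two similarity matrices do not share the same node universe/order."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (case-insensitive, may be empty)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("sequence record id must be nonempty")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered node universe."""

    node_ids: tuple[str, ...]
    values: np.ndarray

    def __init__(self, node_ids: Sequence[str], values: np.ndarray):
        self.node_ids = tuple(node_ids)
        self.values = np.asarray(values, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise InvalidInputError("node ids must be unique")
        if self.values.shape != (n, n):
            raise InvalidInputError(
                f"matrix shape {self.values.shape} does not match {n} node ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise InvalidInputError("similarity matrix must be symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise InvalidInputError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.node_ids, columns=self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise LookupError(f"unknown node id {node_id!r}") from None


@njit(cache=False)
def _edit_dp(a, b, sub_cost, indel_cost):  # pragma: no cover - jitted
    m = a.shape[0]
    n = b.shape[0]
    prev = np.empty(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        prev[j] = j * indel_cost
    for i in range(1, m + 1):
        cur[0] = i * indel_cost
        for j in range(1, n + 1):
            c = prev[j - 1] if a[i - 1] == b[j - 1] else prev[j - 1] + sub_cost
            d = prev[j] + indel_cost
            e = cur[j - 1] + indel_cost
            if d < c:
                c = d
            if e < c:
                c = e
            cur[j] = c
        prev, cur = cur, prev
    return prev[n]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def weighted_edit_distance(a: str, b: str, sub_cost: int = 2, indel_cost: int = 1) -> int:
    """Minimum cost of editing ``a`` into ``b`` with weighted operations."""
    if sub_cost <= 0 or indel_cost <= 0:
        raise InvalidInputError("edit costs must be positive")
    return int(_edit_dp(_encode(a), _encode(b), sub_cost, indel_cost))


def lncrna_sequence_similarity(
    seqs: Sequence[SequenceRecord], sub_cost: int = 2, indel_cost: int = 1
) -> SimilarityMatrix:
    """Pairwise sequence similarity ``1 - dist / (len_i + len_j)``.

    ``dist`` is the minimum-cost weighted edit distance. A pair of two
    distinct empty sequences has a zero denominator and raises
    :class:`InvalidInputError`; the diagonal self-pair of an empty
    sequence is defined as 1.0 (self-similarity convention) so that a
    single empty record does not invalidate the whole matrix.
    """
    if not seqs:
        raise InvalidInputError("sequence list must be nonempty")
    if sub_cost <= 0 or indel_cost <= 0:
        raise InvalidInputError("edit costs must be positive")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("sequence ids must be unique")
    arrays = [_encode(s.sequence) for s in seqs]
    odd = set("".join(s.sequence.upper() for s in seqs)) - RNA_ALPHABET
    if odd:
        warnings.warn(
            f"sequences contain characters outside {{A,C,G,T,U}}: {sorted(odd)}; "
            "treated as ordinary symbols by the edit distance",
            stacklevel=2,
        )
    n = len(seqs)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            denom = arrays[i].size + arrays[j].size
            if denom == 0:
                raise InvalidInputError(
                    f"both sequences empty for pair ({ids[i]!r}, {ids[j]!r}): "
                    "similarity denominator is zero"
                )
            dist = _edit_dp(arrays[i], arrays[j], sub_cost, indel_cost)
            values[i, j] = values[j, i] = 1.0 - dist / denom
    return SimilarityMatrix(ids, np.clip(values, 0.0, 1.0))


class DiseaseDAG:
    """Disease ontology as a DAG of child -> parent edges.

    Every declared node is a disease; roots are nodes with no parent.
    The ancestor set ``T(D)`` of a disease always contains the disease
    itself.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        self.nodes: tuple[str, ...] = tuple(nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise InvalidDAGError("duplicate disease identifiers in DAG")
        self.edges: tuple[tuple[str, str], ...] = tuple((c, p) for c, p in edges)
        for child, parent in self.edges:
            if child not in node_set or parent not in node_set:
                raise InvalidDAGError(
                    f"edge ({child!r}, {parent!r}) references an undeclared disease"
                )
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)  # child -> parent direction
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidDAGError("disease ontology contains a cycle")
        self._graph = g
        self._parents: dict[str, list[str]] = {n: sorted(g.successors(n)) for n in self.nodes}

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if not self._parents[n])

    def parents(self, node: str) -> list[str]:
        if node not in self._parents:
            raise LookupError(f"disease {node!r} not present in the DAG")
        return self._parents[node]

    def ancestor_contributions(self, disease: str) -> dict[str, float]:
        """Decayed contribution of every ancestor (including self).

        The contribution of ancestor ``d`` to disease ``D`` is the max
        over ancestor paths of ``decay**len(path)``, which equals
        ``decay**shortest_path`` for a constant decay < 1; computed by
        breadth-first search over parent links.
        """
        if disease not in self._parents:
            raise LookupError(f"disease {disease!r} not present in the DAG")
        contrib: dict[str, float] = {disease: 1.0}
        frontier = [disease]
        value = 1.0
        while frontier:
            value *= SEMANTIC_DECAY
            nxt = []
            for node in frontier:
                for parent in self._parents[node]:
                    if parent not in contrib:
                        contrib[parent] = value
                        nxt.append(parent)
            frontier = nxt
        return contrib


def disease_semantic_similarity(
    dag: DiseaseDAG, diseases: Sequence[str]
) -> SimilarityMatrix:
    """Wang semantic similarity over the ancestor overlap of disease pairs.

    ``DSS(i, j) = sum_{t in T(i) & T(j)} (D_i(t) + D_j(t)) / (DV(i) + DV(j))``
    with ``DV(D)`` the total decayed contribution of ``T(D)``.
    """
    contribs = [dag.ancestor_contributions(d) for d in diseases]
    dv = np.array([sum(c.values()) for c in contribs])
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        ci = contribs[i]
        for j in range(i + 1, n):
            cj = contribs[j]
            common = ci.keys() & cj.keys()
            if common:
                num = sum(ci[t] + cj[t] for t in common)
                values[i, j] = values[j, i] = num / (dv[i] + dv[j])
    return SimilarityMatrix(diseases, values)


def gip_kernel_similarity(
    assoc: np.ndarray,
    orientation: str = "rows",
    node_ids: Sequence[str] | None = None,
) -> SimilarityMatrix | np.ndarray:
    """Gaussian interaction profile kernel over binary association profiles.

    The bandwidth is ``xi = 1 / mean(||profile||^2)`` and the kernel is
    ``exp(-xi * ||profile_i - profile_j||^2)``. ``orientation='rows'``
    treats matrix rows as profiles (lncRNAs); ``'columns'`` uses columns
    (diseases). Returns a plain symmetric array with unit diagonal, or a
    :class:`SimilarityMatrix` when ``node_ids`` is given.
    """
    assoc = np.asarray(assoc, dtype=float)
    if assoc.ndim != 2:
        raise InvalidInputError("association matrix must be 2-D")
    if not np.isin(assoc, (0.0, 1.0)).all():
        raise InvalidInputError("association matrix must be binary")
    if orientation == "rows":
        profiles = assoc
    elif orientation == "columns":
        profiles = assoc.T
    else:
        raise InvalidInputError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    norms = (profiles**2).sum(axis=1)
    total = norms.mean()
    if total == 0.0:
        raise DegenerateInputError(
            "all-zero association matrix: GIP bandwidth is undefined"
        )
    xi = 1.0 / total
    sq = norms[:, None] + norms[None, :] - 2.0 * profiles @ profiles.T
    np.clip(sq, 0.0, None, out=sq)
    kernel = np.exp(-xi * sq)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    if node_ids is not None:
        return SimilarityMatrix(node_ids, kernel)
    return kernel


@dataclass(frozen=True)
class FusionConfig:
    """Weights of the linear similarity fusion.

    ``alpha`` weighs the semantic similarity against the GIP kernel;
    ``divisor`` is the trailing division (2 as printed, so fused values
    max out at 0.5 — a uniform scale absorbed by the learned projection).
    """

    alpha: float = 0.5
    divisor: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidInputError("alpha must lie in [0, 1]")
        if self.divisor <= 0:
            raise InvalidInputError("divisor must be positive")


def fuse_similarities(
    a: SimilarityMatrix,
    b: SimilarityMatrix | np.ndarray,
    cfg: FusionConfig | None = None,
) -> SimilarityMatrix:
    """Entry-wise ``(alpha * a + (1 - alpha) * b) / divisor``."""
    cfg = cfg or FusionConfig()
    if isinstance(b, SimilarityMatrix):
        if b.node_ids != a.node_ids:
            raise AlignmentError("similarity matrices do not share node ids/order")
        b_values = b.values
    else:
        b_values = np.asarray(b, dtype=float)
        if b_values.shape != a.values.shape:
            raise AlignmentError("similarity matrices do not share shape")
    fused = (cfg.alpha * a.values + (1.0 - cfg.alpha) * b_values) / cfg.divisor
    return SimilarityMatrix(a.node_ids, fused)
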