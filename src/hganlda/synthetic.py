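"""Self-contained synthetic datasets with planted block structure.

The generator emulates the statistical structure the model exploits:
lncRNAs, diseases and miRNAs share a common block (community) partition;
association matrices are Bernoulli with a higher rate inside matched
blocks than between blocks, sequences within a lncRNA block descend
from a common ancestor sequence, and the disease ontology groups
block-mates under shared ancestors. Held-out links are therefore
statistically recoverable from the remaining data.

All randomness flows from the single spec seed; regeneration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graphs import HeteroGraph
from .similarity import DiseaseDAG, SequenceRecord

__all__ = ["SyntheticSpec", "Dataset", "generate_sequences", "generate_dag",
           "generate_associations", "generate_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

RNA_BASES = np.frombuffer(b"ACGU", dtype=np.uint8)
DNA_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a planted-block dataset.

    Defaults give 120 lncRNAs, 80 diseases and 60 miRNAs in 6 shared
    blocks, within-block association probability 0.3 versus 0.02
    between blocks, 100-180 nt sequences diverging at 5% per base
    within a cluster. ``scramble_associations`` destroys the planted
    structure by uniformly permuting the entries of every association
    matrix (density preserved) — the signal-free control.
    """

    n_lnc: int = 120
    n_dis: int = 80
    n_mir: int = 60
    n_blocks: int = 6
    p_in: float = 0.3
    p_out: float = 0.02
    # optional per-matrix overrides (lncRNA-miRNA / miRNA-disease) so real
    # datasets' very different sparsities can be emulated; default to p_in/p_out
    p_in_lm: float | None = None
    p_out_lm: float | None = None
    p_in_md: float | None = None
    p_out_md: float | None = None
    seq_len_range: tuple[int, int] = (100, 180)
    mutation_rate: float = 0.05
    dag_branching: int = 3
    alphabet: str = "rna"
    scramble_associations: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lnc, self.n_dis, self.n_mir, self.n_blocks) < 1:
            raise ValueError("node and block counts must be positive")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for suffix in ("lm", "md"):
            p_in = getattr(self, f"p_in_{suffix}")
            p_out = getattr(self, f"p_out_{suffix}")
            if (p_in is None) != (p_out is None):
                raise ValueError(f"p_in_{suffix} and p_out_{suffix} must be set together")
            if p_in is not None and not 0.0 <= p_out < p_in <= 1.0:
                raise ValueError(f"need 0 <= p_out_{suffix} < p_in_{suffix} <= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.alphabet not in ("rna", "dna"):
            raise ValueError("alphabet must be 'rna' or 'dna'")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Round-robin block assignment (deterministic, near-equal sizes)."""
    return np.arange(n) % n_blocks


def generate_sequences(spec: SyntheticSpec) -> list[SequenceRecord]:
    """Clustered nucleotide sequences: per-block ancestors plus mutations."""
    rng = spec._rng(1)
    bases = RNA_BASES if spec.alphabet == "rna" else DNA_BASES
    blocks = _blocks(spec.n_lnc, spec.n_blocks)
    lo, hi = spec.seq_len_range
    ancestors = [
        rng.choice(bases, size=int(rng.integers(lo, hi + 1)))
        for _ in range(spec.n_blocks)
    ]
    records = []
    for i in range(spec.n_lnc):
        seq = ancestors[blocks[i]].copy()
        mutate = rng.random(seq.size) < spec.mutation_rate
        if mutate.any():
            # substitute each mutated base with one of the three others
            offsets = rng.integers(1, 4, size=int(mutate.sum()))
            positions = np.searchsorted(bases, seq[mutate])
            seq[mutate] = bases[(positions + offsets) % 4]
        records.append(SequenceRecord(f"l{i:03d}", seq.tobytes().decode("ascii")))
    return records


def generate_dag(spec: SyntheticSpec) -> DiseaseDAG:
    """Rooted random tree over diseases grouping block-mates together.

    The first disease of block 0 is the global root; the first disease
    of every other block attaches to it; remaining diseases attach to an
    earlier disease of their own block with fewer than ``dag_branching``
    children, so block-mates share close ancestors.
    """
    rng = spec._rng(2)
    ids = [f"d{i:03d}" for i in range(spec.n_dis)]
    blocks = _blocks(spec.n_dis, spec.n_blocks)
    edges: list[tuple[str, str]] = []
    child_count = np.zeros(spec.n_dis, dtype=int)
    block_root: dict[int, int] = {}
    for i in range(spec.n_dis):
        b = int(blocks[i])
        if b not in block_root:
            block_root[b] = i
            if i != 0:
                edges.append((ids[i], ids[0]))
                child_count[0] += 1
            continue
        candidates = [
            j
            for j in range(i)
            if blocks[j] == b and child_count[j] < spec.dag_branching
        ] or [block_root[b]]
        parent = int(candidates[rng.integers(len(candidates))])
        edges.append((ids[i], ids[parent]))
        child_count[parent] += 1
    return DiseaseDAG(ids, edges)


def _planted(rng, n_rows, n_cols, blocks_rows, blocks_cols, p_in, p_out) -> np.ndarray:
    prob = np.where(blocks_rows[:, None] == blocks_cols[None, :], p_in, p_out)
    return (rng.random((n_rows, n_cols)) < prob).astype(np.int8)


def _repair(mat: np.ndarray, blocks_rows, blocks_cols, rng, name: str) -> None:
    """Give every isolated row/column one within-block association."""
    repaired = 0
    for i in np.flatnonzero(mat.sum(axis=1) == 0):
        mates = np.flatnonzero(blocks_cols == blocks_rows[i])
        if mates.size == 0:
            mates = np.arange(mat.shape[1])
        mat[i, mates[rng.integers(mates.size)]] = 1
        repaired += 1
    for j in np.flatnonzero(mat.sum(axis=0) == 0):
        mates = np.flatnonzero(blocks_rows == blocks_cols[j])
        if mates.size == 0:
            mates = np.arange(mat.shape[0])
        mat[mates[rng.integers(mates.size)], j] = 1
        repaired += 1
    if repaired:
        logger.info("repaired %d isolated nodes in %s", repaired, name)


def generate_associations(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-aligned Bernoulli association matrices (E_ld, E_lm, E_md)."""
    rng = spec._rng(3)
    bl = _blocks(spec.n_lnc, spec.n_blocks)
    bd = _blocks(spec.n_dis, spec.n_blocks)
    bm = _blocks(spec.n_mir, spec.n_blocks)
    p_in_lm = spec.p_in if spec.p_in_lm is None else spec.p_in_lm
    p_out_lm = spec.p_out if spec.p_out_lm is None else spec.p_out_lm
    p_in_md = spec.p_in if spec.p_in_md is None else spec.p_in_md
    p_out_md = spec.p_out if spec.p_out_md is None else spec.p_out_md
    E_ld = _planted(rng, spec.n_lnc, spec.n_dis, bl, bd, spec.p_in, spec.p_out)
    E_lm = _planted(rng, spec.n_lnc, spec.n_mir, bl, bm, p_in_lm, p_out_lm)
    E_md = _planted(rng, spec.n_mir, spec.n_dis, bm, bd, p_in_md, p_out_md)
    if spec.scramble_associations:
        srng = spec._rng(4)
        for mat in (E_ld, E_lm, E_md):
            flat = srng.permutation(mat.reshape(-1))
            mat[...] = flat.reshape(mat.shape)
    _repair(E_ld, bl, bd, rng, "E_ld")
    _repair(E_lm, bl, bm, rng, "E_lm")
    _repair(E_md, bm, bd, rng, "E_md")
    return E_ld, E_lm, E_md


@dataclass
class Dataset:
    """In-memory synthetic dataset: sequences, ontology and associations."""

    sequences: list[SequenceRecord]
    dag: DiseaseDAG
    hetero: HeteroGraph
    spec: SyntheticSpec


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Generate the full dataset from one spec (and its single seed)."""
    sequences = generate_sequences(spec)
    dag = generate_dag(spec)
    E_ld, E_lm, E_md = generate_associations(spec)
    hetero = HeteroGraph(
        [s.id for s in sequences],
        list(dag.nodes),
        [f"m{i:03d}" for i in range(spec.n_mir)],
        E_ld,
        E_lm,
        E_md,
    )
    return Dataset(sequences, dag, hetero, spec)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write the dataset in the on-disk layout the io readers consume."""
    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_fasta(dataset.sequences, out / "sequences.fasta")
    io_mod.write_dag(dataset.dag, out / "disease_dag.tsv")
    h = dataset.hetero
    io_mod.write_node_list(h.lnc_ids, out / "lncRNAs.txt")
    io_mod.write_node_list(h.dis_ids, out / "diseases.txt")
    io_mod.write_node_list(h.mir_ids, out / "miRNAs.txt")
    io_mod.write_edge_list(h.E_ld, h.lnc_ids, h.dis_ids, out / "lnc_dis.tsv")
    io_mod.write_edge_list(h.E_lm, h.lnc_ids, h.mir_ids, out / "lnc_mir.tsv")
    io_mod.write_edge_list(h.E_md, h.mir_ids, h.dis_ids, out / "mir_dis.tsv")
    manifest = {
        "format": "hganlda-dataset-v1",
        "spec": dataclasses.asdict(dataset.spec),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
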