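"""Readers/writers for the on-disk formats and the pipeline entry point.

All tabular interchange is UTF-8 TSV with a header row; node universes
are explicit one-id-per-line files so isolated nodes stay representable;
sequences travel as FASTA. ``run_pipeline`` ties the stages together:
similarities -> graphs -> hierarchical attention -> cross-validated
prediction, writing metrics, ROC/PR coordinates, a trained checkpoint
and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .graphs import HeteroGraph
from .model import ModelConfig
from .similarity import (
    DiseaseDAG,
    FusionConfig,
    SequenceRecord,
    SimilarityMatrix,
    disease_semantic_similarity,
    lncrna_sequence_similarity,
)
from .synthetic import Dataset, SyntheticSpec

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_node_list",
    "write_node_list",
    "read_edge_list",
    "write_edge_list",
    "read_dag",
    "write_dag",
    "write_similarity",
    "read_similarity",
    "load_dataset",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


# -- sequences -------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; ids are the first header token, order preserved."""
    path = Path(path)
    text_lines = path.read_text().splitlines()
    first_content = next(
        ((i, ln) for i, ln in enumerate(text_lines) if ln.strip()), None
    )
    if first_content is None:
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    if not first_content[1].lstrip().startswith(">"):
        raise ParseError(
            f"{path}: malformed FASTA header at line {first_content[0] + 1}"
        )
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found (line 1)")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# -- node universes and edge lists -----------------------------------------

def read_node_list(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate node identifiers")
    return ids


def write_node_list(ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def read_edge_list(
    path: str | Path, left_universe, right_universe
) -> np.ndarray:
    """Binary matrix from a two-column TSV of (left id, right id) edges.

    Duplicate edges collapse to a single entry with a warning; ids not
    in the universes raise a :class:`ParseError` listing them.
    """
    left_index = {n: i for i, n in enumerate(left_universe)}
    right_index = {n: i for i, n in enumerate(right_universe)}
    matrix = np.zeros((len(left_index), len(right_index)), dtype=np.int8)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if df.empty:
        return matrix
    unknown = sorted(
        set(df.iloc[:, 0]) - left_index.keys() | set(df.iloc[:, 1]) - right_index.keys()
    )
    if unknown:
        raise ParseError(f"{path}: unknown identifiers {unknown}")
    if df.duplicated().any():
        warnings.warn(
            f"{path}: {int(df.duplicated().sum())} duplicate edges collapsed",
            stacklevel=2,
        )
        df = df.drop_duplicates()
    rows = df.iloc[:, 0].map(left_index).to_numpy()
    cols = df.iloc[:, 1].map(right_index).to_numpy()
    matrix[rows, cols] = 1
    return matrix


def write_edge_list(matrix, left_ids, right_ids, path: str | Path,
                    columns=("source", "target")) -> None:
    rows, cols = np.nonzero(np.asarray(matrix))
    pd.DataFrame(
        {columns[0]: [left_ids[i] for i in rows], columns[1]: [right_ids[j] for j in cols]}
    ).to_csv(path, sep="\t", index=False)


# -- ontology ---------------------------------------------------------------

def read_dag(path: str | Path, nodes=None) -> DiseaseDAG:
    """DAG from a child<TAB>parent TSV; the node set defaults to all ids seen."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    edges = list(df.itertuples(index=False, name=None))
    if nodes is None:
        seen: list[str] = []
        for c, p in edges:
            for n in (c, p):
                if n not in seen:
                    seen.append(n)
        nodes = seen
    return DiseaseDAG(nodes, edges)


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    pd.DataFrame(dag.edges, columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False
    )


# -- similarity matrices ----------------------------------------------------

def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    sim.to_frame().to_csv(path, sep="\t", index_label="id")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.index), df.to_numpy(float))


# -- datasets ---------------------------------------------------------------

def load_dataset(data_dir: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`synthetic.write_dataset`."""
    d = Path(data_dir)
    sequences = read_fasta(d / "sequences.fasta")
    lnc_ids = read_node_list(d / "lncRNAs.txt")
    dis_ids = read_node_list(d / "diseases.txt")
    mir_ids = read_node_list(d / "miRNAs.txt")
    dag = read_dag(d / "disease_dag.tsv", nodes=dis_ids)
    hetero = HeteroGraph(
        lnc_ids,
        dis_ids,
        mir_ids,
        read_edge_list(d / "lnc_dis.tsv", lnc_ids, dis_ids),
        read_edge_list(d / "lnc_mir.tsv", lnc_ids, mir_ids),
        read_edge_list(d / "mir_dis.tsv", mir_ids, dis_ids),
    )
    spec = None
    manifest = d / "manifest.json"
    if manifest.exists():
        raw = json.loads(manifest.read_text()).get("spec", {})
        if "seq_len_range" in raw:
            raw["seq_len_range"] = tuple(raw["seq_len_range"])
        spec = SyntheticSpec(**raw)
    return Dataset(sequences, dag, hetero, spec)


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level configuration for a pipeline run."""

    data_dir: str = "."
    out_dir: str = "run"
    n_folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    mask_test_edges: bool = True
    gip_per_fold: bool = True
    max_epochs: int | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Strict YAML config loader; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    model_raw = raw.pop("model", {}) or {}
    fusion_raw = raw.pop("fusion", {}) or {}
    for section, cls in (("model", ModelConfig), ("fusion", FusionConfig)):
        data = model_raw if section == "model" else fusion_raw
        bad = set(data) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ParseError(f"{path}: unknown {section} keys {sorted(bad)}")
    return RunConfig(model=ModelConfig(**model_raw), fusion=FusionConfig(**fusion_raw), **raw)


# -- pipeline ---------------------------------------------------------------

def compute_similarities(dataset: Dataset):
    """Sequence and semantic similarity matrices for a loaded dataset."""
    lss = lncrna_sequence_similarity(dataset.sequences)
    if tuple(lss.node_ids) != tuple(dataset.hetero.lnc_ids):
        raise ParseError("FASTA ids do not match the lncRNA universe order")
    dss = disease_semantic_similarity(dataset.dag, dataset.hetero.dis_ids)
    return lss, dss


def run_pipeline(cfg: RunConfig):
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    from . import __version__
    from .train_eval import cross_validate

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(cfg.data_dir)
    logger.info("stage 1/4: similarity matrices")
    lss, dss = compute_similarities(dataset)
    logger.info("stage 2-4: cross-validated training and prediction")
    report = cross_validate(
        dataset.hetero,
        lss,
        dss,
        cfg.model,
        n_folds=cfg.n_folds,
        seed=cfg.seed,
        fusion=cfg.fusion,
        threshold=cfg.threshold,
        mask_test_edges=cfg.mask_test_edges,
        gip_per_fold=cfg.gip_per_fold,
        max_epochs=cfg.max_epochs,
    )
    report.to_frame().to_csv(out / "metrics.tsv", sep="\t")
    for i, (probs, labels) in enumerate(report.fold_scores, start=1):
        pd.DataFrame({"score": probs, "label": labels}).to_csv(
            out / f"scores_fold{i}.tsv", sep="\t", index=False
        )
    _write_curves(report, out)
    manifest = {
        "package": "hganlda",
        "version": __version__,
        "numpy": np.__version__,
        "config": cfg.to_dict(),
        "mean_metrics": report.mean,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return report


def _write_curves(report, out: Path) -> None:
    from sklearn.metrics import precision_recall_curve, roc_curve

    probs = np.concatenate([p for p, _ in report.fold_scores])
    labels = np.concatenate([l for _, l in report.fold_scores])
    if labels.min() != labels.max():
        fpr, tpr, _ = roc_curve(labels, probs)
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(out / "roc.tsv", sep="\t", index=False)
        prec, rec, _ = precision_recall_curve(labels, probs)
        pd.DataFrame({"recall": rec, "precision": prec}).to_csv(
            out / "pr.tsv", sep="\t", index=False
        )
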