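"""Readers, writers and the nested pipeline configuration.

Input is a character-separated table with an identifier column ("MR No")
and a free-text report column ("Hist_report"); column names and separator
are configurable.  All artefacts are plain text: character-separated
tables for features, scores, edges, ROC/calibration points and history;
JSON for metrics, the run manifest and the model hyperparameter manifest;
a coordinate-format sparse file for the adjacency matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .encoder import EncoderConfig, ReportRecord
from .synthetic import SyntheticConfig
from .training import EvalReport, TrainConfig

log = logging.getLogger("bgmbc")

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_reports_table",
    "write_reports_table",
    "read_labels",
    "write_labels",
    "write_feature_table",
    "read_feature_table",
    "write_scores",
    "read_scores",
    "write_edge_list",
    "read_edge_list",
    "write_adjacency_mtx",
    "write_eval_report",
    "write_points_table",
    "write_history",
    "sha256_file",
]


class SchemaError(ValueError):
    """An input table does not match the declared schema."""


# -- configuration --------------------------------------------------------


@dataclass
class GraphConfig:
    node_threshold: float = 200.0
    node_connections: int = 5
    symmetrise: bool = True
    class_source: str = "centroid"  # centroid | true_labels

    def __post_init__(self) -> None:
        if self.class_source not in ("centroid", "true_labels"):
            raise ValueError("class_source must be 'centroid' or 'true_labels'")


@dataclass
class SelectionConfig:
    top_k: int = 30
    n_trees: int = 100
    seed: int = 0
    shap_max_records: int = 256


@dataclass
class ModelConfig:
    hidden_units: tuple[int, int] = (34, 34)
    aggregation: str = "sum"
    dropout: float = 0.2
    ffn_stack_depth: int = 3


@dataclass
class InputConfig:
    path: str | None = None
    id_column: str = "MR No"
    text_column: str = "Hist_report"
    label_column: str | None = None
    sep: str = ","


@dataclass
class PipelineConfig:
    """Nested configuration for the full pipeline; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "bgmbc_out"
    verbosity: str = "info"  # quiet | info | debug
    synthetic: bool = True
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synthetic_data: SyntheticConfig = field(default_factory=SyntheticConfig)
    input: InputConfig = field(default_factory=InputConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a nested dict, rejecting unknown keys at every level."""
        sections = {
            "encoder": EncoderConfig,
            "selection": SelectionConfig,
            "graph": GraphConfig,
            "model": ModelConfig,
            "train": TrainConfig,
            "synthetic_data": SyntheticConfig,
            "input": InputConfig,
        }
        top = {f.name for f in fields(cls)}
        unknown = set(raw) - top
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                klass = sections[key]
                known = {f.name for f in fields(klass)}
                bad = set(value) - known
                if bad:
                    raise ValueError(
                        f"unknown keys under '{key}': {sorted(bad)}"
                    )
                value = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = klass(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# -- report tables --------------------------------------------------------


def read_reports_table(
    path: str | Path,
    id_column: str = "MR No",
    text_column: str = "Hist_report",
    sep: str = ",",
    keep_blank: bool = False,
) -> list[ReportRecord]:
    """Read the two-column patient report table.

    Rows with a missing identifier or (by default) blank report text are
    dropped with a logged message; duplicate identifiers are an error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in (id_column, text_column) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records: list[ReportRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rid = row[id_column]
        text = row[text_column]
        if pd.isna(rid) or not str(rid).strip():
            log.info("dropping row %d: missing identifier", i)
            continue
        rid = str(rid).strip()
        if pd.isna(text) or not str(text).strip():
            if not keep_blank:
                log.info("dropping row %d (%s): blank report text", i, rid)
                continue
            text = ""
        if rid in seen:
            raise SchemaError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(ReportRecord(record_id=rid, text=str(text)))
    return records


def write_reports_table(
    path: str | Path,
    records: list[ReportRecord],
    id_column: str = "MR No",
    text_column: str = "Hist_report",
    sep: str = ",",
) -> None:
    pd.DataFrame(
        {id_column: [r.record_id for r in records],
         text_column: [r.text for r in records]}
    ).to_csv(path, sep=sep, index=False)


def write_labels(path: str | Path, record_ids: list[str], labels: np.ndarray) -> None:
    pd.DataFrame({"record_id": record_ids, "label": labels}).to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={"record_id": str})
    return df["record_id"].tolist(), df["label"].to_numpy(dtype=np.int64)


# -- numeric artefacts ----------------------------------------------------


def write_feature_table(
    path: str | Path, record_ids: list[str], X: np.ndarray, column_ids=None
) -> None:
    """One row per record; columns f0..f(p-1) unless ids are given."""
    cols = column_ids or [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "record_id", record_ids)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, dtype={"record_id": str})
    ids = df.pop("record_id").tolist()
    return ids, df.to_numpy(dtype=np.float64), list(df.columns)


def write_scores(path: str | Path, record_ids: list[str], scores: np.ndarray) -> None:
    pd.DataFrame({"record_id": record_ids, "score": scores}).to_csv(path, index=False)


def read_scores(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={"record_id": str})
    return df["record_id"].tolist(), df["score"].to_numpy(dtype=np.float64)


def write_edge_list(path: str | Path, graph) -> None:
    """Tab-separated (source record_id, target record_id), one edge per line."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in graph.edges:
            fh.write(f"{graph.record_ids[s]}\t{graph.record_ids[t]}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["source", "target"]:
        raise SchemaError(f"{path}: expected 'source'/'target' header")
    return list(df.itertuples(index=False, name=None))


def write_adjacency_mtx(path: str | Path, graph) -> None:
    """Adjacency of the message-passing edges in MatrixMarket coordinate form."""
    import scipy.io
    import scipy.sparse

    e = graph.message_edges()
    n = graph.n_nodes
    mat = scipy.sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    scipy.io.mmwrite(str(path), mat)


def write_eval_report(path: str | Path, report: EvalReport) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def write_points_table(path: str | Path, points, columns) -> None:
    pd.DataFrame(points, columns=columns).to_csv(path, index=False)


def write_history(path: str | Path, history: list[dict]) -> None:
    pd.DataFrame(history).to_csv(path, index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
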