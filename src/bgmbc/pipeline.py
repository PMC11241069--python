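"""End-to-end pipeline: encode -> select -> build graph -> train -> evaluate.

Every stage writes its artefact into the configured output directory, and
a run manifest (configuration, seed, content hashes of every artefact)
closes the run.  Identical configuration + seed reproduces every metric
file byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as bio
from .encoder import extract_report_features, node_attention_score, tokenise_report
from .estimators import BGMBCClassifier
from .io import PipelineConfig
from .selection import FeatureTable, normalise_features, select_features
from .synthetic import generate_reports
from .training import split_dataset

log = logging.getLogger("bgmbc")

__all__ = ["run_pipeline", "encode_reports", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def encode_reports(records, encoder_cfg):
    """Encode every report: (features matrix, attention scores) per record."""
    feats = []
    scores = []
    for rec in records:
        rf = extract_report_features(rec, encoder_cfg)
        tok = tokenise_report(
            rec.text, encoder_cfg.max_len, vocab_size=encoder_cfg.vocab_size
        )
        from .encoder import encode_report

        out = encode_report(tok, encoder_cfg)
        sc = node_attention_score(
            out, tok.pad_mask, record_id=rec.record_id, mode=encoder_cfg.score_mode
        )
        feats.append(rf.values)
        scores.append(sc.score)
    return np.asarray(feats), np.asarray(scores)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns a dict of artefact paths and metrics."""
    level = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}
    logging.basicConfig(level=level.get(cfg.verbosity, logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, str] = {}

    @_stage("load")
    def load():
        if cfg.synthetic:
            import dataclasses

            syn = dataclasses.replace(cfg.synthetic_data, seed=cfg.seed)
            records, labels = generate_reports(syn)
            bio.write_reports_table(out / "reports.csv", records)
            bio.write_labels(out / "labels.csv", [r.record_id for r in records], labels)
            artefacts["reports"] = str(out / "reports.csv")
            artefacts["labels"] = str(out / "labels.csv")
            return records, labels
        if cfg.input.path is None:
            raise ValueError("no input path configured and synthetic=False")
        records = bio.read_reports_table(
            cfg.input.path,
            id_column=cfg.input.id_column,
            text_column=cfg.input.text_column,
            sep=cfg.input.sep,
        )
        if cfg.input.label_column is None:
            raise ValueError("training requires a label column or synthetic data")
        import pandas as pd

        df = pd.read_csv(cfg.input.path, sep=cfg.input.sep, dtype=str)
        kept = {r.record_id for r in records}
        df = df[df[cfg.input.id_column].isin(kept)]
        labels = df[cfg.input.label_column].to_numpy(dtype=np.int64)
        return records, labels

    records, labels = load()
    record_ids = [r.record_id for r in records]
    log.info("loaded %d records", len(records))

    @_stage("encode")
    def encode():
        X, scores = encode_reports(records, cfg.encoder)
        bio.write_feature_table(out / "features.csv", record_ids, X)
        bio.write_scores(out / "scores.csv", record_ids, scores)
        artefacts["features"] = str(out / "features.csv")
        artefacts["scores"] = str(out / "scores.csv")
        return X, scores

    X, scores = encode()
    log.info("encoded %d reports to width %d", len(records), X.shape[1])

    train_idx, test_idx = split_dataset(
        labels, cfg.train.train_fraction, seed=cfg.seed
    )

    @_stage("select")
    def select():
        table = FeatureTable(
            X=X[train_idx],
            y=labels[train_idx],
            column_ids=[f"f{j}" for j in range(X.shape[1])],
            record_ids=[record_ids[i] for i in train_idx],
        )
        selected, report = select_features(
            table,
            k=cfg.selection.top_k,
            n_trees=cfg.selection.n_trees,
            seed=cfg.selection.seed,
            shap_max_records=cfg.selection.shap_max_records,
        )
        report.to_csv(out / "selection_report.csv", index=False)
        artefacts["selection_report"] = str(out / "selection_report.csv")
        return selected

    selected = select()
    sel_idx = [int(c[1:]) for c in selected]
    X_sel = normalise_features(X)[:, sel_idx]
    log.info("selected %d of %d columns", len(selected), X.shape[1])

    @_stage("graph")
    def build():
        clf = BGMBCClassifier.from_arrays(
            X_sel,
            scores,
            labels,
            record_ids=record_ids,
            train_idx=train_idx,
            node_threshold=cfg.graph.node_threshold,
            node_connections=cfg.graph.node_connections,
            use_true_labels=cfg.graph.class_source == "true_labels",
            hidden_units=cfg.model.hidden_units,
            aggregation=cfg.model.aggregation,
            dropout=cfg.model.dropout,
            ffn_stack_depth=cfg.model.ffn_stack_depth,
        )
        clf.graph.symmetrise = cfg.graph.symmetrise
        bio.write_edge_list(out / "edges.tsv", clf.graph)
        bio.write_adjacency_mtx(out / "adjacency.mtx", clf.graph)
        artefacts["edges"] = str(out / "edges.tsv")
        artefacts["adjacency"] = str(out / "adjacency.mtx")
        return clf

    clf = build()
    log.info("graph: %d nodes, %d directed edges", clf.graph.n_nodes, len(clf.graph.edges))

    @_stage("train")
    def fit():
        import dataclasses

        tcfg = dataclasses.replace(cfg.train, seed=cfg.seed, dropout=cfg.model.dropout)
        res = clf.fit(cfg=tcfg, train_idx=train_idx, test_idx=test_idx,
                      init_seed=cfg.seed)
        from .model import save_params

        save_params(res.params, out / "model")
        bio.write_history(out / "history.csv", res.history)
        artefacts["model"] = str(out / "model.npz")
        artefacts["model_manifest"] = str(out / "model.json")
        artefacts["history"] = str(out / "history.csv")
        return res

    res = fit()

    @_stage("evaluate")
    def evaluate():
        rep = res.evaluate()
        bio.write_eval_report(out / "metrics.json", rep)
        bio.write_points_table(out / "roc.csv", rep.roc_points, ["fpr", "tpr"])
        bio.write_points_table(
            out / "calibration.csv",
            rep.calibration,
            ["mean_predicted", "observed_frequency", "count"],
        )
        import pandas as pd

        pd.DataFrame(
            {
                "record_id": record_ids,
                "prob_class1": res.probs[:, 1],
                "predicted": res.predict(),
                "label": labels,
                "split": ["train" if i in set(train_idx.tolist()) else "test"
                          for i in range(len(record_ids))],
            }
        ).to_csv(out / "predictions.csv", index=False)
        artefacts["metrics"] = str(out / "metrics.json")
        artefacts["roc"] = str(out / "roc.csv")
        artefacts["calibration"] = str(out / "calibration.csv")
        artefacts["predictions"] = str(out / "predictions.csv")
        return rep

    rep = evaluate()
    log.info(
        "held-out accuracy %.3f, AUC %s", rep.accuracy,
        f"{rep.auc:.3f}" if rep.auc is not None else "n/a",
    )

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "artefacts": {k: bio.sha256_file(v) for k, v in artefacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artefacts["manifest"] = str(out / "manifest.json")
    return {
        "artefacts": artefacts,
        "metrics": rep.to_dict(),
        "out_dir": str(out),
        "results": res,
    }
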