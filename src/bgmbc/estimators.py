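"""High-level model objects: build from data, ``fit()``, inspect a Results object.

``BGMBCClassifier`` wraps the attention-graph node-classification network;
``BaselineClassifier`` wraps the skip-connected feedforward baseline.
Both follow the model/results idiom: the model object holds the data and
architecture choices, ``fit()`` runs training and returns a results object
carrying the fitted parameters, the training history, held-out metrics,
and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import GraphDataset, NodeRecord, assign_provisional_class, build_graph
from .model import (
    baseline_forward,
    init_baseline_params,
    init_model_params,
    model_forward,
)
from .training import (
    EvalReport,
    TrainConfig,
    compute_metrics,
    split_dataset,
    train,
    train_baseline,
)

__all__ = ["BGMBCClassifier", "BaselineClassifier", "NodeClassifierResults"]


class BGMBCClassifier:
    """Graph node classifier over an attention-derived patient graph.

    Parameters
    ----------
    graph
        The constructed :class:`~bgmbc.graph.GraphDataset`.
    labels
        True node labels; defaults to the classes stored on the graph.
    hidden_units, aggregation, dropout, ffn_stack_depth
        Architecture knobs (defaults: [34, 34], sum aggregation, 0.2, 3).
    """

    def __init__(
        self,
        graph: GraphDataset,
        labels: np.ndarray | None = None,
        hidden_units: tuple[int, int] = (34, 34),
        aggregation: str = "sum",
        dropout: float = 0.2,
        ffn_stack_depth: int = 3,
    ) -> None:
        self.graph = graph
        self.labels = np.asarray(
            graph.labels if labels is None else labels, dtype=np.int64
        )
        if len(self.labels) != graph.n_nodes:
            raise ValueError("labels must cover every node")
        self.hidden_units = tuple(hidden_units)
        self.aggregation = aggregation
        self.dropout = dropout
        self.ffn_stack_depth = ffn_stack_depth

    @classmethod
    def from_arrays(
        cls,
        features: np.ndarray,
        scores: np.ndarray,
        labels: np.ndarray,
        record_ids: list[str] | None = None,
        train_idx: np.ndarray | None = None,
        node_threshold: float = 200.0,
        node_connections: int = 5,
        use_true_labels: bool = False,
        **kwargs,
    ) -> "BGMBCClassifier":
        """Build the graph from per-node features, scores and labels.

        Provisional classes for grouping come from the nearest-centroid
        rule on ``train_idx`` labels unless ``use_true_labels`` is set
        (which leaks held-out labels into the graph).
        """
        features = np.asarray(features, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        scores = np.asarray(scores, dtype=np.float64)
        if record_ids is None:
            record_ids = [f"N{i:05d}" for i in range(len(labels))]
        if use_true_labels or train_idx is None:
            prov = labels
        else:
            prov = assign_provisional_class(scores, train_idx, labels[train_idx])
        nodes = [
            NodeRecord(record_ids[i], float(scores[i]), int(prov[i]), features[i])
            for i in range(len(labels))
        ]
        graph = build_graph(nodes, node_threshold, node_connections)
        return cls(graph, labels=labels, **kwargs)

    def fit(
        self,
        cfg: TrainConfig | None = None,
        train_idx: np.ndarray | None = None,
        test_idx: np.ndarray | None = None,
        init_seed: int = 0,
    ) -> "NodeClassifierResults":
        """Train and return a results object with held-out metrics."""
        cfg = cfg or TrainConfig(dropout=self.dropout)
        if train_idx is None:
            train_idx, test_idx = split_dataset(
                self.labels, cfg.train_fraction, seed=cfg.seed
            )
        params = init_model_params(
            n_features=self.graph.features.shape[1],
            hidden_units=self.hidden_units,
            aggregation=self.aggregation,
            dropout=cfg.dropout,
            ffn_stack_depth=self.ffn_stack_depth,
            seed=init_seed,
        )
        params, history = train(
            self.graph, self.labels, train_idx, cfg, params=params
        )
        probs = model_forward(
            self.graph.features, self.graph.message_edges(), params
        )
        return NodeClassifierResults(
            model=self,
            params=params,
            history=history,
            probs=probs,
            train_idx=np.asarray(train_idx),
            test_idx=None if test_idx is None else np.asarray(test_idx),
            cfg=cfg,
        )


class BaselineClassifier:
    """Skip-connected feedforward classifier on node features alone."""

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        width: int = 34,
        dropout: float = 0.2,
        ffn_stack_depth: int = 3,
        n_iterations: int = 4,
    ) -> None:
        self.features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.width = width
        self.dropout = dropout
        self.ffn_stack_depth = ffn_stack_depth
        self.n_iterations = n_iterations

    def fit(
        self,
        cfg: TrainConfig | None = None,
        train_idx: np.ndarray | None = None,
        test_idx: np.ndarray | None = None,
        init_seed: int = 0,
    ) -> "NodeClassifierResults":
        cfg = cfg or TrainConfig(dropout=self.dropout)
        if train_idx is None:
            train_idx, test_idx = split_dataset(
                self.labels, cfg.train_fraction, seed=cfg.seed
            )
        params = init_baseline_params(
            n_features=self.features.shape[1],
            width=self.width,
            dropout=cfg.dropout,
            ffn_stack_depth=self.ffn_stack_depth,
            n_iterations=self.n_iterations,
            seed=init_seed,
        )
        params, history = train_baseline(
            self.features, self.labels, train_idx, cfg, params=params
        )
        probs = baseline_forward(self.features, params)
        return NodeClassifierResults(
            model=self,
            params=params,
            history=history,
            probs=probs,
            train_idx=np.asarray(train_idx),
            test_idx=None if test_idx is None else np.asarray(test_idx),
            cfg=cfg,
        )


class NodeClassifierResults:
    """Fitted parameters, history, and evaluation helpers."""

    def __init__(self, model, params, history, probs, train_idx, test_idx, cfg):
        self.model = model
        self.params = params
        self.history = history
        self.probs = probs
        self.train_idx = train_idx
        self.test_idx = test_idx
        self.cfg = cfg

    @property
    def labels(self) -> np.ndarray:
        return self.model.labels

    def predict(self) -> np.ndarray:
        return self.probs.argmax(axis=1)

    def evaluate(self, idx: np.ndarray | None = None) -> EvalReport:
        """Metrics on a node subset (default: the held-out test set)."""
        if idx is None:
            idx = self.test_idx
        if idx is None:
            idx = np.arange(len(self.labels))
        return compute_metrics(self.labels[idx], self.probs[idx])

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def summary(self) -> str:
        """Plain-text summary table in the model/results idiom."""
        kind = self.params.hyper.get("kind", "?")
        lines = [
            "=" * 62,
            f"{'BG-MBC node classifier' if kind == 'bgmbc' else 'Baseline feedforward classifier':^62}",
            "=" * 62,
            f"{'No. nodes:':<28}{len(self.labels):>10}",
            f"{'No. training nodes:':<28}{len(self.train_idx):>10}",
        ]
        if kind == "bgmbc":
            g = self.model.graph
            lines += [
                f"{'No. edges (directed):':<28}{len(g.edges):>10}",
                f"{'Aggregation:':<28}{self.model.aggregation:>10}",
                f"{'Hidden units:':<28}{str(list(self.model.hidden_units)):>10}",
            ]
        lines += [
            f"{'Epochs run:':<28}{len(self.history):>10}",
            f"{'Final train loss:':<28}{self.history[-1]['train_loss']:>10.4f}",
            f"{'Best validation accuracy:':<28}{max(h['val_acc'] for h in self.history):>10.4f}",
        ]
        if self.test_idx is not None and self.test_idx.size:
            rep = self.evaluate()
            lines += [
                "-" * 62,
                f"{'Held-out accuracy:':<28}{rep.accuracy:>10.4f}",
                f"{'Held-out balanced acc.:':<28}{rep.balanced_accuracy:>10.4f}",
                f"{'Held-out F1 (class 1):':<28}{rep.f1:>10.4f}",
                f"{'Held-out AUC:':<28}{(rep.auc if rep.auc is not None else float('nan')):>10.4f}",
            ]
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve on the held-out set (matplotlib axes returned)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rep = self.evaluate()
        if ax is None:
            _, ax = plt.subplots()
        xs = [p[0] for p in rep.roc_points]
        ys = [p[1] for p in rep.roc_points]
        ax.plot(xs, ys, marker=".", label=f"AUC = {rep.auc:.3f}")
        ax.plot([0, 1], [0, 1], "--", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def plot_calibration(self, ax=None):
        """Reliability diagram on the held-out set."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rep = self.evaluate()
        if ax is None:
            _, ax = plt.subplots()
        xs = [b[0] for b in rep.calibration]
        ys = [b[1] for b in rep.calibration]
        ax.plot(xs, ys, marker="o")
        ax.plot([0, 1], [0, 1], "--", color="grey")
        ax.set_xlabel("mean predicted probability")
        ax.set_ylabel("observed frequency")
        return ax
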