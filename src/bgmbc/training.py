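"""Splitting, learning-rate finding, training loops, and evaluation metrics.

The graph model trains full-batch (every step is one full-graph forward
pass; mini-batching is incompatible with whole-graph convolution), with
Adam on an integer-label cross-entropy loss and early stopping on a
held-out validation slice of the training split.  The feedforward baseline
and the learning-rate range test use mini-batches (default size 128).

Metrics follow fixed conventions: accuracy at the 0.5 threshold, balanced
accuracy as the mean of per-class recalls, F1 of the positive class, ROC
by threshold sweep over the unique scores plus sentinels with trapezoidal
AUC (ties earn half-concordance), and a 10-bin equal-width calibration
curve with empty bins omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, gather_rows, softmax, softmax_cross_entropy
from .graph import GraphDataset, NodeRecord, assign_provisional_class, build_graph
from .model import (
    BaselineParams,
    ModelParams,
    _baseline_logits,
    _model_logits,
    init_baseline_params,
    init_model_params,
)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "split_dataset",
    "stratified_folds",
    "suggest_lr",
    "lr_finder",
    "train",
    "train_baseline",
    "kfold_cv",
    "compute_metrics",
    "calibration_curve",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the model's operating point)."""

    learning_rate: float = 0.01
    dropout: float = 0.2
    epochs: int = 300
    batch_size: int = 128
    k_folds: int = 3
    train_fraction: float = 0.8
    patience: int = 50
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.k_folds < 2:
            raise ValueError("epochs, batch_size must be >= 1 and k_folds >= 2")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class EvalReport:
    """Classification metrics for one evaluation."""

    accuracy: float
    balanced_accuracy: float
    f1: float
    auc: float | None
    roc_points: list[tuple[float, float]]
    calibration: list[tuple[float, float, int]]
    cv_mean: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "roc_points": self.roc_points,
            "calibration": [list(b) for b in self.calibration],
            "cv_mean": self.cv_mean,
        }


# -- splitting ------------------------------------------------------------


def split_dataset(
    labels: np.ndarray,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split returning index arrays.

    ``|train| = round(train_fraction * n)``; when stratified, per-class
    training counts equal ``round(train_fraction * n_c)`` up to a +-1
    adjustment that fixes the total.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two records to split")
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratified split needs both classes present")
    targets = {c: int(round(train_fraction * k)) for c, k in zip(classes, counts)}
    # fix rounding drift while keeping every class represented on both sides
    by_size = sorted(classes, key=lambda c: -targets[c])
    i = 0
    while sum(targets.values()) != n_train:
        c = by_size[i % len(by_size)]
        step = 1 if sum(targets.values()) < n_train else -1
        cap = counts[list(classes).index(c)]
        if 0 < targets[c] + step < cap:
            targets[c] += step
        i += 1
    train_parts, test_parts = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        train_parts.append(idx[: targets[c]])
        test_parts.append(idx[targets[c] :])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition indices into k stratified folds of sizes differing by <= 1."""
    labels = np.asarray(labels)
    if k < 2 or k > len(labels):
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
        start += len(idx)  # rotate so remainders spread across folds
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


# -- learning-rate range test ---------------------------------------------


def suggest_lr(
    lrs: np.ndarray, losses: np.ndarray, smooth: float = 0.5, blowup: float = 4.0
) -> tuple[float | None, bool]:
    """Pick the rate where smoothed loss falls fastest w.r.t. log-lr.

    The search is restricted to steps before the first divergence (loss
    exceeding ``blowup`` x the running minimum).  Returns ``(lr, weak)``
    where ``weak`` flags a curve with no descent at all; an immediately
    divergent curve yields ``(None, True)``.
    """
    lrs = np.asarray(lrs, dtype=np.float64)
    losses = np.asarray(losses, dtype=np.float64)
    sm = np.empty_like(losses)
    acc = losses[0]
    for i, v in enumerate(losses):
        acc = smooth * acc + (1 - smooth) * v
        sm[i] = acc
    running_min = np.minimum.accumulate(sm)
    diverged = np.flatnonzero(sm > blowup * running_min)
    last = int(diverged[0]) if diverged.size else len(sm)
    if last < 2:
        return None, True
    slopes = np.diff(sm[:last]) / np.diff(np.log(lrs[:last]))
    best = int(np.argmin(slopes))
    weak = bool(slopes[best] >= 0)
    return float(lrs[best + 1]), weak


def lr_finder(
    model_factory,
    X: np.ndarray,
    y: np.ndarray,
    lr_min: float = 1e-5,
    lr_max: float = 1.0,
    steps: int = 50,
    batch_size: int = 128,
    seed: int = 0,
):
    """Geometric learning-rate sweep, one mini-batch per step.

    ``model_factory()`` must return ``(params, logits_fn)`` where
    ``logits_fn(X_batch, training, rng)`` produces a logits Tensor.
    Returns ``(table, suggested_lr, weak)`` with one (lr, loss) row per step.
    """
    if not lr_min < lr_max:
        raise ValueError("need lr_min < lr_max")
    if steps < 2:
        raise ValueError("need at least two steps")
    rng = np.random.default_rng(seed)
    lrs = np.geomspace(lr_min, lr_max, steps)
    params, logits_fn = model_factory()
    opt = Adam(params.tensors(), lr=lrs[0])
    n = len(y)
    order = rng.permutation(n)
    losses = np.empty(steps)
    for i, lr in enumerate(lrs):
        batch = order[(i * batch_size % n + np.arange(batch_size)) % n]
        opt.lr = lr
        opt.zero_grad()
        logits = logits_fn(X[batch], True, rng)
        loss = softmax_cross_entropy(logits, y[batch])
        loss.backward()
        opt.step()
        losses[i] = float(loss.data)
    suggested, weak = suggest_lr(lrs, losses)
    table = [(float(a), float(b)) for a, b in zip(lrs, losses)]
    return table, suggested, weak


# -- training loops -------------------------------------------------------


def _bn_layers(params):
    from .model import _all_ffn_blocks

    return [layer.bn for block in _all_ffn_blocks(params) for layer in block.layers]


def _snapshot(params):
    """Copy all weights plus batchnorm running statistics."""
    return (
        [t.data.copy() for t in params.tensors()],
        [(bn.running_mean.copy(), bn.running_var.copy()) for bn in _bn_layers(params)],
    )


def _restore(params, snap) -> None:
    weights, stats = snap
    for t, d in zip(params.tensors(), weights):
        t.data = d.copy()
    for bn, (rm, rv) in zip(_bn_layers(params), stats):
        bn.running_mean = rm.copy()
        bn.running_var = rv.copy()


def train(
    graph: GraphDataset,
    labels: np.ndarray,
    train_idx: np.ndarray,
    cfg: TrainConfig | None = None,
    params: ModelParams | None = None,
    init_seed: int = 0,
) -> tuple[ModelParams, list[dict]]:
    """Train the BG-MBC network full-batch with early stopping.

    ``labels`` are the true labels; the loss sees only ``train_idx`` rows
    (minus a stratified validation slice used for early stopping on
    validation accuracy, with best-parameter restore).
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if params is None:
        params = init_model_params(
            n_features=graph.features.shape[1],
            dropout=cfg.dropout,
            seed=init_seed,
        )
    edges = graph.message_edges()
    X = graph.features
    if len(np.unique(labels[train_idx])) > 1 and cfg.val_fraction > 0:
        fit_rel, val_rel = split_dataset(
            labels[train_idx], 1.0 - cfg.val_fraction, seed=cfg.seed
        )
        fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
    else:
        fit_idx, val_idx = train_idx, np.empty(0, dtype=np.int64)
    opt = Adam(params.tensors(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_val = -np.inf
    best_snap = _snapshot(params)
    since_best = 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        logits = _model_logits(X, edges, params, True, rng)
        loss = softmax_cross_entropy(gather_rows(logits, fit_idx), labels[fit_idx])
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged: non-finite loss at epoch {epoch} "
                f"(lr={cfg.learning_rate})"
            )
        loss.backward()
        opt.step()
        probs = softmax(_model_logits(X, edges, params, False, rng).data)
        pred = probs.argmax(axis=1)
        train_acc = float((pred[fit_idx] == labels[fit_idx]).mean())
        val_acc = (
            float((pred[val_idx] == labels[val_idx]).mean())
            if val_idx.size
            else train_acc
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(loss.data),
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val:
            best_val = val_acc
            best_snap = _snapshot(params)
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    _restore(params, best_snap)
    return params, history


def train_baseline(
    X: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    cfg: TrainConfig | None = None,
    params: BaselineParams | None = None,
    init_seed: int = 0,
) -> tuple[BaselineParams, list[dict]]:
    """Train the feedforward baseline with mini-batches and early stopping."""
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    X = np.asarray(X, dtype=np.float64)
    if params is None:
        params = init_baseline_params(
            n_features=X.shape[1], dropout=cfg.dropout, seed=init_seed
        )
    if len(np.unique(labels[train_idx])) > 1 and cfg.val_fraction > 0:
        fit_rel, val_rel = split_dataset(
            labels[train_idx], 1.0 - cfg.val_fraction, seed=cfg.seed
        )
        fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
    else:
        fit_idx, val_idx = train_idx, np.empty(0, dtype=np.int64)
    opt = Adam(params.tensors(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_val = -np.inf
    best_snap = _snapshot(params)
    since_best = 0
    for epoch in range(cfg.epochs):
        order = fit_idx[rng.permutation(len(fit_idx))]
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            if len(batch) < 2:
                continue  # batchnorm needs >= 2 rows
            opt.zero_grad()
            logits = _baseline_logits(X[batch], params, True, rng)
            loss = softmax_cross_entropy(logits, labels[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"baseline training diverged at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        probs = softmax(_baseline_logits(X, params, False, rng).data)
        pred = probs.argmax(axis=1)
        train_acc = float((pred[fit_idx] == labels[fit_idx]).mean())
        val_acc = (
            float((pred[val_idx] == labels[val_idx]).mean())
            if val_idx.size
            else train_acc
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val:
            best_val = val_acc
            best_snap = _snapshot(params)
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    _restore(params, best_snap)
    return params, history


def kfold_cv(
    nodes: list[NodeRecord],
    k: int = 3,
    cfg: TrainConfig | None = None,
    node_threshold: float = 200.0,
    node_connections: int = 5,
) -> tuple[list[EvalReport], float]:
    """Stratified k-fold cross-validation of the full graph pipeline.

    The graph is rebuilt for every fold with provisional classes derived
    only from the training folds' labels (held-out labels never shape the
    graph).  Returns the per-fold reports and the mean accuracy.
    """
    cfg = cfg or TrainConfig(k_folds=k)
    labels = np.asarray([n.cls for n in nodes], dtype=np.int64)
    scores = np.asarray([n.score for n in nodes], dtype=np.float64)
    folds = stratified_folds(labels, k, seed=cfg.seed)
    reports: list[EvalReport] = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.sort(
            np.concatenate([f for j, f in enumerate(folds) if j != fold_i])
        )
        prov = assign_provisional_class(scores, train_idx, labels[train_idx])
        fold_nodes = [
            NodeRecord(n.record_id, n.score, int(prov[i]), n.features)
            for i, n in enumerate(nodes)
        ]
        graph = build_graph(fold_nodes, node_threshold, node_connections)
        params, _ = train(graph, labels, train_idx, cfg, init_seed=cfg.seed + fold_i)
        probs = softmax(
            _model_logits(
                graph.features, graph.message_edges(), params, False,
                np.random.default_rng(0),
            ).data
        )
        reports.append(compute_metrics(labels[test_idx], probs[test_idx]))
    mean_acc = float(np.mean([r.accuracy for r in reports]))
    for r in reports:
        r.cv_mean = mean_acc
    return reports, mean_acc


# -- metrics --------------------------------------------------------------


def roc_curve_points(
    y_true: np.ndarray, scores: np.ndarray
) -> list[tuple[float, float]]:
    """(FPR, TPR) points from a threshold sweep over the unique scores.

    Sentinels pin the curve at (0, 0) and (1, 1); tied scores share a
    threshold so ties contribute half-concordance to the trapezoidal AUC.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = []
    for t in thresholds:
        pred = scores >= t
        tpr = float((pred & pos).sum() / n_pos)
        fpr = float((pred & ~pos).sum() / n_neg)
        points.append((fpr, tpr))
    return points


def compute_metrics(
    y_true: np.ndarray, probs: np.ndarray, calibration_bins: int = 10
) -> EvalReport:
    """Evaluate class-probability predictions against true labels."""
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != len(y_true):
        raise ValueError("probs must be (n, 2) matching y_true")
    p1 = probs[:, 1]
    pred = (p1 >= 0.5).astype(np.int64)
    accuracy = float((pred == y_true).mean())
    recalls = [
        float((pred[y_true == c] == c).mean()) for c in np.unique(y_true)
    ]
    balanced = float(np.mean(recalls))
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    if len(np.unique(y_true)) < 2:
        auc, roc_points = None, []
    else:
        roc_points = roc_curve_points(y_true, p1)
        fpr = np.array([p[0] for p in roc_points])
        tpr = np.array([p[1] for p in roc_points])
        auc = float(np.trapezoid(tpr, fpr))
    cal = calibration_curve(y_true, p1, bins=calibration_bins)
    return EvalReport(
        accuracy=accuracy,
        balanced_accuracy=balanced,
        f1=float(f1),
        auc=auc,
        roc_points=roc_points,
        calibration=cal,
    )


def calibration_curve(
    y_true: np.ndarray, p1: np.ndarray, bins: int = 10
) -> list[tuple[float, float, int]]:
    """Reliability curve: per equal-width bin on [0, 1], the mean predicted
    probability, the observed positive frequency, and the bin count.
    Empty bins are omitted; bin counts sum to n."""
    y_true = np.asarray(y_true)
    p1 = np.asarray(p1, dtype=np.float64)
    if np.any((p1 < 0) | (p1 > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.minimum((p1 * bins).astype(int), bins - 1)
    out = []
    for b in range(bins):
        mask = idx == b
        if not mask.any():
            continue
        out.append(
            (float(p1[mask].mean()), float(y_true[mask].mean()), int(mask.sum()))
        )
    return out
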