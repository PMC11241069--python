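"""The BG-MBC network and its feedforward baseline.

Architecture (node classification, 2 classes):

* **pre-processing block** — a stack (default depth 3) of
  batch-normalisation -> dropout -> dense+GELU layers mapping the selected
  node features to the first hidden width;
* **two graph convolution layers** (hidden widths default [34, 34]) — each
  gathers linearly transformed neighbour states along incoming edges,
  aggregates them by a configurable mode (sum, mean or max; isolated nodes
  receive a zero message), and updates every node as
  ``GELU(dense([own_state || aggregated_message]))`` plus an additive skip
  connection (projected when widths differ);
* **post-processing block** — another FFN stack; then a dense softmax head
  producing per-node class probabilities.

The baseline drops the graph entirely: pairs of FFN blocks wrapped in
additive skip connections, the pair iterated four times (unshared
weights), then the same softmax head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import (
    Adam,
    Tensor,
    concat,
    gather_rows,
    gelu,
    segment_max,
    segment_mean,
    segment_sum,
    softmax,
)

__all__ = [
    "DenseParams",
    "BatchNormParams",
    "FFNLayerParams",
    "FFNBlockParams",
    "GraphConvParams",
    "ModelParams",
    "BaselineParams",
    "ffn_block_forward",
    "graph_conv_forward",
    "model_forward",
    "baseline_forward",
    "init_model_params",
    "init_baseline_params",
    "save_params",
    "load_params",
]

_AGGREGATORS = {"sum": segment_sum, "mean": segment_mean, "max": segment_max}


@dataclass
class DenseParams:
    W: Tensor
    b: Tensor

    def tensors(self):
        yield self.W
        yield self.b


@dataclass
class BatchNormParams:
    """Affine batch normalisation over the node dimension with running stats."""

    gamma: Tensor
    beta: Tensor
    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.9
    eps: float = 1e-5

    def tensors(self):
        yield self.gamma
        yield self.beta


@dataclass
class FFNLayerParams:
    bn: BatchNormParams
    dropout_rate: float
    dense: DenseParams

    def tensors(self):
        yield from self.bn.tensors()
        yield from self.dense.tensors()


@dataclass
class FFNBlockParams:
    layers: list[FFNLayerParams]

    def tensors(self):
        for layer in self.layers:
            yield from layer.tensors()


@dataclass
class GraphConvParams:
    w_msg: Tensor
    update: DenseParams
    w_skip: Tensor | None
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.aggregation not in _AGGREGATORS:
            raise ValueError(
                f"unknown aggregation {self.aggregation!r}; choose sum, mean or max"
            )

    def tensors(self):
        yield self.w_msg
        yield from self.update.tensors()
        if self.w_skip is not None:
            yield self.w_skip


@dataclass
class ModelParams:
    """All learnable state of the BG-MBC network."""

    pre: FFNBlockParams
    conv1: GraphConvParams
    conv2: GraphConvParams
    post: FFNBlockParams
    head: DenseParams
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.head.W.shape[1] != 2:
            raise ValueError("softmax head must have output width 2")

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for block in (self.pre, self.conv1, self.conv2, self.post, self.head):
            out.extend(block.tensors())
        return out


@dataclass
class BaselineParams:
    """Learnable state of the skip-connected feedforward baseline."""

    block_pairs: list[tuple[FFNBlockParams, FFNBlockParams]]
    skips: list[tuple[Tensor | None, Tensor | None]]
    head: DenseParams
    hyper: dict = field(default_factory=dict)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for (a, b), (sa, sb) in zip(self.block_pairs, self.skips):
            out.extend(a.tensors())
            out.extend(b.tensors())
            for s in (sa, sb):
                if s is not None:
                    out.extend([s])
        out.extend(self.head.tensors())
        return out


# -- initialisation -------------------------------------------------------


def _dense(rng, n_in: int, n_out: int) -> DenseParams:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return DenseParams(
        W=Tensor(rng.standard_normal((n_in, n_out)) * scale, requires_grad=True),
        b=Tensor(np.zeros(n_out), requires_grad=True),
    )


def _bn(width: int) -> BatchNormParams:
    return BatchNormParams(
        gamma=Tensor(np.ones(width), requires_grad=True),
        beta=Tensor(np.zeros(width), requires_grad=True),
        running_mean=np.zeros(width),
        running_var=np.ones(width),
    )


def _ffn_block(rng, widths: list[int], dropout: float) -> FFNBlockParams:
    layers = [
        FFNLayerParams(
            bn=_bn(widths[i]),
            dropout_rate=dropout,
            dense=_dense(rng, widths[i], widths[i + 1]),
        )
        for i in range(len(widths) - 1)
    ]
    return FFNBlockParams(layers=layers)


def _graph_conv(rng, width: int, aggregation: str) -> GraphConvParams:
    return GraphConvParams(
        w_msg=Tensor(
            rng.standard_normal((width, width)) * np.sqrt(1.0 / width),
            requires_grad=True,
        ),
        update=_dense(rng, 2 * width, width),
        w_skip=None,  # widths match: identity skip
        aggregation=aggregation,
    )


def init_model_params(
    n_features: int,
    hidden_units: tuple[int, int] = (34, 34),
    aggregation: str = "sum",
    dropout: float = 0.2,
    ffn_stack_depth: int = 3,
    seed: int = 0,
) -> ModelParams:
    """Seeded parameter initialisation for the BG-MBC network."""
    if hidden_units[0] != hidden_units[1]:
        raise ValueError("the two graph-conv widths must match (identity skips)")
    rng = np.random.default_rng(np.random.SeedSequence([31, seed]))
    h = hidden_units[0]
    pre_widths = [n_features] + [h] * ffn_stack_depth
    post_widths = [h] * (ffn_stack_depth + 1)
    return ModelParams(
        pre=_ffn_block(rng, pre_widths, dropout),
        conv1=_graph_conv(rng, h, aggregation),
        conv2=_graph_conv(rng, h, aggregation),
        post=_ffn_block(rng, post_widths, dropout),
        head=_dense(rng, h, 2),
        hyper={
            "n_features": n_features,
            "hidden_units": list(hidden_units),
            "aggregation": aggregation,
            "dropout": dropout,
            "ffn_stack_depth": ffn_stack_depth,
            "kind": "bgmbc",
        },
    )


def init_baseline_params(
    n_features: int,
    width: int = 34,
    dropout: float = 0.2,
    ffn_stack_depth: int = 3,
    n_iterations: int = 4,
    seed: int = 0,
) -> BaselineParams:
    """Seeded initialisation of the skip-connected feedforward baseline."""
    rng = np.random.default_rng(np.random.SeedSequence([37, seed]))
    pairs = []
    skips = []
    w_in = n_features
    for _ in range(n_iterations):
        a = _ffn_block(rng, [w_in] + [width] * ffn_stack_depth, dropout)
        skip_a = (
            None
            if w_in == width
            else Tensor(
                rng.standard_normal((w_in, width)) * np.sqrt(1.0 / w_in),
                requires_grad=True,
            )
        )
        b = _ffn_block(rng, [width] * (ffn_stack_depth + 1), dropout)
        pairs.append((a, b))
        skips.append((skip_a, None))
        w_in = width
    return BaselineParams(
        block_pairs=pairs,
        skips=skips,
        head=_dense(rng, width, 2),
        hyper={
            "n_features": n_features,
            "width": width,
            "dropout": dropout,
            "ffn_stack_depth": ffn_stack_depth,
            "n_iterations": n_iterations,
            "kind": "baseline",
        },
    )


# -- forward passes -------------------------------------------------------


def _batchnorm(x: Tensor, bn: BatchNormParams, training: bool) -> Tensor:
    if training and x.shape[0] > 1:
        mu = x.mean(axis=0)
        var = (x - mu).pow(2).mean(axis=0)
        bn.running_mean = (
            bn.momentum * bn.running_mean + (1 - bn.momentum) * mu.data
        )
        bn.running_var = (
            bn.momentum * bn.running_var + (1 - bn.momentum) * var.data
        )
        xhat = (x - mu) / (var + bn.eps).sqrt()
    else:
        xhat = (x - Tensor(bn.running_mean)) / Tensor(
            np.sqrt(bn.running_var + bn.eps)
        )
    return bn.gamma * xhat + bn.beta


def ffn_block_forward(
    x: Tensor | np.ndarray,
    params: FFNBlockParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Apply a stack of batchnorm -> dropout -> dense+GELU layers."""
    h = x if isinstance(x, Tensor) else Tensor(x)
    for layer in params.layers:
        if h.shape[1] != layer.dense.W.shape[0]:
            raise ValueError(
                f"width mismatch: input {h.shape[1]}, dense expects "
                f"{layer.dense.W.shape[0]}"
            )
        h = _batchnorm(h, layer.bn, training)
        if training and layer.dropout_rate > 0:
            if rng is None:
                rng = np.random.default_rng()
            keep = (rng.random(h.shape) >= layer.dropout_rate).astype(np.float64)
            h = h * Tensor(keep / (1.0 - layer.dropout_rate))
        h = gelu(h @ layer.dense.W + layer.dense.b)
    return h


def graph_conv_forward(
    h: Tensor | np.ndarray,
    edges: np.ndarray,
    params: GraphConvParams,
) -> Tensor:
    """One graph convolution: transform, aggregate, update with skip.

    ``edges`` is an (m, 2) array of (source, target) pairs; messages flow
    source -> target along each listed edge.  Isolated nodes receive a zero
    aggregated message under every mode.
    """
    h = h if isinstance(h, Tensor) else Tensor(h)
    n = h.shape[0]
    agg_fn = _AGGREGATORS[params.aggregation]
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    msg = gather_rows(h, edges[:, 0]) @ params.w_msg
    agg = agg_fn(msg, edges[:, 1], n)
    upd = gelu(concat([h, agg], axis=1) @ params.update.W + params.update.b)
    skip = h if params.w_skip is None else h @ params.w_skip
    return upd + skip


def model_forward(
    X: np.ndarray,
    edges: np.ndarray,
    params: ModelParams,
    training: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Full BG-MBC forward pass; returns an (n, 2) class-probability matrix."""
    logits = _model_logits(X, edges, params, training, np.random.default_rng(seed))
    return softmax(logits.data)


def _model_logits(
    X, edges, params: ModelParams, training: bool, rng: np.random.Generator
) -> Tensor:
    h = ffn_block_forward(X, params.pre, training, rng)
    h = graph_conv_forward(h, edges, params.conv1)
    h = graph_conv_forward(h, edges, params.conv2)
    h = ffn_block_forward(h, params.post, training, rng)
    return h @ params.head.W + params.head.b


def baseline_forward(
    X: np.ndarray,
    params: BaselineParams,
    training: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Baseline forward pass; returns an (n, 2) class-probability matrix."""
    logits = _baseline_logits(X, params, training, np.random.default_rng(seed))
    return softmax(logits.data)


def _baseline_logits(
    X, params: BaselineParams, training: bool, rng: np.random.Generator
) -> Tensor:
    h = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
    for (block_a, block_b), (skip_a, skip_b) in zip(
        params.block_pairs, params.skips
    ):
        sa = h if skip_a is None else h @ skip_a
        h = sa + ffn_block_forward(h, block_a, training, rng)
        sb = h if skip_b is None else h @ skip_b
        h = sb + ffn_block_forward(h, block_b, training, rng)
    return h @ params.head.W + params.head.b


# -- serialisation --------------------------------------------------------


def _collect_arrays(params) -> dict[str, np.ndarray]:
    arrays = {f"t{i}": t.data for i, t in enumerate(params.tensors())}
    bns = [
        layer.bn
        for block in _all_ffn_blocks(params)
        for layer in block.layers
    ]
    for i, bn in enumerate(bns):
        arrays[f"rm{i}"] = bn.running_mean
        arrays[f"rv{i}"] = bn.running_var
    return arrays


def _all_ffn_blocks(params):
    if isinstance(params, ModelParams):
        return [params.pre, params.post]
    blocks = []
    for a, b in params.block_pairs:
        blocks.extend([a, b])
    return blocks


def save_params(params: ModelParams | BaselineParams, path: str | Path) -> None:
    """Serialise parameters to ``<path>.npz`` plus a JSON hyperparameter manifest."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **_collect_arrays(params))
    path.with_suffix(".json").write_text(json.dumps(params.hyper, indent=2))


def load_params(path: str | Path) -> ModelParams | BaselineParams:
    """Rebuild parameters from :func:`save_params` output."""
    path = Path(path)
    hyper = json.loads(path.with_suffix(".json").read_text())
    if hyper["kind"] == "bgmbc":
        params = init_model_params(
            n_features=hyper["n_features"],
            hidden_units=tuple(hyper["hidden_units"]),
            aggregation=hyper["aggregation"],
            dropout=hyper["dropout"],
            ffn_stack_depth=hyper["ffn_stack_depth"],
        )
    else:
        params = init_baseline_params(
            n_features=hyper["n_features"],
            width=hyper["width"],
            dropout=hyper["dropout"],
            ffn_stack_depth=hyper["ffn_stack_depth"],
            n_iterations=hyper["n_iterations"],
        )
    params.hyper = hyper
    with np.load(path.with_suffix(".npz")) as data:
        for i, t in enumerate(params.tensors()):
            t.data = data[f"t{i}"]
        bns = [layer.bn for block in _all_ffn_blocks(params) for layer in block.layers]
        for i, bn in enumerate(bns):
            bn.running_mean = data[f"rm{i}"]
            bn.running_var = data[f"rv{i}"]
    return params
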