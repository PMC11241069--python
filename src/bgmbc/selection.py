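"""Three-selector feature reduction over the embedding columns.

The 767 pooled-embedding columns are scored by three selectors —
per-column one-way ANOVA F between the two classes, extra-trees impurity
importance, and mean absolute Shapley attribution on the same extra-trees
model — and the per-selector rankings are combined by mean rank.  The
top ``k`` columns (default 30) are retained as node features.

Rank 1 is the most relevant column; ties break towards the lowest column
index throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from ._treeshap import forest_shap_values

__all__ = [
    "FeatureTable",
    "SelectorRanking",
    "normalise_features",
    "univariate_scores",
    "extra_trees_importance",
    "shap_importance",
    "aggregate_and_select",
    "select_features",
]


@dataclass
class FeatureTable:
    """An (n records x p features) matrix with binary labels and column ids."""

    X: np.ndarray
    y: np.ndarray
    column_ids: list[str]
    record_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on record count")
        if self.X.shape[1] != len(self.column_ids):
            raise ValueError("column_ids length must equal feature count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SelectorRanking:
    """Per-column scores and the 1-based ranks they induce for one selector."""

    name: str
    scores: np.ndarray
    ranks: np.ndarray
    column_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        p = len(self.column_ids)
        if sorted(self.ranks.tolist()) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..p")


def _ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    """Rank columns by descending score, ties broken by lowest column index."""
    p = len(scores)
    order = np.lexsort((np.arange(p), -np.asarray(scores, dtype=np.float64)))
    ranks = np.empty(p, dtype=np.int64)
    ranks[order] = np.arange(1, p + 1)
    return ranks


def normalise_features(X: np.ndarray) -> np.ndarray:
    """Z-score each column; constant columns map to all-zero."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least two records to normalise")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def univariate_scores(X: np.ndarray, y: np.ndarray, column_ids=None) -> SelectorRanking:
    """Per-column one-way ANOVA F statistic between the two class groups.

    Embedding values are signed reals, so the F statistic (rather than a
    chi-squared test, which needs non-negative features) is the univariate
    relevance score.  Degenerate 0/0 columns score 0 by convention.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("univariate scoring needs both classes present")
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        grp = X[y == c]
        m = grp.mean(axis=0)
        ss_between += len(grp) * (m - grand) ** 2
        ss_within += ((grp - m) ** 2).sum(axis=0)
    df_b = len(classes) - 1
    df_w = n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f[np.isnan(f)] = 0.0  # 0/0: constant column
    if column_ids is None:
        column_ids = [f"f{j}" for j in range(X.shape[1])]
    return SelectorRanking(
        name="univariate_anova_f",
        scores=f,
        ranks=_ranks_from_scores(f),
        column_ids=tuple(column_ids),
    )


def fit_extra_trees(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed: int = 0
) -> ExtraTreesClassifier:
    """Fit the extremely-randomised-trees ensemble shared by two selectors."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    model = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(X, y)
    return model


def extra_trees_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    column_ids=None,
    model: ExtraTreesClassifier | None = None,
) -> SelectorRanking:
    """Mean impurity-decrease importance per column from an extra-trees fit."""
    if model is None:
        model = fit_extra_trees(X, y, n_trees=n_trees, seed=seed)
    imp = model.feature_importances_
    if column_ids is None:
        column_ids = [f"f{j}" for j in range(len(imp))]
    return SelectorRanking(
        name="extra_trees_importance",
        scores=imp,
        ranks=_ranks_from_scores(imp),
        column_ids=tuple(column_ids),
    )


def shap_importance(
    model: ExtraTreesClassifier,
    X: np.ndarray,
    column_ids=None,
    max_records: int | None = 256,
    seed: int = 0,
) -> SelectorRanking:
    """Mean absolute Shapley attribution per column over (a subsample of) records.

    Uses exact path-dependent tree attribution on the fitted ensemble; the
    mean |SHAP| is estimated on a seeded subsample of at most
    ``max_records`` rows (pass ``None`` to use all rows).
    """
    X = np.asarray(X, dtype=np.float64)
    if max_records is not None and X.shape[0] > max_records:
        idx = np.random.default_rng(seed).choice(X.shape[0], max_records, replace=False)
        X = X[np.sort(idx)]
    phi, _ = forest_shap_values(model, X)
    scores = np.abs(phi).mean(axis=0)
    if column_ids is None:
        column_ids = [f"f{j}" for j in range(X.shape[1])]
    return SelectorRanking(
        name="mean_abs_shap",
        scores=scores,
        ranks=_ranks_from_scores(scores),
        column_ids=tuple(column_ids),
    )


def aggregate_and_select(rankings: list[SelectorRanking], k: int = 30) -> list[str]:
    """Order columns by mean rank across selectors and keep the first ``k``."""
    if not rankings:
        raise ValueError("need at least one ranking")
    ids = rankings[0].column_ids
    for r in rankings[1:]:
        if r.column_ids != ids:
            raise ValueError("rankings cover different column sets")
    p = len(ids)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    mean_rank = np.mean([r.ranks for r in rankings], axis=0)
    order = np.lexsort((np.arange(p), mean_rank))
    return [ids[j] for j in order[:k]]


def select_features(
    table: FeatureTable,
    k: int = 30,
    n_trees: int = 100,
    seed: int = 0,
    shap_max_records: int | None = 256,
) -> tuple[list[str], pd.DataFrame]:
    """Run all three selectors, aggregate by mean rank, keep the top ``k``.

    Returns the selected column ids plus a per-column report with each
    selector's score, the mean rank, and a selected flag.
    """
    Xs = normalise_features(table.X)
    uni = univariate_scores(Xs, table.y, table.column_ids)
    model = fit_extra_trees(Xs, table.y, n_trees=n_trees, seed=seed)
    tree = extra_trees_importance(
        Xs, table.y, column_ids=table.column_ids, model=model
    )
    shap = shap_importance(
        model, Xs, column_ids=table.column_ids, max_records=shap_max_records, seed=seed
    )
    rankings = [uni, tree, shap]
    selected = aggregate_and_select(rankings, k=k)
    mean_rank = np.mean([r.ranks for r in rankings], axis=0)
    report = pd.DataFrame(
        {
            "column_id": table.column_ids,
            "univariate_f": uni.scores,
            "tree_importance": tree.scores,
            "mean_abs_shap": shap.scores,
            "mean_rank": mean_rank,
            "selected": [c in set(selected) for c in table.column_ids],
        }
    )
    return selected, report
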