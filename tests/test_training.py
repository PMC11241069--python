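"""Splitting, lr finding, the training loops, metrics and calibration."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from bgmbc.graph import GraphDataset, NodeRecord
from bgmbc.model import init_baseline_params, _baseline_logits
from bgmbc.synthetic import SyntheticConfig, generate_encoded_dataset
from bgmbc.training import (
    TrainConfig,
    calibration_curve,
    compute_metrics,
    kfold_cv,
    lr_finder,
    split_dataset,
    stratified_folds,
    suggest_lr,
    train,
    train_baseline,
)


class TestSplit:
    def test_eighty_twenty_on_ten(self):
        y = np.array([0, 1] * 5)
        tr, te = split_dataset(y, 0.8, seed=0)
        assert len(tr) == 8 and len(te) == 2
        assert set(tr) | set(te) == set(range(10))
        assert not set(tr) & set(te)

    def test_stratification_on_balanced_thousand(self):
        y = np.array([0] * 500 + [1] * 500)
        tr, _ = split_dataset(y, 0.8, seed=1)
        assert len(tr) == 800
        assert (y[tr] == 0).sum() == 400
        assert (y[tr] == 1).sum() == 400

    def test_seeding_contract(self):
        y = np.array([0, 1] * 50)
        a1, _ = split_dataset(y, 0.8, seed=0)
        a2, _ = split_dataset(y, 0.8, seed=0)
        b, _ = split_dataset(y, 0.8, seed=1)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)

    def test_imbalanced_proportions_within_one(self):
        y = np.array([0] * 70 + [1] * 33)
        tr, te = split_dataset(y, 0.8, seed=2)
        assert len(tr) == round(0.8 * 103)
        for c, n_c in ((0, 70), (1, 33)):
            got = (y[tr] == c).sum()
            assert abs(got - 0.8 * n_c) <= 1


class TestFolds:
    def test_leave_one_out_boundary(self):
        y = np.array([0, 1, 0, 1])
        folds = stratified_folds(y, k=4, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_fold_sizes_differ_by_at_most_one(self):
        y = np.array([0] * 40 + [1] * 27)
        folds = stratified_folds(y, k=5, seed=0)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert np.concatenate(folds).size == 67
        assert set(np.concatenate(folds).tolist()) == set(range(67))

    def test_three_folds_on_99_balanced(self):
        y = np.array([0, 1] * 49 + [0])  # 50 zeros, 49 ones
        folds = stratified_folds(y, k=3, seed=1)
        assert sorted(len(f) for f in folds) == [33, 33, 33]
        for f in folds:
            c1 = int(y[f].sum())
            assert c1 in (16, 17)


class TestLrFinder:
    def test_flat_curve_flagged_weak(self):
        lrs = np.geomspace(1e-4, 1.0, 20)
        lr, weak = suggest_lr(lrs, np.ones(20))
        assert weak
        assert lr == pytest.approx(lrs[1])

    def test_constructed_curve_returns_steepest_descent_point(self):
        lrs = np.geomspace(1e-5, 1.0, 30)
        # piecewise: slow descent, steep drop around index 17, then blow-up
        losses = np.concatenate([
            np.linspace(1.0, 0.9, 17),
            np.linspace(0.85, 0.3, 6),
            np.full(7, 5.0),
        ])
        lr, weak = suggest_lr(lrs, losses, smooth=0.0)
        assert not weak
        steep = int(np.argmin(np.diff(losses[:23]) / np.diff(np.log(lrs[:23]))))
        assert lr == pytest.approx(lrs[steep + 1])

    def test_immediate_divergence_reports_no_suggestion(self):
        lrs = np.geomspace(1e-3, 1.0, 10)
        losses = np.array([1.0] + [50.0] * 9)
        lr, weak = suggest_lr(lrs, losses, smooth=0.0)
        assert lr is None and weak

    def test_schedule_endpoints(self, small_dataset):
        table, _, _ = small_dataset

        def factory():
            params = init_baseline_params(n_features=table.n_features, seed=0)
            return params, lambda X, training, rng: _baseline_logits(
                X, params, training, rng
            )

        tablelr, lr, weak = lr_finder(
            factory, table.X, table.y, lr_min=1e-4, lr_max=0.1, steps=8,
            batch_size=16, seed=0,
        )
        assert tablelr[0][0] == pytest.approx(1e-4)
        assert tablelr[-1][0] == pytest.approx(0.1)
        assert len(tablelr) == 8


def _toy_graph(n=40, seed=0, with_edges=False):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, 4))
    X[:, 0] += 3.0 * y  # linearly separable
    nodes = [NodeRecord(f"n{i:03d}", float(i), int(y[i]), X[i]) for i in range(n)]
    from bgmbc.graph import build_graph

    g = build_graph(nodes, node_threshold=2.0 if with_edges else 0.0,
                    node_connections=5 if with_edges else 0)
    return g, y


class TestTrain:
    def test_zero_learning_rate_leaves_params_unchanged(self):
        g, y = _toy_graph()
        cfg = TrainConfig(learning_rate=0.0, epochs=3, patience=10)
        params, _ = train(g, y, np.arange(40), cfg)
        from bgmbc.model import init_model_params

        fresh = init_model_params(n_features=4, dropout=cfg.dropout, seed=0)
        for a, b in zip(params.tensors(), fresh.tensors()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_separable_data_without_edges_trains_to_high_accuracy(self):
        g, y = _toy_graph(n=60, with_edges=False)
        cfg = TrainConfig(epochs=120, patience=120, val_fraction=0.0)
        params, history = train(g, y, np.arange(60), cfg)
        losses = [h["train_loss"] for h in history]
        assert losses[5] < losses[0]  # early descent
        assert history[-1]["train_acc"] >= 0.95 or max(
            h["train_acc"] for h in history
        ) >= 0.95

    def test_patience_zero_stops_one_epoch_after_best(self):
        g, y = _toy_graph(n=40)
        # lr 0: validation accuracy never improves after the first epoch
        cfg = TrainConfig(learning_rate=0.0, epochs=50, patience=0)
        _, history = train(g, y, np.arange(40), cfg)
        assert len(history) == 2

    def test_nan_loss_aborts_with_diagnostic(self):
        g, y = _toy_graph(n=20)
        g.features[0, 0] = np.nan  # poisons the loss on the first epoch
        cfg = TrainConfig(learning_rate=10.0, epochs=20, patience=20)
        with pytest.raises(RuntimeError, match="non-finite|diverged"):
            train(g, y, np.arange(20), cfg)

    def test_baseline_trains_on_separable_data(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 30)
        X = rng.standard_normal((60, 3))
        X[:, 1] -= 2.5 * y
        cfg = TrainConfig(epochs=40, patience=40, batch_size=16, val_fraction=0.0)
        params, history = train_baseline(X, y, np.arange(60), cfg)
        assert history[-1]["train_acc"] >= 0.9


class TestKFold:
    def test_three_fold_cv_partitions_and_reports(self):
        cfg = SyntheticConfig(n_records=45, n_features=6, n_informative=2, seed=3)
        table, scores, _ = generate_encoded_dataset(cfg)
        nodes = [
            NodeRecord(f"n{i:03d}", float(scores[i]), int(table.y[i]), table.X[i])
            for i in range(45)
        ]
        tcfg = TrainConfig(epochs=30, patience=30, seed=0)
        reports, mean_acc = kfold_cv(nodes, k=3, cfg=tcfg)
        assert len(reports) == 3
        assert 0.0 <= mean_acc <= 1.0
        assert all(r.cv_mean == pytest.approx(mean_acc) for r in reports)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        probs = np.column_stack([1.0 - y, y]).astype(float)
        rep = compute_metrics(y, probs)
        assert rep.accuracy == rep.balanced_accuracy == rep.f1 == rep.auc == 1.0

    def test_auc_075_by_pair_counting(self):
        y = np.array([1, 0, 1, 0])
        p1 = np.array([0.9, 0.8, 0.3, 0.1])
        rep = compute_metrics(y, np.column_stack([1 - p1, p1]))
        # exhaustive concordant-pair oracle
        pos = p1[y == 1]
        neg = p1[y == 0]
        conc = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        )
        assert rep.auc == pytest.approx(conc / (len(pos) * len(neg)))
        assert rep.auc == pytest.approx(0.75)

    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        probs = np.full((4, 2), 0.5)
        rep = compute_metrics(y, probs)
        assert rep.auc == pytest.approx(0.5)

    def test_trapezoid_matches_pair_counting_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p1 = np.round(rng.random(n), 2)  # coarse grid forces ties
            rep = compute_metrics(y, np.column_stack([1 - p1, p1]))
            pos, neg = p1[y == 1], p1[y == 0]
            conc = sum(
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in pos for b in neg
            )
            oracle = conc / (len(pos) * len(neg))
            assert rep.auc == pytest.approx(oracle, abs=1e-9)
            # cross-check against the standard library implementation
            assert rep.auc == pytest.approx(roc_auc_score(y, p1), abs=1e-9)

    def test_single_class_auc_missing(self):
        rep = compute_metrics(np.zeros(4, dtype=int), np.full((4, 2), 0.5))
        assert rep.auc is None

    def test_balanced_accuracy_is_mean_recall(self):
        y = np.array([0] * 8 + [1] * 2)
        p1 = np.array([0.1] * 8 + [0.9, 0.1])
        rep = compute_metrics(y, np.column_stack([1 - p1, p1]))
        assert rep.balanced_accuracy == pytest.approx((1.0 + 0.5) / 2)


class TestCalibration:
    def test_perfectly_calibrated_points_on_diagonal(self):
        # within each bin, predictions equal empirical frequencies exactly
        p1 = np.array([0.25] * 4 + [0.75] * 4)
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        bins = calibration_curve(y, p1, bins=10)
        for mean_pred, obs, _ in bins:
            assert obs == pytest.approx(mean_pred)

    def test_all_half_predictions_single_bin(self):
        p1 = np.full(10, 0.5)
        y = np.array([0, 1] * 5)
        bins = calibration_curve(y, p1, bins=10)
        assert len(bins) == 1
        assert bins[0] == (0.5, 0.5, 10)

    def test_bin_counts_sum_to_n_and_empty_bins_omitted(self, rng):
        p1 = rng.random(50)
        y = rng.integers(0, 2, size=50)
        bins = calibration_curve(y, p1, bins=10)
        assert sum(b[2] for b in bins) == 50

    def test_simulated_calibrated_predictor_near_diagonal(self):
        rng = np.random.default_rng(5)
        p = rng.random(1000)
        y = (rng.random(1000) < p).astype(int)
        bins = calibration_curve(y, p, bins=10)
        # direct histogram oracle
        idx = np.minimum((p * 10).astype(int), 9)
        for b, (mean_pred, obs, count) in zip(sorted(set(idx)), bins):
            mask = idx == b
            assert obs == pytest.approx(y[mask].mean())
            assert count == mask.sum()
        # count-weighted mean per-bin deviation from the diagonal (ECE):
        # at ~100 records per bin the per-bin binomial standard error is
        # about 0.05, so the mean deviation is the stable summary
        n = sum(c for _, _, c in bins)
        ece = sum(abs(mp - ob) * c for mp, ob, c in bins) / n
        assert ece < 0.08
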