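"""Splitting, sampling and optimization loops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronomt import (
    ModelConfig,
    MultiTaskCNNLSTMClassifier,
    ScheduleConfig,
    SingleTaskNet,
    TrainConfig,
    balanced_batch_iterator,
    class_balance_weights,
    repeat_runs,
    stratified_split,
    train_single_task,
)
from chronomt.select import TaskDataset
from conftest import tiny_datasets


class TestStratifiedSplit:
    def test_exact_proportional_allocation(self):
        labels = np.array([1] * 30 + [0] * 70)
        s = stratified_split(labels, (0.6, 0.2, 0.2), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (60, 20, 20)
        assert labels[s.train].sum() == 18
        assert labels[s.validation].sum() == 6
        assert labels[s.test].sum() == 6

    def test_largest_remainder_hand_oracle(self):
        # n=10, 3 positives: positives 1.8/.6/.6 -> 2/1/0; negatives 4.2/1.4/1.4 -> 4/2/1
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        s = stratified_split(labels, (0.6, 0.2, 0.2), seed=5)
        assert labels[s.train].sum() == 2 and len(s.train) == 6
        assert labels[s.validation].sum() == 1 and len(s.validation) == 3
        assert labels[s.test].sum() == 0 and len(s.test) == 1

    def test_deterministic(self):
        labels = (np.arange(57) % 3 == 0).astype(int)
        a = stratified_split(labels, seed=3)
        b = stratified_split(labels, seed=3)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.zeros(10, dtype=int))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        n=st.integers(10, 300),
        pos_frac=st.floats(0.05, 0.95),
        seed=st.integers(0, 10_000),
    )
    def test_partition_and_ratio_invariants(self, n, pos_frac, seed):
        n_pos = min(max(int(n * pos_frac), 1), n - 1)
        labels = np.zeros(n, dtype=int)
        labels[:n_pos] = 1
        s = stratified_split(labels, (0.6, 0.2, 0.2), seed=seed)
        parts = [s.train, s.validation, s.test]
        all_idx = np.concatenate(parts)
        assert len(all_idx) == n and len(set(all_idx.tolist())) == n
        for part, frac in zip(parts, (0.6, 0.2, 0.2)):
            assert abs(labels[part].sum() - frac * n_pos) < 1.0


class TestClassBalanceWeights:
    def test_inverse_frequency(self):
        labels = np.array([1] * 20 + [0] * 80)
        w = class_balance_weights(labels)
        assert np.allclose(w[:20], 1 / 20)
        assert np.allclose(w[20:], 1 / 80)

    def test_balanced_labels_uniform(self):
        w = class_balance_weights(np.array([0, 1] * 10))
        assert np.allclose(w, w[0])

    def test_sampled_batches_are_class_balanced(self):
        labels = np.array([1] * 20 + [0] * 80)
        w = class_balance_weights(labels)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(labels), size=32 * 10_000, replace=True, p=w / w.sum())
        assert abs(labels[draws].mean() - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_balance_weights(np.ones(5, dtype=int))


class TestBalancedBatchIterator:
    def test_cohort_sizes_give_106_alternating_batches(self):
        batches = balanced_batch_iterator({"dm": 3379, "htn": 2159}, 32, seed=0)
        per_task = {"dm": 0, "htn": 0}
        for i, (task, _) in enumerate(batches):
            per_task[task] += 1
            assert task == ("dm" if i % 2 == 0 else "htn")
        assert per_task == {"dm": 106, "htn": 106}

    def test_larger_task_sees_every_sample_once(self):
        batches = balanced_batch_iterator({"a": 500, "b": 200}, 32, seed=1)
        seen = np.concatenate([idx for task, idx in batches if task == "a"])
        assert sorted(seen.tolist()) == list(range(500))

    def test_equal_sizes_no_resampling(self):
        batches = balanced_batch_iterator({"a": 96, "b": 96}, 32, seed=2)
        for task in ("a", "b"):
            seen = np.concatenate([idx for t, idx in batches if t == task])
            assert sorted(seen.tolist()) == list(range(96))

    def test_single_task_plain_batching(self):
        batches = balanced_batch_iterator({"a": 100}, 32, seed=3)
        assert len(batches) == 4
        assert sorted(np.concatenate([i for _, i in batches]).tolist()) == list(range(100))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            balanced_batch_iterator({"a": 0}, 32, seed=0)

    def test_deterministic(self):
        a = balanced_batch_iterator({"a": 100, "b": 60}, 16, seed=9)
        b = balanced_batch_iterator({"a": 100, "b": 60}, 16, seed=9)
        assert all(
            ta == tb and np.array_equal(ia, ib) for (ta, ia), (tb, ib) in zip(a, b)
        )


def separable_dataset(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4, 3))
    y = (X[:, -1, 0] > 0).astype(int)
    X[:, :, 0] += 2.0 * y[:, None]  # make the margin wide
    return TaskDataset("t", X, y, ["a", "b", "c"], np.arange(n))


class TestTrainSingleTask:
    def test_learns_separable_toy_within_50_epochs(self):
        ds = separable_dataset()
        cfg = TrainConfig(epochs=50, learning_rate=0.01, seed=0)
        model = SingleTaskNet(3, ModelConfig(conv_filters=8, lstm_units=[8, 4],
                                             dropout=0.0), seed=0)
        model, history = train_single_task(model, ds, cfg)
        split = stratified_split(ds.y, cfg.split_fractions, seed=cfg.seed)
        from chronomt.training import _Scaler

        scaler = _Scaler(ds.X[split.train])
        pred = (model(scaler(ds.X[split.train])).data >= 0.5).astype(int)
        assert (pred == ds.y[split.train]).mean() >= 0.95

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        ds = separable_dataset(seed=1)
        model = SingleTaskNet(3, ModelConfig(conv_filters=4, lstm_units=[4],
                                             dropout=0.0), seed=1)
        before = [p.data.copy() for p in model.parameters()]
        train_single_task(model, ds, TrainConfig(epochs=3, learning_rate=0.0, seed=1))
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before, model.parameters()))

    def test_history_is_deterministic(self):
        ds = separable_dataset(seed=2)
        cfg = TrainConfig(epochs=4, seed=7)
        mc = ModelConfig(conv_filters=4, lstm_units=[4], dropout=0.3)
        _, h1 = train_single_task(SingleTaskNet(3, mc, seed=7), ds, cfg)
        _, h2 = train_single_task(SingleTaskNet(3, mc, seed=7), ds, cfg)
        assert h1 == h2


class TestMultiTaskTraining:
    def test_fit_records_history_trace_and_test_metrics(self):
        datasets = tiny_datasets()
        clf = MultiTaskCNNLSTMClassifier(
            schedule_config=ScheduleConfig.from_ratio("diabetes", "hypertension", 3.0),
            model_config=ModelConfig(conv_filters=6, lstm_units=[6, 4], dropout=0.3),
            train_config=TrainConfig(epochs=2, batch_size=16),
            seed=0,
        )
        clf.fit(datasets)
        assert len(clf.history_) == 2
        assert set(clf.test_metrics_) == {"diabetes", "hypertension"}
        for m in clf.test_metrics_.values():
            assert set(m) == {"accuracy", "auc", "f1", "precision", "recall"}
        # weight trace: blocks of cycle_length per focus task in epoch 0
        epoch0 = [r for r in clf.trace_ if r["epoch"] == 0]
        for row in epoch0:
            expected = "diabetes" if (row["iteration"] // 20) % 2 == 0 else "hypertension"
            assert row["focus"] == expected
            w_focus = row[f"w_{row['focus']}"]
            other = "hypertension" if row["focus"] == "diabetes" else "diabetes"
            assert w_focus == clf.schedule_config.initial_weights[row["focus"]]
            assert row[f"w_{other}"] == pytest.approx(
                clf.schedule_config.initial_weights[other] * 0.1
            )

    def test_schedule_dataset_mismatch_rejected(self):
        datasets = tiny_datasets()
        clf = MultiTaskCNNLSTMClassifier(
            schedule_config=ScheduleConfig.from_ratio("diabetes", "gout", 1.0),
            train_config=TrainConfig(epochs=1),
            seed=0,
        )
        with pytest.raises(ValueError):
            clf.fit(datasets)


class TestRepeatRuns:
    def test_aggregation_matches_brute_force(self):
        values = {0: 0.8, 1: 0.6, 2: 0.7}

        def experiment(seed):
            return {"t": {"auc": values[seed]}}

        report = repeat_runs(experiment, 3, 0)
        vals = np.array(list(values.values()))
        mean, sd = report.per_task["t"]["auc"]
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=1))

    def test_single_repeat_flags_degenerate_sd(self):
        report = repeat_runs(lambda s: {"t": {"auc": 0.9}}, 1, 0)
        assert report.degenerate_sd
        assert report.per_task["t"]["auc"] == (0.9, 0.0)

    def test_constant_experiment_zero_sd(self):
        report = repeat_runs(lambda s: {"t": {"acc": 0.5}}, 4, 0)
        assert report.per_task["t"]["acc"] == (0.5, 0.0)
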