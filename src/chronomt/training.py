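"""Splitting, imbalance-aware sampling, and the optimization loops.

Single- and multi-task models train with Adam on binary cross-entropy.
Class imbalance is handled by inverse-frequency weighted sampling with
replacement; the multi-task loop interleaves single-task batches from a
balanced batch iterator (tasks strictly alternate; the smaller task is
resampled with replacement so both contribute the same batch count per
epoch) and weights each batch's loss by the PCWL schedule.  Splits are
stratified 60/20/20 by default; the checkpoint with the best validation
AUC is kept.

The estimator classes at the bottom wrap these loops in the familiar
fit/predict interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .evaluate import MetricsReport, compute_metrics
from .networks import ModelConfig, MultiTaskNet, SingleTaskNet
from .nn import Adam, Tensor
from .pcwl import ScheduleConfig, ScheduleState, focus_for, stage_for_epoch, task_weights
from .select import TaskDataset

__all__ = [
    "TrainConfig",
    "SplitIndices",
    "stratified_split",
    "class_balance_weights",
    "balanced_batch_iterator",
    "train_single_task",
    "train_multi_task",
    "train_multi_task_uniform",
    "repeat_runs",
    "SingleTaskCNNLSTMClassifier",
    "MultiTaskCNNLSTMClassifier",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 300
    n_repeats: int = 10
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    selection_metric: str = "auc"
    redraw_split: bool = True  # repeated runs re-draw the split per seed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1 or self.epochs < 1 or self.n_repeats < 1:
            raise ValueError("batch_size, epochs, n_repeats must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split subsets must be pairwise disjoint")


def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitIndices:
    """Per-class proportional train/validation/test allocation.

    Within each class, subset sizes follow largest-remainder rounding of
    the requested fractions, so every subset's class ratio is within one
    patient of the overall ratio.  Deterministic given the seed.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to stratify")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    subsets: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_c = len(idx)
        quotas = [f * n_c for f in fractions]
        base = [math.floor(q) for q in quotas]
        remainder = n_c - sum(base)
        order = sorted(range(3), key=lambda i: (-(quotas[i] - base[i]), i))
        for i in order[:remainder]:
            base[i] += 1
        start = 0
        for i, size in enumerate(base):
            subsets[i].extend(idx[start : start + size].tolist())
            start += size
    return SplitIndices(
        train=np.array(sorted(subsets[0])),
        validation=np.array(sorted(subsets[1])),
        test=np.array(sorted(subsets[2])),
    )


def class_balance_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse class-frequency sample weights: weight = 1 / count(class).

    Sampling with replacement under these weights draws each class with
    expected frequency one half.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    return np.array([1.0 / count_of[y] for y in labels])


def _n_of(d) -> int:
    if isinstance(d, int):
        return d
    if hasattr(d, "n_patients"):
        return d.n_patients
    return len(d)


def balanced_batch_iterator(
    datasets: dict,
    batch_size: int,
    seed: int,
    sample_weights: dict[str, np.ndarray] | None = None,
    task_order: list[str] | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Single-task batches with strict task alternation.

    Per epoch each task contributes ceil(n_max / batch_size) batches; a
    task matching the largest size is covered by a plain permutation
    (every sample exactly once), smaller tasks are resampled with
    replacement.  Optional per-task sample weights switch a task to
    weighted sampling with replacement.  Returns (task, index-array)
    pairs; deterministic given the seed.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    sizes = {t: _n_of(d) for t, d in datasets.items()}
    if any(n == 0 for n in sizes.values()):
        raise ValueError("empty dataset")
    if task_order is None:
        task_order = list(datasets)
    n_max = max(sizes.values())
    n_batches = math.ceil(n_max / batch_size)
    rng = np.random.default_rng(seed)
    streams: dict[str, list[np.ndarray]] = {}
    for task in task_order:
        n = sizes[task]
        if sample_weights is not None and sample_weights.get(task) is not None:
            w = np.asarray(sample_weights[task], dtype=float)
            idx = rng.choice(n, size=n_batches * batch_size, replace=True, p=w / w.sum())
        elif n == n_max:
            idx = rng.permutation(n)
        else:
            idx = rng.choice(n, size=n_batches * batch_size, replace=True)
        streams[task] = [
            idx[b * batch_size : (b + 1) * batch_size] for b in range(n_batches)
        ]
    batches: list[tuple[str, np.ndarray]] = []
    for b in range(n_batches):
        for task in task_order:
            batch = streams[task][b]
            if len(batch):
                batches.append((task, batch))
    return batches


# --------------------------------------------------------------- primitives
def _bce(p: Tensor, y: np.ndarray) -> Tensor:
    yt = Tensor(np.asarray(y, dtype=float))
    eps = 1e-7
    return -(yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log()).mean()


class _Scaler:
    """Per-feature z-scoring from training-split statistics."""

    def __init__(self, X_train: np.ndarray):
        self.mean = X_train.mean(axis=(0, 1))
        sd = X_train.std(axis=(0, 1))
        sd[sd < 1e-12] = 1.0
        self.sd = sd

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _check_finite(loss: float, where: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite loss at {where}")


def train_single_task(
    model: SingleTaskNet,
    dataset: TaskDataset,
    config: TrainConfig,
    split: SplitIndices | None = None,
) -> tuple[SingleTaskNet, list[dict]]:
    """Adam/BCE training with inverse-frequency sampling; returns the
    best-validation-AUC checkpoint and the per-epoch history."""
    if split is None:
        split = stratified_split(dataset.y, config.split_fractions, seed=config.seed)
    scaler = _Scaler(dataset.X[split.train])
    X_train, y_train = scaler(dataset.X[split.train]), dataset.y[split.train]
    X_val, y_val = scaler(dataset.X[split.validation]), dataset.y[split.validation]
    weights = class_balance_weights(y_train)
    probs = weights / weights.sum()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = len(y_train)
    best_score, best_state = -np.inf, model.state_arrays()
    history: list[dict] = []
    for epoch in range(config.epochs):
        model.train()
        order = rng.choice(n, size=n, replace=True, p=probs)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            p = model(X_train[idx])
            loss = _bce(p, y_train[idx])
            _check_finite(loss.item(), f"epoch {epoch}, batch at {start}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        model.eval()
        val_metrics = compute_metrics(y_val, model(X_val).data)
        record = {"epoch": epoch, "train_loss": epoch_loss / n}
        record.update({f"val_{k}": v for k, v in val_metrics.items()})
        history.append(record)
        score = val_metrics[config.selection_metric]
        if np.isfinite(score) and score > best_score:
            best_score = score
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    model.eval()
    return model, history


def _prepare_multi(datasets, config, splits):
    if splits is None:
        splits = {
            t: stratified_split(d.y, config.split_fractions, seed=config.seed)
            for t, d in datasets.items()
        }
    scalers = {t: _Scaler(d.X[splits[t].train]) for t, d in datasets.items()}
    train = {
        t: (scalers[t](d.X[splits[t].train]), d.y[splits[t].train])
        for t, d in datasets.items()
    }
    val = {
        t: (scalers[t](d.X[splits[t].validation]), d.y[splits[t].validation])
        for t, d in datasets.items()
    }
    weights = {t: class_balance_weights(y) for t, (_, y) in train.items()}
    return splits, scalers, train, val, weights


def _val_record(model, val, epoch: int) -> dict:
    model.eval()
    record = {"epoch": epoch}
    for task, (Xv, yv) in val.items():
        metrics = compute_metrics(yv, model(Xv, task).data)
        record.update({f"val_{task}_{k}": v for k, v in metrics.items()})
    return record


def train_multi_task(
    model: MultiTaskNet,
    datasets: dict[str, TaskDataset],
    schedule: ScheduleConfig,
    config: TrainConfig,
    splits: dict[str, SplitIndices] | None = None,
) -> tuple[MultiTaskNet, list[dict], list[dict]]:
    """PCWL-weighted multi-task training.

    Each iteration takes one single-task batch from the balanced iterator,
    weights its loss by the schedule's current task weight, steps Adam and
    advances the schedule.  Returns (model at the central task's best
    validation checkpoint, per-epoch history, per-iteration weight trace).
    """
    if set(schedule.initial_weights) != set(datasets):
        raise ValueError("schedule tasks and dataset tasks differ")
    task_order = [schedule.central_task] + [
        t for t in datasets if t != schedule.central_task
    ]
    splits, scalers, train, val, weights = _prepare_multi(datasets, config, splits)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    sizes = {t: len(y) for t, (_, y) in train.items()}
    state = ScheduleState()
    history: list[dict] = []
    trace: list[dict] = []
    best_score, best_state = -np.inf, model.state_arrays()
    for epoch in range(config.epochs):
        batches = balanced_batch_iterator(
            sizes, config.batch_size, seed=int(rng.integers(2**31)),
            sample_weights=weights, task_order=task_order,
        )
        model.train()
        for task, idx in batches:
            Xb, yb = train[task][0][idx], train[task][1][idx]
            p = model(Xb, task)
            loss = _bce(p, yb)
            _check_finite(loss.item(), f"epoch {epoch}, iteration {state.iteration}")
            w = task_weights(state, schedule, task_order)
            weighted = w[task] * loss
            opt.zero_grad()
            weighted.backward()
            opt.step()
            row = {
                "epoch": state.epoch,
                "iteration": state.iteration,
                "stage": stage_for_epoch(state.epoch, schedule),
                "focus": focus_for(state, schedule, task_order),
                "task": task,
                "loss": loss.item(),
            }
            row.update({f"w_{t}": w[t] for t in task_order})
            trace.append(row)
            state.advance(len(batches))
        record = _val_record(model, val, epoch)
        history.append(record)
        score = record[f"val_{schedule.central_task}_{config.selection_metric}"]
        if np.isfinite(score) and score > best_score:
            best_score = score
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    model.eval()
    return model, history, trace


def train_multi_task_uniform(
    model: MultiTaskNet,
    datasets: dict[str, TaskDataset],
    config: TrainConfig,
    splits: dict[str, SplitIndices] | None = None,
    checkpoint_task: str | None = None,
) -> tuple[MultiTaskNet, list[dict]]:
    """Plain alternating multi-task training with unit task weights.

    The schedule-free reference: identical batching and optimization but
    every task's loss weight is 1 at every iteration.
    """
    task_order = list(datasets)
    if checkpoint_task is None:
        checkpoint_task = task_order[0]
    else:
        task_order = [checkpoint_task] + [t for t in task_order if t != checkpoint_task]
    splits, scalers, train, val, weights = _prepare_multi(datasets, config, splits)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    sizes = {t: len(y) for t, (_, y) in train.items()}
    history: list[dict] = []
    best_score, best_state = -np.inf, model.state_arrays()
    for epoch in range(config.epochs):
        batches = balanced_batch_iterator(
            sizes, config.batch_size, seed=int(rng.integers(2**31)),
            sample_weights=weights, task_order=task_order,
        )
        model.train()
        for task, idx in batches:
            Xb, yb = train[task][0][idx], train[task][1][idx]
            loss = _bce(model(Xb, task), yb)
            _check_finite(loss.item(), f"epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        record = _val_record(model, val, epoch)
        history.append(record)
        score = record[f"val_{checkpoint_task}_{config.selection_metric}"]
        if np.isfinite(score) and score > best_score:
            best_score = score
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    model.eval()
    return model, history


def repeat_runs(experiment, n_repeats: int, base_seed: int) -> MetricsReport:
    """Run ``experiment(seed)`` for seeds base..base+n-1 and aggregate the
    returned {task: {metric: value}} dictionaries into mean ± sd."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    runs = [experiment(base_seed + i) for i in range(n_repeats)]
    return MetricsReport.from_runs(runs)


# ------------------------------------------------------------- estimators
class SingleTaskCNNLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Single-task CNN-LSTM (or plain LSTM/GRU/RNN baseline) classifier.

    Accepts ``X`` of shape [N, T, F].  ``use_cnn=False`` with
    ``cell_type`` in {LSTM, GRU, RNN} gives the recurrent baselines.
    """

    def __init__(
        self,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        use_cnn: bool = True,
        seed: int = 0,
    ):
        self.model_config = model_config
        self.train_config = train_config
        self.use_cnn = use_cnn
        self.seed = seed

    def _configs(self):
        mc = self.model_config if self.model_config is not None else ModelConfig()
        tc = self.train_config if self.train_config is not None else TrainConfig()
        return mc, replace(tc, seed=self.seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SingleTaskCNNLSTMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 3:
            raise ValueError("X must be [N, T, F]")
        mc, tc = self._configs()
        dataset = TaskDataset(
            task="task", X=X, y=y,
            feature_names=[f"x{i}" for i in range(X.shape[2])],
            patient_ids=np.arange(len(y)),
        )
        self.classes_ = np.unique(y)
        self.split_ = stratified_split(y, tc.split_fractions, seed=tc.seed)
        model = SingleTaskNet(X.shape[2], mc, use_cnn=self.use_cnn, seed=self.seed)
        self.model_, self.history_ = train_single_task(model, dataset, tc, self.split_)
        self.scaler_ = _Scaler(X[self.split_.train])
        self.test_metrics_ = compute_metrics(
            y[self.split_.test], self.predict_proba(X[self.split_.test])[:, 1]
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        self.model_.eval()
        p = self.model_(self.scaler_(np.asarray(X, dtype=float))).data
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class MultiTaskCNNLSTMClassifier(BaseEstimator):
    """Multi-task CNN-LSTM with the PCWL schedule.

    ``fit`` takes a mapping task -> :class:`TaskDataset`; predictions are
    per task.  ``test_metrics_`` holds each task's test-split metrics of
    the best-validation checkpoint.
    """

    def __init__(
        self,
        schedule_config: ScheduleConfig | None = None,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ):
        self.schedule_config = schedule_config
        self.model_config = model_config
        self.train_config = train_config
        self.seed = seed

    def fit(self, datasets: dict[str, TaskDataset], y=None) -> "MultiTaskCNNLSTMClassifier":
        mc = self.model_config if self.model_config is not None else ModelConfig()
        tc = self.train_config if self.train_config is not None else TrainConfig()
        tc = replace(tc, seed=self.seed)
        sched = self.schedule_config
        if sched is None:
            tasks = list(datasets)
            sched = ScheduleConfig(
                central_task=tasks[0], initial_weights={t: 1.0 for t in tasks}
            )
        model = MultiTaskNet(
            {t: d.X.shape[2] for t, d in datasets.items()}, mc, seed=self.seed
        )
        self.splits_ = {
            t: stratified_split(d.y, tc.split_fractions, seed=tc.seed)
            for t, d in datasets.items()
        }
        self.model_, self.history_, self.trace_ = train_multi_task(
            model, datasets, sched, tc, self.splits_
        )
        self.scalers_ = {
            t: _Scaler(d.X[self.splits_[t].train]) for t, d in datasets.items()
        }
        self.test_metrics_ = {
            t: compute_metrics(
                d.y[self.splits_[t].test],
                self.predict_proba(d.X[self.splits_[t].test], t),
            )
            for t, d in datasets.items()
        }
        return self

    def predict_proba(self, X: np.ndarray, task: str) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        self.model_.eval()
        return self.model_(self.scalers_[task](np.asarray(X, dtype=float)), task).data

    def predict(self, X: np.ndarray, task: str) -> np.ndarray:
        return (self.predict_proba(X, task) >= 0.5).astype(int)
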