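"""Metrics, repeated-run reports, and the N-time-step experiment family.

Metrics are stored in [0, 1] and displayed x100 (percent, two decimals) to
match the usual clinical-prediction table layout.  AUC is the pairwise
rank statistic (ties half credit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

__all__ = [
    "METRIC_NAMES",
    "MetricsReport",
    "compute_metrics",
    "n_time_step_experiment",
    "render_report",
]

METRIC_NAMES = ("accuracy", "auc", "f1", "precision", "recall")


def compute_metrics(
    y_true: np.ndarray, p: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, AUC, F1, precision and recall from probabilities.

    Accuracy/precision/recall/F1 come from the confusion matrix at
    ``threshold``; AUC from pairwise concordance.  With single-class truth
    the AUC is undefined and reported as NaN.
    """
    y_true = np.asarray(y_true).astype(int)
    p = np.asarray(p, dtype=float)
    if y_true.shape != p.shape:
        raise ValueError("y_true and p must have equal length")
    y_pred = (p >= threshold).astype(int)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
    }
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class truth: AUC undefined", RuntimeWarning)
        out["auc"] = float("nan")
    else:
        out["auc"] = float(roc_auc_score(y_true, p))
    return out


@dataclass
class MetricsReport:
    """Mean and sample standard deviation of each metric over repeated
    runs, per task."""

    per_task: dict[str, dict[str, tuple[float, float]]]
    n_runs: int
    degenerate_sd: bool = False

    @classmethod
    def from_runs(cls, runs: list[dict[str, dict[str, float]]]) -> "MetricsReport":
        """Aggregate per-run {task: {metric: value}} dictionaries."""
        if not runs:
            raise ValueError("no runs to aggregate")
        tasks = list(runs[0])
        per_task: dict[str, dict[str, tuple[float, float]]] = {}
        for task in tasks:
            per_task[task] = {}
            for metric in runs[0][task]:
                vals = np.array([r[task][metric] for r in runs], dtype=float)
                mean = float(np.nanmean(vals))
                sd = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
                per_task[task][metric] = (mean, sd)
        return cls(per_task=per_task, n_runs=len(runs), degenerate_sd=len(runs) == 1)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "degenerate_sd": self.degenerate_sd,
            "per_task": {
                t: {m: {"mean": v[0], "sd": v[1]} for m, v in metrics.items()}
                for t, metrics in self.per_task.items()
            },
        }


def _cell(mean: float, sd: float) -> str:
    if not np.isfinite(mean):
        warnings.warn("empty metric rendered as em dash", RuntimeWarning)
        return "—"
    return f"{100 * mean:.2f} ± {100 * sd:.2f}"


def render_report(
    reports: dict[str, MetricsReport], style: str = "table3"
) -> str:
    """Aligned text table, one row per (label, task), cells 'mean ± sd' in
    percent.  ``style`` names the layout family: per-method rows
    ('table3') or per-time-step rows ('table5'); both share the format."""
    if not reports:
        raise ValueError("no reports to render")
    if style not in ("table3", "table5"):
        raise ValueError(f"unknown style {style!r}")
    row_head = "Method" if style == "table3" else "Time steps"
    header = ["Task", row_head] + [m.capitalize() for m in METRIC_NAMES]
    rows = [header]
    for label, report in reports.items():
        for task, metrics in report.per_task.items():
            row = [task, str(label)]
            for m in METRIC_NAMES:
                mean, sd = metrics.get(m, (float("nan"), float("nan")))
                row.append(_cell(mean, sd))
            rows.append(row)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)


def n_time_step_experiment(
    panel,
    tasks: dict[str, list[str]],
    schedule_config,
    train_config,
    n_range=range(2, 8),
    n_repeats: int = 1,
) -> dict[int, MetricsReport]:
    """Train the multi-task model on the last N input waves for each N.

    ``tasks`` maps task id -> selected feature names.  The label wave is
    the panel's final wave, so N ranges up to ``n_waves - 1``; each N
    yields one repeated-run metrics report.
    """
    from .select import build_tensor
    from .training import MultiTaskCNNLSTMClassifier, repeat_runs

    n_range = list(n_range)
    if max(n_range) > panel.n_waves - 1:
        raise ValueError(
            f"N={max(n_range)} exceeds the {panel.n_waves - 1} available input waves"
        )
    out: dict[int, MetricsReport] = {}
    for n in n_range:
        datasets = {
            task: build_tensor(panel, feats, n, task) for task, feats in tasks.items()
        }

        def run_once(seed: int) -> dict[str, dict[str, float]]:
            clf = MultiTaskCNNLSTMClassifier(
                schedule_config=schedule_config,
                train_config=train_config,
                seed=seed,
            )
            clf.fit(datasets)
            return clf.test_metrics_

        out[n] = repeat_runs(run_once, n_repeats, train_config.seed)
    return out
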