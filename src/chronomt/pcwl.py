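"""Periodic and central weighted learning (PCWL) schedule.

Two tasks share one model; a rule-based schedule decides, at every
optimizer iteration, which task is the *focus* and what loss weight each
task receives:

* **PWL** (periodic weighted learning) — the focus rotates between tasks
  in blocks of ``cycle_length`` iterations (default 20), starting at the
  central task.
* **CWL** (central weighted learning) — the central task is the focus at
  every iteration.

Epochs alternate PWL, CWL, PWL, … (0-based even epochs are PWL).  The
focus task keeps its configured initial weight; every other task's initial
weight is multiplied by ``aux_multiplier`` (default 0.1) — a constant
per-iteration multiplier on the *initial* weight, not a cumulative decay
(cumulative multiplication would underflow within one epoch, contradicting
the fixed displayed weights of the scheme).  The overall loss is the
weighted sum of task losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ScheduleConfig",
    "ScheduleState",
    "stage_for_epoch",
    "focus_for",
    "task_weights",
    "combined_loss",
    "weight_trace",
]

STANDARD_WEIGHT_RATIOS = (1, 3, 6, 9, 12, 15)  # central : auxiliary


@dataclass
class ScheduleConfig:
    central_task: str
    initial_weights: dict[str, float]
    cycle_length: int = 20
    aux_multiplier: float = 0.1
    alternate_stages: bool = True  # per-epoch PWL/CWL alternation

    def __post_init__(self) -> None:
        if self.central_task not in self.initial_weights:
            raise ValueError("central_task must appear in initial_weights")
        if any(w <= 0 for w in self.initial_weights.values()):
            raise ValueError("initial weights must be positive")
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be >= 1")
        if not 0.0 < self.aux_multiplier <= 1.0:
            raise ValueError("aux_multiplier must be in (0, 1]")

    @classmethod
    def from_ratio(
        cls, central_task: str, auxiliary_task: str, ratio: float, **kwargs
    ) -> "ScheduleConfig":
        """Build from a central:auxiliary ratio, e.g. 3 for [3:1]."""
        return cls(
            central_task=central_task,
            initial_weights={central_task: float(ratio), auxiliary_task: 1.0},
            **kwargs,
        )


@dataclass
class ScheduleState:
    epoch: int = 0
    iteration: int = 0  # within the current epoch

    def advance(self, iterations_per_epoch: int | None = None) -> None:
        """Advance by one iteration; roll the epoch when its length is known."""
        self.iteration += 1
        if iterations_per_epoch is not None and self.iteration >= iterations_per_epoch:
            self.iteration = 0
            self.epoch += 1


def stage_for_epoch(epoch: int, config: ScheduleConfig | None = None) -> str:
    """'PWL' on even (0-based) epochs, 'CWL' on odd ones."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if config is not None and not config.alternate_stages:
        return "PWL"
    return "PWL" if epoch % 2 == 0 else "CWL"


def focus_for(
    state: ScheduleState, config: ScheduleConfig, task_order: list[str]
) -> str:
    """Focus task at the state's (epoch, iteration).

    PWL rotates round-robin in blocks of ``cycle_length``, with the order
    rotated so the central task goes first; CWL always focuses the central
    task.
    """
    if config.central_task not in task_order:
        raise ValueError("task_order must contain the central task")
    if stage_for_epoch(state.epoch, config) == "CWL":
        return config.central_task
    start = task_order.index(config.central_task)
    order = task_order[start:] + task_order[:start]
    block = (state.iteration // config.cycle_length) % len(order)
    return order[block]


def task_weights(
    state: ScheduleState, config: ScheduleConfig, task_order: list[str] | None = None
) -> dict[str, float]:
    """Per-task loss weights at this iteration.

    The focus task gets its initial weight; every other task gets its
    initial weight times ``aux_multiplier``.
    """
    if task_order is None:
        task_order = list(config.initial_weights)
    focus = focus_for(state, config, task_order)
    return {
        task: w if task == focus else w * config.aux_multiplier
        for task, w in config.initial_weights.items()
    }


def combined_loss(
    task_losses: dict[str, float], weights: dict[str, float]
) -> float:
    """Weighted sum of per-task losses."""
    if set(task_losses) != set(weights):
        raise KeyError("task_losses and weights must have identical task sets")
    return float(sum(weights[t] * task_losses[t] for t in task_losses))


def weight_trace(
    config: ScheduleConfig,
    task_order: list[str],
    n_epochs: int,
    iterations_per_epoch: int,
) -> list[dict]:
    """The full deterministic schedule: one record per iteration with
    epoch, iteration, stage, focus and each task's weight."""
    rows = []
    for epoch in range(n_epochs):
        stage = stage_for_epoch(epoch, config)
        for it in range(iterations_per_epoch):
            state = ScheduleState(epoch=epoch, iteration=it)
            weights = task_weights(state, config, task_order)
            row = {
                "epoch": epoch,
                "iteration": it,
                "stage": stage,
                "focus": focus_for(state, config, task_order),
            }
            for task in task_order:
                row[f"w_{task}"] = weights[task]
            rows.append(row)
    return rows
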