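"""Run configuration: YAML schema, validation, defaults, and the
end-to-end pipeline driver.

A run config composes the stage configs (synthetic cohort, imputer,
selection, model, schedule, training) plus an output directory and a
top-level seed.  Unknown keys are rejected by name; a config without an
explicit seed is an error — no stage may fall back to system entropy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluate import MetricsReport, render_report
from .impute import RecurrentImputer
from .networks import ModelConfig
from .panel import CohortPanel
from .pcwl import ScheduleConfig
from .select import SelectionConfig, build_tensor, exclude_diagnostic, missingness_filter, select_features
from .simulate import SyntheticSpec, eligibility_filter, generate_panel
from .training import (
    MultiTaskCNNLSTMClassifier,
    SingleTaskCNNLSTMClassifier,
    TrainConfig,
    repeat_runs,
)

__all__ = ["RunConfig", "load_config", "parse_weights", "run_pipeline"]


def parse_weights(spec: str) -> float:
    """Parse a 'central:auxiliary' ratio string like '15:1'."""
    try:
        central, aux = spec.split(":")
        central, aux = float(central), float(aux)
    except ValueError:
        raise ValueError(f"weight ratio must look like '3:1', got {spec!r}") from None
    if central <= 0 or aux <= 0:
        raise ValueError("weights must be positive")
    return central / aux


@dataclass
class RunConfig:
    seed: int
    output_dir: str = "runs/run"
    synthetic: SyntheticSpec | None = None
    data_paths: dict[str, str] | None = None  # values/mask/labels CSVs
    imputer: dict = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: ScheduleConfig | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    central_task: str = "diabetes"
    n_waves_in: int | None = None  # default: all input waves
    train_single: bool = True
    train_multi: bool = True
    missing_mechanism: str = "MCAR"
    # imputed values are computed once and reused after feature selection;
    # this flag re-fits the imputer on the selected feature subset instead
    reimpute_after_selection: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.synthetic is None and self.data_paths is None:
            raise ValueError("config needs either a 'synthetic' spec or 'data' paths")


_SECTION_FIELDS = {
    "synthetic": {f.name for f in dataclasses.fields(SyntheticSpec)},
    "selection": {f.name for f in dataclasses.fields(SelectionConfig)},
    "model": {f.name for f in dataclasses.fields(ModelConfig)},
    "train": {f.name for f in dataclasses.fields(TrainConfig)},
}
_TOP_KEYS = {
    "seed", "output_dir", "synthetic", "data", "imputer", "selection", "model",
    "schedule", "train", "central_task", "n_waves_in", "train_single",
    "train_multi", "missing_mechanism", "reimpute_after_selection", "verbosity",
}
_IMPUTER_KEYS = {
    "hidden_size", "learning_rate", "batch_size", "epochs", "consistency_weight",
    "aux_classify_weight", "classify_task", "validation_fraction", "patience",
}
_SCHEDULE_KEYS = {"central_task", "weights", "initial_weights", "cycle_length",
                  "aux_multiplier", "alternate_stages"}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    for key in given:
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in config section {section!r}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; fills documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys("<top-level>", raw, _TOP_KEYS)
    if "seed" not in raw:
        raise ValueError("config must set an explicit 'seed' (no implicit entropy)")
    seed = int(raw["seed"])

    synthetic = None
    if "synthetic" in raw:
        sect = dict(raw["synthetic"])
        _check_keys("synthetic", sect, _SECTION_FIELDS["synthetic"])
        sect.setdefault("seed", seed)
        synthetic = SyntheticSpec(**sect)

    data_paths = raw.get("data")
    if data_paths is not None:
        _check_keys("data", data_paths, {"values", "mask", "labels"})
        if "values" not in data_paths:
            raise ValueError("data section requires a 'values' path")

    sect = dict(raw.get("selection", {}))
    _check_keys("selection", sect, _SECTION_FIELDS["selection"])
    sect.setdefault("seed", seed)
    selection = SelectionConfig(**sect)

    sect = dict(raw.get("model", {}))
    _check_keys("model", sect, _SECTION_FIELDS["model"])
    model = ModelConfig(**sect)

    sect = dict(raw.get("train", {}))
    _check_keys("train", sect, _SECTION_FIELDS["train"])
    sect.setdefault("seed", seed)
    if "split_fractions" in sect:
        sect["split_fractions"] = tuple(sect["split_fractions"])
    train = TrainConfig(**sect)

    imputer = dict(raw.get("imputer", {}))
    _check_keys("imputer", imputer, _IMPUTER_KEYS)

    central_task = raw.get("central_task", "diabetes")
    schedule = None
    if "schedule" in raw:
        sect = dict(raw["schedule"])
        _check_keys("schedule", sect, _SCHEDULE_KEYS)
        sched_central = sect.get("central_task", central_task)
        central_task = sched_central
        if "weights" in sect:
            ratio = parse_weights(str(sect["weights"]))
            initial = None
        else:
            ratio = None
            initial = sect.get("initial_weights")
        kwargs = {
            k: sect[k]
            for k in ("cycle_length", "aux_multiplier", "alternate_stages")
            if k in sect
        }
        if initial is not None:
            schedule = ScheduleConfig(
                central_task=sched_central, initial_weights=dict(initial), **kwargs
            )
        else:
            # auxiliary task names are resolved at pipeline time; store ratio
            schedule = ("ratio", sched_central, ratio if ratio is not None else 1.0, kwargs)

    return RunConfig(
        seed=seed,
        output_dir=raw.get("output_dir", "runs/run"),
        synthetic=synthetic,
        data_paths=data_paths,
        imputer=imputer,
        selection=selection,
        model=model,
        schedule=schedule,
        train=train,
        central_task=central_task,
        n_waves_in=raw.get("n_waves_in"),
        train_single=bool(raw.get("train_single", True)),
        train_multi=bool(raw.get("train_multi", True)),
        missing_mechanism=str(raw.get("missing_mechanism", "MCAR")),
        reimpute_after_selection=bool(raw.get("reimpute_after_selection", False)),
        verbosity=int(raw.get("verbosity", 1)),
    )


def _log(config: RunConfig, stage: str, message: str) -> None:
    if config.verbosity > 0:
        print(f"[{stage}] {message}")


def _resolve_schedule(config: RunConfig, tasks: list[str]) -> ScheduleConfig:
    sched = config.schedule
    if isinstance(sched, ScheduleConfig):
        return sched
    central = config.central_task
    ratio, kwargs = 1.0, {}
    if isinstance(sched, tuple):
        _, central, ratio, kwargs = sched
    aux = [t for t in tasks if t != central]
    weights = {central: float(ratio)}
    weights.update({t: 1.0 for t in aux})
    return ScheduleConfig(central_task=central, initial_weights=weights, **kwargs)


def run_pipeline(config: RunConfig) -> Path:
    """Simulate/load -> eligibility -> missingness filter -> impute ->
    diagnostic exclusion -> LASSO -> tensors -> train -> evaluate.

    Every stage's artifacts and seeds are written under the run directory;
    the run is a pure function of the config.
    """
    from .io import read_panel, write_json, write_panel

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        _log(config, "simulate", f"generating panel with seed {config.synthetic.seed}")
        panel = generate_panel(config.synthetic)
        write_panel(panel, out, stem="panel")
    else:
        paths = config.data_paths
        _log(config, "load", f"reading panel from {paths['values']}")
        panel = read_panel(paths["values"], paths.get("mask"), paths.get("labels"))
    tasks = panel.tasks

    # per-task eligibility exclusion on one master panel -> overlapping cohorts
    cohorts: dict[str, CohortPanel] = {}
    for task in tasks:
        cohorts[task] = eligibility_filter(panel, task)
        _log(config, "eligibility", f"{task}: {cohorts[task].n_patients} eligible")

    survivors = {t: missingness_filter(c, config.selection.missing_threshold)
                 for t, c in cohorts.items()}

    selections = {}
    datasets = {}
    for task in tasks:
        raw_cohort = cohorts[task].subset_features(survivors[task])
        cohort = raw_cohort
        if not cohort.observed_mask.all():
            _log(config, "impute", f"{task}: fitting recurrent imputer")
            imputer = RecurrentImputer(seed=config.seed, **config.imputer)
            cohort = imputer.fit_transform(cohort)
        candidates = exclude_diagnostic(
            list(cohort.feature_names), task, config.selection
        )
        result = select_features(cohort, task, config.selection, candidates)
        selections[task] = result
        if config.reimpute_after_selection and not raw_cohort.observed_mask.all():
            _log(config, "impute", f"{task}: re-imputing on selected features")
            sub = raw_cohort.subset_features(result.selected_features)
            imputer = RecurrentImputer(seed=config.seed, **config.imputer)
            cohort = imputer.fit_transform(sub)
        _log(
            config, "select",
            f"{task}: alpha={result.best_alpha}, "
            f"{len(result.selected_features)} features",
        )
        n_in = config.n_waves_in or cohort.n_waves - 1
        datasets[task] = build_tensor(cohort, result.selected_features, n_in, task)
    write_json({t: r.to_dict() for t, r in selections.items()}, out / "selection.json")

    report: dict = {"seed": config.seed, "tasks": tasks}
    reports_for_table: dict[str, MetricsReport] = {}

    if config.train_single:
        single_metrics = {}
        for task in tasks:
            _log(config, "train-single", f"{task}: CNN-LSTM")

            def run_once(seed: int, task=task) -> dict:
                clf = SingleTaskCNNLSTMClassifier(
                    model_config=config.model, train_config=config.train, seed=seed
                )
                clf.fit(datasets[task].X, datasets[task].y)
                return {task: clf.test_metrics_}

            single_metrics[task] = repeat_runs(
                run_once, config.train.n_repeats, config.seed
            )
        report["single_task"] = {
            t: r.to_dict() for t, r in single_metrics.items()
        }
        for t, r in single_metrics.items():
            reports_for_table[f"CNN-LSTM ({t})"] = r

    if config.train_multi:
        schedule = _resolve_schedule(config, tasks)
        _log(config, "train-multi", f"central={schedule.central_task}")

        def run_multi(seed: int) -> dict:
            clf = MultiTaskCNNLSTMClassifier(
                schedule_config=schedule,
                model_config=config.model,
                train_config=config.train,
                seed=seed,
            )
            clf.fit(datasets)
            return clf.test_metrics_

        multi_report = repeat_runs(run_multi, config.train.n_repeats, config.seed)
        report["multi_task"] = multi_report.to_dict()
        reports_for_table["Multi-task CNN-LSTM"] = multi_report

        # persist one weight trace for audit
        clf = MultiTaskCNNLSTMClassifier(
            schedule_config=schedule, model_config=config.model,
            train_config=dataclasses.replace(config.train, epochs=1),
            seed=config.seed,
        )
        clf.fit(datasets)
        import pandas as pd

        pd.DataFrame(clf.trace_).to_csv(out / "weights_trace.csv", index=False)

    write_json(report, out / "report.json")
    if reports_for_table:
        (out / "report.txt").write_text(render_report(reports_for_table) + "\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_snapshot(config), fh)
    _log(config, "done", f"artifacts in {out}")
    return out


def _snapshot(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return clean(
        {
            "seed": config.seed,
            "output_dir": config.output_dir,
            "synthetic": config.synthetic,
            "data": config.data_paths,
            "imputer": config.imputer,
            "selection": config.selection,
            "model": config.model,
            "schedule": config.schedule
            if not isinstance(config.schedule, tuple)
            else {"central_task": config.schedule[1], "ratio": config.schedule[2]},
            "train": config.train,
            "central_task": config.central_task,
            "n_waves_in": config.n_waves_in,
        }
    )
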