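"""Panel readers and writers (wide CSV interchange).

Values: ``patient_id, wave, <feature...>`` with one row per patient per
wave; waves are 1-based and contiguous.  Mask: the same layout with 0/1
entries (missing file means all-observed).  Labels: long CSV
``patient_id, task, label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CohortPanel

__all__ = ["write_panel", "read_panel", "write_json", "read_json"]


def write_panel(panel: CohortPanel, out_dir: str | Path, stem: str = "panel") -> dict:
    """Write values/mask/labels CSVs; returns the path mapping."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n, t, _ = panel.values.shape
    pid = np.repeat(panel.patient_ids, t)
    wave = np.tile(np.arange(1, t + 1), n)
    base = {"patient_id": pid, "wave": wave}
    values = pd.DataFrame(
        {**base, **{f: panel.values[:, :, i].ravel() for i, f in enumerate(panel.feature_names)}}
    )
    mask = pd.DataFrame(
        {
            **base,
            **{
                f: panel.observed_mask[:, :, i].ravel().astype(int)
                for i, f in enumerate(panel.feature_names)
            },
        }
    )
    labels = pd.DataFrame(
        [
            {"patient_id": p, "task": task, "label": int(y_i)}
            for task, y in panel.labels.items()
            for p, y_i in zip(panel.patient_ids, y)
        ]
    )
    paths = {
        "values": out_dir / f"{stem}.values.csv",
        "mask": out_dir / f"{stem}.mask.csv",
        "labels": out_dir / f"{stem}.labels.csv",
    }
    values.to_csv(paths["values"], index=False)
    mask.to_csv(paths["mask"], index=False)
    labels.to_csv(paths["labels"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _pivot(df: pd.DataFrame, features: list[str]) -> np.ndarray:
    df = df.sort_values(["patient_id", "wave"])
    patients = df["patient_id"].unique()
    waves = np.sort(df["wave"].unique())
    if not np.array_equal(waves, np.arange(1, len(waves) + 1)):
        raise ValueError(f"wave index must be contiguous starting at 1, got {waves.tolist()}")
    expected = len(patients) * len(waves)
    if len(df) != expected:
        raise ValueError("values table is not a complete patient x wave grid")
    arr = df[features].to_numpy(dtype=float).reshape(len(patients), len(waves), len(features))
    return arr


def read_panel(
    values_path: str | Path,
    mask_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    wave_interval_years: float = 2.0,
) -> CohortPanel:
    """Read a panel from CSVs; validates shape, contiguity and labels."""
    values_df = pd.read_csv(values_path)
    for col in ("patient_id", "wave"):
        if col not in values_df.columns:
            raise ValueError(f"values file lacks required column {col!r}")
    features = [c for c in values_df.columns if c not in ("patient_id", "wave")]
    try:
        values = _pivot(values_df, features)
    except ValueError:
        raise
    patients = np.sort(values_df["patient_id"].unique())

    if mask_path is not None and Path(mask_path).exists():
        mask_df = pd.read_csv(mask_path)
        if sorted(mask_df.columns) != sorted(values_df.columns):
            raise ValueError("mask columns do not match values columns")
        mask = _pivot(mask_df, features).astype(bool)
    else:
        mask = np.ones_like(values, dtype=bool)

    labels: dict[str, np.ndarray] = {}
    if labels_path is not None:
        labels_df = pd.read_csv(labels_path)
        for task, group in labels_df.groupby("task"):
            by_patient = dict(zip(group["patient_id"], group["label"]))
            missing = [p for p in patients if p not in by_patient]
            if missing:
                raise ValueError(
                    f"labels for task {task!r} missing patient(s) {missing[:5]}"
                )
            labels[str(task)] = np.array([by_patient[p] for p in patients], dtype=int)

    values = np.where(mask, values, np.nan)
    return CohortPanel(
        values=values,
        observed_mask=mask,
        feature_names=features,
        labels=labels,
        patient_ids=patients,
        wave_interval_years=wave_interval_years,
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
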