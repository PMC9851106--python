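"""Longitudinal cohort panel container.

A :class:`CohortPanel` holds the three-dimensional block of clinical
measurements — one value per (patient, wave, feature) — together with an
observed-entry mask, per-task binary outcome labels taken at the final wave,
and optional metadata (ground-truth values under masked entries, the
simulator's informative-feature bookkeeping, diagnostic rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CohortPanel"]


@dataclass
class CohortPanel:
    """Panel of feature values by (patient, wave, feature).

    Attributes
    ----------
    values : ndarray, shape (n_patients, n_waves, n_features)
        Measurement values; entries where ``observed_mask`` is False are
        treated as missing by every consumer.
    observed_mask : ndarray of bool, same shape as ``values``
    feature_names : list of str
    labels : dict mapping task id -> binary int vector (n_patients,)
        Disease status at the final wave.
    patient_ids : ndarray of int
    wave_interval_years : float
        Spacing between examination waves (the emulated cohort is biannual).
    metadata : dict
        Free-form; the simulator stores ground truth here (e.g.
        ``truth_values`` for entries hidden by the missingness mechanism,
        ``informative_features``, ``diagnostic_rules``).
    """

    values: np.ndarray
    observed_mask: np.ndarray
    feature_names: list[str]
    labels: dict[str, np.ndarray]
    patient_ids: np.ndarray | None = None
    wave_interval_years: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array [patients, waves, features]")
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError("feature_names length does not match values")
        if self.patient_ids is None:
            self.patient_ids = np.arange(self.values.shape[0])
        else:
            self.patient_ids = np.asarray(self.patient_ids)
        if len(self.patient_ids) != self.values.shape[0]:
            raise ValueError("patient_ids length does not match values")
        for task, y in self.labels.items():
            y = np.asarray(y)
            if y.shape != (self.values.shape[0],):
                raise ValueError(f"labels for task {task!r} have wrong length")
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"labels for task {task!r} must be binary")
            self.labels[task] = y.astype(int)
        if not np.isfinite(self.values[self.observed_mask]).all():
            raise ValueError("observed entries must be finite")
        if self.wave_interval_years <= 0:
            raise ValueError("wave_interval_years must be positive")

    # ---------------------------------------------------------------- queries
    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    @property
    def tasks(self) -> list[str]:
        return list(self.labels)

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def missing_fraction(self) -> float:
        return float(1.0 - self.observed_mask.mean())

    # ------------------------------------------------------------------ views
    def copy(self) -> "CohortPanel":
        return CohortPanel(
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
            feature_names=list(self.feature_names),
            labels={t: y.copy() for t, y in self.labels.items()},
            patient_ids=self.patient_ids.copy(),
            wave_interval_years=self.wave_interval_years,
            metadata=dict(self.metadata),
        )

    def subset_patients(self, index: np.ndarray) -> "CohortPanel":
        """Return a panel restricted to the given patient row indices."""
        index = np.asarray(index)
        meta = dict(self.metadata)
        if "truth_values" in meta:
            meta["truth_values"] = meta["truth_values"][index]
        if "holdout_mask" in meta:
            meta["holdout_mask"] = meta["holdout_mask"][index]
        return CohortPanel(
            values=self.values[index],
            observed_mask=self.observed_mask[index],
            feature_names=list(self.feature_names),
            labels={t: y[index] for t, y in self.labels.items()},
            patient_ids=self.patient_ids[index],
            wave_interval_years=self.wave_interval_years,
            metadata=meta,
        )

    def subset_features(self, names: list[str]) -> "CohortPanel":
        idx = [self.feature_index(n) for n in names]
        meta = dict(self.metadata)
        if "truth_values" in meta:
            meta["truth_values"] = meta["truth_values"][:, :, idx]
        if "holdout_mask" in meta:
            meta["holdout_mask"] = meta["holdout_mask"][:, :, idx]
        return CohortPanel(
            values=self.values[:, :, idx],
            observed_mask=self.observed_mask[:, :, idx],
            feature_names=list(names),
            labels={t: y.copy() for t, y in self.labels.items()},
            patient_ids=self.patient_ids.copy(),
            wave_interval_years=self.wave_interval_years,
            metadata=meta,
        )
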