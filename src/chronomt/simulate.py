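"""Synthetic longitudinal multimorbidity cohorts.

The restricted community-cohort data the pipeline targets cannot be
redistributed, so this module generates panels with the statistical
structure the downstream stages assume:

* two correlated chronic-disease tasks driven by a *shared* latent AR(1)
  risk process plus a task-private AR(1) process per patient;
* informative features that load on those latent risks, plus pure-noise
  filler features;
* diagnostic-analog features (a fasting-glucose analog for the
  diabetes-like task; systolic/diastolic blood-pressure analogs for the
  hypertension-like task) expressed in real clinical units so the
  eligibility exclusion can be exercised with the literal clinical cutoffs
  (126 mg/dL; 140/90 mmHg);
* final-wave disease labels obtained by thresholding cumulative risk, with
  the threshold calibrated by empirical quantile so prevalence hits the
  requested targets (defaults 16.43% and 32.61%);
* missingness by MCAR or by monotone follow-up dropout.

Everything is a pure function of the generator seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import CohortPanel

__all__ = [
    "SyntheticSpec",
    "CalibrationError",
    "generate_panel",
    "apply_missingness",
    "eligibility_filter",
    "ar1_panel",
    "make_planted_selection_data",
    "DEFAULT_DIAGNOSTIC_RULES",
]

TASK_A = "diabetes"
TASK_B = "hypertension"

# any-of rules: (feature name, inclusive lower cutoff)
DEFAULT_DIAGNOSTIC_RULES: dict[str, list[tuple[str, float]]] = {
    TASK_A: [("glucose_analog", 126.0)],
    TASK_B: [("sbp_analog", 140.0), ("dbp_analog", 90.0)],
}

# location/scale of the diagnostic analogs (monotone in the task risk);
# chosen so the baseline exclusion removes a visibly larger share of the
# hypertension-like cohort than of the diabetes-like one, as in community
# cohorts where prevalent hypertension is the more common exclusion.
_DIAG_TRANSFORMS = {
    "glucose_analog": (103.0, 13.0, TASK_A),
    "sbp_analog": (127.0, 12.0, TASK_B),
    "dbp_analog": (81.0, 7.0, TASK_B),
}


class CalibrationError(RuntimeError):
    """Prevalence calibration failed (degenerate risk distribution)."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    ``n_features`` counts every column, including the three diagnostic
    analogs; ``n_shared_informative`` features load on the shared latent
    risk and ``n_task_specific`` on each task's own risk.
    """

    n_patients: int
    n_waves: int = 8
    n_features: int = 56
    n_shared_informative: int = 20
    n_task_specific: int = 5
    latent_autocorrelation: float = 0.8
    effect_size: float = 1.0
    target_prevalence: dict[str, float] = field(
        default_factory=lambda: {TASK_A: 0.1643, TASK_B: 0.3261}
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_waves <= 0 or self.n_features <= 0:
            raise ValueError("n_patients, n_waves, n_features must be positive")
        if not 0.0 <= self.latent_autocorrelation < 1.0:
            raise ValueError("latent_autocorrelation must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        n_informative = 3 + self.n_shared_informative + 2 * self.n_task_specific
        if n_informative > self.n_features:
            raise ValueError(
                f"{n_informative} informative columns exceed n_features={self.n_features}"
            )
        for task, p in self.target_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"target prevalence for {task!r} must be in (0, 1)")


def _ar1(rng: np.random.Generator, n: int, t: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) paths, shape (n, t)."""
    x = np.empty((n, t))
    x[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - phi**2)
    for j in range(1, t):
        x[:, j] = phi * x[:, j - 1] + innov_sd * rng.standard_normal(n)
    return x


def generate_panel(spec: SyntheticSpec) -> CohortPanel:
    """Generate a two-task cohort panel from the latent-risk model.

    Each patient carries a shared AR(1) risk path and one private AR(1)
    path per task; the task risk is their normalized sum, so the two task
    risks correlate at 0.5 and both have unit stationary variance.  Labels
    threshold the patient's mean risk over waves at the empirical quantile
    matching the target prevalence.
    """
    rng = np.random.default_rng(spec.seed)
    n, t, phi = spec.n_patients, spec.n_waves, spec.latent_autocorrelation
    tasks = list(spec.target_prevalence)
    if set(tasks) != {TASK_A, TASK_B}:
        raise ValueError(f"target_prevalence must cover tasks {TASK_A!r} and {TASK_B!r}")

    shared = _ar1(rng, n, t, phi)
    private = {task: _ar1(rng, n, t, phi) for task in (TASK_A, TASK_B)}
    risk = {task: (shared + private[task]) / np.sqrt(2.0) for task in (TASK_A, TASK_B)}

    names: list[str] = []
    columns: list[np.ndarray] = []
    informative: dict[str, list[str]] = {TASK_A: [], TASK_B: [], "shared": []}

    for name, (loc, scale, task) in _DIAG_TRANSFORMS.items():
        names.append(name)
        columns.append(loc + spec.effect_size * scale * risk[task])
        informative[task].append(name)

    for i in range(spec.n_shared_informative):
        name = f"shared_{i + 1:02d}"
        names.append(name)
        loading = rng.uniform(0.5, 1.0)
        columns.append(spec.effect_size * loading * shared + rng.standard_normal((n, t)))
        informative["shared"].append(name)

    for task, tag in ((TASK_A, "dm"), (TASK_B, "htn")):
        for i in range(spec.n_task_specific):
            name = f"{tag}_specific_{i + 1:02d}"
            names.append(name)
            loading = rng.uniform(0.5, 1.0)
            columns.append(
                spec.effect_size * loading * risk[task] + rng.standard_normal((n, t))
            )
            informative[task].append(name)

    n_noise = spec.n_features - len(names)
    for i in range(n_noise):
        names.append(f"noise_{i + 1:02d}")
        columns.append(rng.standard_normal((n, t)))

    values = np.stack(columns, axis=2)

    labels: dict[str, np.ndarray] = {}
    for task in (TASK_A, TASK_B):
        cumulative = risk[task].mean(axis=1)
        target = spec.target_prevalence[task]
        if np.ptp(cumulative) < 1e-12:
            raise CalibrationError(
                f"risk distribution for task {task!r} is degenerate; "
                "cannot calibrate prevalence"
            )
        threshold = np.quantile(cumulative, 1.0 - target)
        y = (cumulative > threshold).astype(int)
        # quantile calibration is exact to one patient; below n=100 the
        # discreteness, not the calibration, limits the attainable accuracy
        if abs(y.mean() - target) > max(0.01, 1.0 / n):
            raise CalibrationError(
                f"calibrated prevalence {y.mean():.4f} misses target {target:.4f} "
                f"for task {task!r}"
            )
        labels[task] = y

    panel = CohortPanel(
        values=values,
        observed_mask=np.ones_like(values, dtype=bool),
        feature_names=names,
        labels=labels,
        metadata={
            "informative_features": informative,
            "diagnostic_rules": {k: list(v) for k, v in DEFAULT_DIAGNOSTIC_RULES.items()},
        },
    )
    if spec.missing_rate > 0:
        # derived sub-seed keeps the whole panel a function of spec.seed
        panel = apply_missingness(
            panel, spec.missing_rate, "MCAR", seed=int(rng.integers(2**31))
        )
    return panel


def apply_missingness(
    panel: CohortPanel, rate: float, mechanism: str, seed: int
) -> CohortPanel:
    """Clear observed entries at the requested marginal rate.

    ``MCAR`` clears each observed entry independently; ``monotone_dropout``
    drops a patient entirely from a random wave onward (emulating loss to
    follow-up), with the dropout probability set so the expected cleared
    fraction equals ``rate``.  True values under newly cleared entries are
    kept in ``metadata['truth_values']`` for imputation evaluation only;
    the exposed ``values`` are NaN there.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    out = panel.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = out.observed_mask
    if mechanism == "MCAR":
        clear = rng.random(mask.shape) < rate
        new_mask = mask & ~clear
    elif mechanism == "monotone_dropout":
        n, t, _ = mask.shape
        # a dropout patient loses waves d..T-1 with d uniform on 1..T-1,
        # i.e. an expected half of their entries; scale the dropout
        # probability so the marginal cleared fraction equals `rate`
        p_drop = min(2.0 * rate, 1.0)
        is_dropout = rng.random(n) < p_drop
        dropout_wave = rng.integers(1, t, size=n)
        wave_idx = np.arange(t)[None, :]
        cleared_rows = is_dropout[:, None] & (wave_idx >= dropout_wave[:, None])
        new_mask = mask & ~cleared_rows[:, :, None]
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")

    truth = out.metadata.get("truth_values")
    if truth is None:
        truth = out.values.copy()
    holdout = mask & ~new_mask
    prior_holdout = out.metadata.get("holdout_mask")
    if prior_holdout is not None:
        holdout = holdout | prior_holdout
    out.values = np.where(new_mask, out.values, np.nan)
    out.observed_mask = new_mask
    out.metadata["truth_values"] = truth
    out.metadata["holdout_mask"] = holdout
    return out


def eligibility_filter(panel: CohortPanel, task: str) -> CohortPanel:
    """Exclude patients already disease-positive at baseline or first follow-up.

    A patient is excluded when the task's diagnostic rule fires at wave 1
    or wave 2 (the diabetes-like rule: fasting-glucose analog >= 126 mg/dL;
    the hypertension-like rule: SBP analog >= 140 or DBP analog >= 90 mmHg).
    Missing diagnostic entries never fire the rule.
    """
    rules = panel.metadata.get("diagnostic_rules", DEFAULT_DIAGNOSTIC_RULES)
    if task not in rules:
        raise KeyError(f"no diagnostic rule configured for task {task!r}")
    fires = np.zeros(panel.n_patients, dtype=bool)
    n_baseline_waves = min(2, panel.n_waves)
    for feature, cutoff in rules[task]:
        f = panel.feature_index(feature)
        vals = panel.values[:, :n_baseline_waves, f]
        obs = panel.observed_mask[:, :n_baseline_waves, f]
        fires |= np.any(obs & (vals >= cutoff), axis=1)
    return panel.subset_patients(np.flatnonzero(~fires))


def ar1_panel(
    n_patients: int,
    n_waves: int,
    n_features: int,
    rho: float,
    seed: int,
) -> CohortPanel:
    """Label-free panel of independent stationary AR(1) series per
    (patient, feature); the imputation benchmark input."""
    rng = np.random.default_rng(seed)
    values = np.empty((n_patients, n_waves, n_features))
    values[:, 0, :] = rng.standard_normal((n_patients, n_features))
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, n_waves):
        values[:, t, :] = rho * values[:, t - 1, :] + innov_sd * rng.standard_normal(
            (n_patients, n_features)
        )
    return CohortPanel(
        values=values,
        observed_mask=np.ones_like(values, dtype=bool),
        feature_names=[f"f{i + 1:02d}" for i in range(n_features)],
        labels={},
    )


def make_planted_selection_data(
    n: int,
    p: int,
    k: int,
    effect_size: float,
    seed: int,
    prevalence: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Cross-sectional design with `k` planted informative columns of `p`.

    Returns (X, y, informative column indices).  The linear score over the
    informative columns plus unit noise is binarized at the quantile giving
    the requested prevalence — ground truth for selection recall/precision.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    w = effect_size * rng.uniform(0.8, 1.2, size=k) * rng.choice([-1.0, 1.0], size=k)
    score = X[:, :k] @ w + rng.standard_normal(n)
    y = (score > np.quantile(score, 1.0 - prevalence)).astype(int)
    return X, y, list(range(k))
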