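"""L1-penalized feature selection for panel inputs.

Pipeline order: missingness filter (on the pre-imputation mask) →
imputation → per-task diagnostic-feature exclusion → LASSO over a penalty
grid chosen by fivefold cross-validation.  The per-wave fits at the chosen
penalty are unioned into one rectangular feature set, which
:func:`build_tensor` turns into the model-ready ``[N, T, F]`` input with
final-wave labels.

The LASSO objective is (1/2n)·‖y − Xβ‖² + α·‖β‖₁, the standard
coordinate-descent form; ``scikit-learn`` provides the solver.  The default
penalty grid spans the significant digits from 1e-3 to 100,
{n·10^k : 1 ≤ n ≤ 9, −3 ≤ k ≤ 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import KFold

from .panel import CohortPanel
from .simulate import DEFAULT_DIAGNOSTIC_RULES

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "TaskDataset",
    "default_alpha_grid",
    "missingness_filter",
    "exclude_diagnostic",
    "lasso_path",
    "select_from_matrix",
    "select_features",
    "build_tensor",
]


def default_alpha_grid(k_min: int = -3, k_max: int = 2) -> list[float]:
    """Significant-digit grid {n·10^k : 1 ≤ n ≤ 9, k_min ≤ k ≤ k_max}."""
    return sorted(float(n) * 10.0**k for k in range(k_min, k_max + 1) for n in range(1, 10))


def _default_diagnostic_features() -> dict[str, list[str]]:
    return {task: [f for f, _ in rules] for task, rules in DEFAULT_DIAGNOSTIC_RULES.items()}


@dataclass
class SelectionConfig:
    """Penalty grid, CV folds, missingness threshold and per-task
    diagnostic feature lists."""

    alpha_grid: list[float] = field(default_factory=default_alpha_grid)
    cv_folds: int = 5
    missing_threshold: float = 0.8
    diagnostic_features: dict[str, list[str]] = field(
        default_factory=_default_diagnostic_features
    )
    logistic: bool = False  # L1 logistic regression instead of L1 linear
    pooled: bool = False  # single pooled fit over waves instead of per-wave union
    alpha_rule: str = "1se"  # '1se' (sparsest within one SE of best) or 'min'
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_grid or any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alpha_grid must be nonempty with positive entries")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.missing_threshold <= 1.0:
            raise ValueError("missing_threshold must be in (0, 1]")
        if self.alpha_rule not in ("1se", "min"):
            raise ValueError("alpha_rule must be '1se' or 'min'")


@dataclass
class SelectionResult:
    task: str
    best_alpha: float
    selected_features: list[str]
    per_fold_scores: np.ndarray  # [n_alphas, n_folds], higher is better
    alpha_grid: list[float]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "best_alpha": self.best_alpha,
            "selected_features": list(self.selected_features),
            "alpha_grid": list(self.alpha_grid),
            "per_fold_scores": self.per_fold_scores.tolist(),
        }


@dataclass
class TaskDataset:
    """One task's model-ready input: values [N, T, F], binary labels [N]."""

    task: str
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 3 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be [N, T, F] matching labels")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]


def missingness_filter(panel: CohortPanel, threshold: float = 0.8) -> list[str]:
    """Features surviving the high-missingness screen.

    A feature is removed iff its missing fraction reaches ``threshold`` at
    any single wave ("80% or more in at least one time step"); survivor
    order is preserved.
    """
    missing_frac = 1.0 - panel.observed_mask.mean(axis=0)  # [T, F]
    drop = (missing_frac >= threshold).any(axis=0)
    return [name for name, d in zip(panel.feature_names, drop) if not d]


def exclude_diagnostic(
    features: list[str], task: str, config: SelectionConfig
) -> list[str]:
    """Remove the task's own diagnostic-criterion features; other tasks'
    diagnostic features stay candidates."""
    if task not in config.diagnostic_features:
        raise KeyError(f"no diagnostic feature list for task {task!r}")
    excluded = set(config.diagnostic_features[task])
    return [f for f in features if f not in excluded]


def lasso_path(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """L1-penalized linear coefficients minimizing
    (1/2n)‖y − Xβ‖² + α‖β‖₁ (no intercept; X is expected standardized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in design or response")
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if alpha == 0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    model = Lasso(alpha=alpha, fit_intercept=False, tol=1e-6, max_iter=50_000)
    model.fit(X, y)
    return model.coef_.copy()


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd


def _fit_coefs(X: np.ndarray, y: np.ndarray, alpha: float, logistic: bool) -> np.ndarray:
    if logistic:
        model = LogisticRegression(
            penalty="l1", C=1.0 / (alpha * len(y)), solver="liblinear", max_iter=2000
        )
        model.fit(X, y)
        return model.coef_.ravel().copy()
    return lasso_path(X, y, alpha)


def _cv_scores(
    X: np.ndarray, y: np.ndarray, config: SelectionConfig
) -> np.ndarray:
    """Mean CV predictive score (negated squared error) per (alpha, fold)."""
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    scores = np.empty((len(config.alpha_grid), config.cv_folds))
    folds = list(kf.split(X))
    yc = y - y.mean()
    for i, alpha in enumerate(config.alpha_grid):
        for j, (tr, te) in enumerate(folds):
            Xtr, Xte = X[tr], X[te]
            coef = _fit_coefs(Xtr, yc[tr] if not config.logistic else y[tr], alpha,
                              config.logistic)
            if config.logistic:
                pred = Xte @ coef
                scores[i, j] = -np.mean((y[te] - 1.0 / (1.0 + np.exp(-pred))) ** 2)
            else:
                scores[i, j] = -np.mean((yc[te] - Xte @ coef) ** 2)
    return scores


def _choose_alpha(scores: np.ndarray, config: SelectionConfig) -> float:
    """Pick the penalty from the CV score matrix [alphas, folds].

    ``'min'`` takes the best mean score (ties toward the larger, sparser
    penalty).  The default ``'1se'`` takes the largest penalty whose mean
    score is within one standard error of the best — the usual guard
    against the overselection of CV-minimum lasso.
    """
    mean_scores = scores.mean(axis=1)
    grid = config.alpha_grid
    best = max(range(len(grid)), key=lambda i: (mean_scores[i], grid[i]))
    if config.alpha_rule == "min":
        return grid[best]
    se = scores[best].std(ddof=1) / np.sqrt(scores.shape[1])
    threshold = mean_scores[best] - se
    eligible = [i for i in range(len(grid)) if mean_scores[i] >= threshold]
    return grid[max(eligible, key=lambda i: grid[i])]


def select_from_matrix(
    X: np.ndarray, y: np.ndarray, config: SelectionConfig, task: str = "task",
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Grid-searched LASSO selection on a single [n, p] design.

    Features with nonzero coefficients at the CV-chosen penalty (see
    :func:`_choose_alpha`) are selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("no candidate features")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    Xs = _standardize(X)
    scores = _cv_scores(Xs, y, config)
    best_alpha = _choose_alpha(scores, config)
    coef = _fit_coefs(
        Xs, y - y.mean() if not config.logistic else y, best_alpha, config.logistic
    )
    selected = [feature_names[i] for i in np.flatnonzero(np.abs(coef) > 1e-12)]
    return SelectionResult(
        task=task,
        best_alpha=best_alpha,
        selected_features=selected,
        per_fold_scores=scores,
        alpha_grid=list(config.alpha_grid),
    )


def select_features(
    panel: CohortPanel, task: str, config: SelectionConfig,
    candidates: list[str] | None = None,
) -> SelectionResult:
    """LASSO selection on an imputed panel for one task.

    The CV grid search scores each penalty averaged over waves; the final
    per-wave fits at the winning penalty are unioned into the task's
    selected feature set (one rectangular tensor needs one common set).
    With ``config.pooled`` the waves are concatenated into a single fit
    instead.
    """
    if not panel.observed_mask.all():
        raise ValueError("panel must be imputed (all entries observed) before selection")
    if candidates is None:
        candidates = exclude_diagnostic(
            missingness_filter(panel, config.missing_threshold), task, config
        )
    if len(candidates) < 1:
        raise ValueError("no candidate features")
    idx = [panel.feature_index(f) for f in candidates]
    y = panel.labels[task].astype(float)
    waves = range(panel.n_waves - 1)  # inputs exclude the label wave

    if config.pooled:
        X = np.concatenate([panel.values[:, t, :][:, idx] for t in waves], axis=0)
        yy = np.tile(y, len(list(waves)))
        return select_from_matrix(X, yy, config, task, candidates)

    per_wave_scores = []
    for t in waves:
        per_wave_scores.append(_cv_scores(_standardize(panel.values[:, t, idx]), y, config))
    scores = np.mean(per_wave_scores, axis=0)
    best_alpha = _choose_alpha(scores, config)

    def union_at(alpha: float) -> list[str]:
        out: list[str] = []
        for t in waves:
            Xs = _standardize(panel.values[:, t, idx])
            coef = _fit_coefs(
                Xs, y - y.mean() if not config.logistic else y, alpha, config.logistic
            )
            for i in np.flatnonzero(np.abs(coef) > 1e-12):
                if candidates[i] not in out:
                    out.append(candidates[i])
        return out

    selected = union_at(best_alpha)
    if not selected and config.alpha_rule == "1se":
        # the sparsity-biased rule can zero out everything on weak data;
        # fall back to the CV-best penalty before giving up
        import dataclasses as _dc

        best_alpha = _choose_alpha(scores, _dc.replace(config, alpha_rule="min"))
        selected = union_at(best_alpha)
    if not selected:
        raise ValueError(f"no features selected for task {task!r} at alpha={best_alpha}")
    return SelectionResult(
        task=task,
        best_alpha=best_alpha,
        selected_features=selected,
        per_fold_scores=scores,
        alpha_grid=list(config.alpha_grid),
    )


def build_tensor(
    panel: CohortPanel, selected: list[str], n_waves_in: int, task: str
) -> TaskDataset:
    """Stack the last ``n_waves_in`` input waves of the selected features.

    The label wave is the panel's final wave; an ``n_waves_in`` of 2 on an
    8-wave panel therefore selects waves 7 and 8 — the last four years of
    progression at biannual spacing.
    """
    if not 1 <= n_waves_in < panel.n_waves:
        raise ValueError(
            f"n_waves_in must be in [1, {panel.n_waves - 1}], got {n_waves_in}"
        )
    idx = [panel.feature_index(f) for f in selected]
    first = panel.n_waves - 1 - n_waves_in
    X = panel.values[:, first : panel.n_waves - 1, :][:, :, idx]
    return TaskDataset(
        task=task,
        X=X.copy(),
        y=panel.labels[task].copy(),
        feature_names=list(selected),
        patient_ids=panel.patient_ids.copy(),
    )
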