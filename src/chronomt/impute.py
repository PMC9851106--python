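"""Missing-value imputation for cohort panels.

The main tool is :class:`RecurrentImputer`, a bidirectional recurrent
imputer in the spirit of BRITS: a recurrent cell runs over the wave axis in
both directions and, at every wave, produces

* a *history* estimate regressed from the hidden state, and
* a *cross-feature* estimate regressed from the other features at the same
  wave (the regression matrix has a zero diagonal so a feature never
  predicts itself),

which are blended by a learned per-feature gate into the final estimate.
Training minimizes the mean absolute reconstruction error of all three
estimates on observed entries, in both directions, plus a consistency
penalty between the forward and backward estimates.  An optional auxiliary
classification head (off by default) lets the imputer co-train against a
task label, keeping the default pipeline stages decoupled.

A per-(feature, wave) mean imputer serves as the simple baseline, and
:func:`evaluate_imputation` computes MAE/MRE on held-out entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Dense, LSTMCell, Tensor, concat, sigmoid
from .panel import CohortPanel

__all__ = [
    "RecurrentImputer",
    "ImputationReport",
    "mean_impute",
    "evaluate_imputation",
]


@dataclass
class ImputationReport:
    """Held-out imputation quality: mean absolute error and mean relative
    error (sum of absolute errors over sum of absolute true values)."""

    mae: float
    mre: float
    n_evaluated: int

    def __post_init__(self) -> None:
        if self.mae < 0 or self.mre < 0 or self.n_evaluated < 1:
            raise ValueError("invalid imputation report")


def mean_impute(panel: CohortPanel) -> CohortPanel:
    """Fill missing entries with the per-(feature, wave) observed mean.

    An empty (feature, wave) cell falls back to the feature's global
    observed mean; a feature with no observed entry at all is an error.
    """
    out = panel.copy()
    values, mask = out.values, out.observed_mask
    filled = values.copy()
    for f in range(out.n_features):
        obs_f = mask[:, :, f]
        if not obs_f.any():
            raise ValueError(f"feature {out.feature_names[f]!r} has no observed entries")
        global_mean = values[:, :, f][obs_f].mean()
        for t in range(out.n_waves):
            obs = obs_f[:, t]
            cell_mean = values[obs, t, f].mean() if obs.any() else global_mean
            filled[~obs, t, f] = cell_mean
    out.values = filled
    out.observed_mask = np.ones_like(mask)
    return out


def evaluate_imputation(
    truth: CohortPanel, imputed: CohortPanel, holdout_mask: np.ndarray
) -> ImputationReport:
    """MAE and MRE over the held-out entries.

    ``truth`` must carry complete values at the held-out positions (e.g.
    the panel before missingness was applied).
    """
    holdout_mask = np.asarray(holdout_mask, dtype=bool)
    if holdout_mask.shape != truth.values.shape:
        raise ValueError("holdout mask shape does not match panel")
    n = int(holdout_mask.sum())
    if n == 0:
        raise ValueError("empty holdout: nothing to evaluate")
    t_vals = truth.values[holdout_mask]
    i_vals = imputed.values[holdout_mask]
    denom = np.abs(t_vals).sum()
    if denom == 0:
        raise ZeroDivisionError("degenerate denominator: held-out truth is all zero")
    abs_err = np.abs(t_vals - i_vals)
    return ImputationReport(
        mae=float(abs_err.mean()), mre=float(abs_err.sum() / denom), n_evaluated=n
    )


class _ImputerNet:
    """One shared parameter set evaluated in both time directions."""

    def __init__(self, n_features: int, hidden_size: int, rng: np.random.Generator):
        self.n_features = n_features
        self.cell = LSTMCell(2 * n_features, hidden_size, rng)
        self.hist = Dense(hidden_size, n_features, rng)
        self.feat = Dense(n_features, n_features, rng)
        self.gate_logit = Tensor(np.zeros(n_features), requires_grad=True)
        self._offdiag = 1.0 - np.eye(n_features)

    def parameters(self) -> list[Tensor]:
        return self.cell.parameters() + self.hist.parameters() + self.feat.parameters() + [
            self.gate_logit
        ]

    def run(self, x: np.ndarray, m: np.ndarray, reverse: bool):
        """Run one direction over the wave axis.

        ``x`` is the standardized panel with zeros at missing entries,
        ``m`` the observed mask as floats; both [N, T, F].  Returns the
        per-wave (history, cross-feature, combined) estimate triples in
        forward wave order, plus the final hidden state.
        """
        n, t_steps, _ = x.shape
        order = range(t_steps - 1, -1, -1) if reverse else range(t_steps)
        state = self.cell.init_state(n)
        gate = sigmoid(self.gate_logit)
        w_feat = self.feat.weight * self._offdiag  # no self-regression
        estimates: dict[int, tuple[Tensor, Tensor, Tensor]] = {}
        h = state[0]
        for t in order:
            x_t, m_t = Tensor(x[:, t, :]), Tensor(m[:, t, :])
            x_hist = self.hist(h)
            x_comp = m_t * x_t + (1.0 - m_t) * x_hist
            x_feat = x_comp @ w_feat + self.feat.bias
            combined = gate * x_feat + (1.0 - gate) * x_hist
            estimates[t] = (x_hist, x_feat, combined)
            u_t = m_t * x_t + (1.0 - m_t) * combined
            h, state = self.cell.step(concat([u_t, m_t], axis=-1), state)
        return [estimates[t] for t in range(t_steps)], h


class RecurrentImputer:
    """Bidirectional recurrent panel imputer (scikit-learn style).

    Parameters
    ----------
    hidden_size : int
        Recurrent state width.
    learning_rate, batch_size : float, int
        Adam step size and minibatch size (defaults 1e-3 and 64).
    epochs : int
        Maximum training epochs; early stopping watches the MAE on a 10%
        holdout of observed entries.
    consistency_weight : float
        Weight of the forward/backward agreement penalty.
    classify_task : str or None
        If set, adds an auxiliary sigmoid head co-trained on that task's
        labels (joint imputation-classification); off by default.
    seed : int
        Controls initialization, batching and the validation holdout.

    Attributes
    ----------
    feature_names_ : list of str
    mean_, scale_ : per-feature standardization statistics (observed entries)
    history_ : list of per-epoch (train loss, validation MAE)
    """

    def __init__(
        self,
        hidden_size: int = 32,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 100,
        consistency_weight: float = 0.1,
        aux_classify_weight: float = 0.3,
        classify_task: str | None = None,
        validation_fraction: float = 0.1,
        patience: int = 15,
        seed: int = 0,
    ):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if batch_size < 1 or epochs < 1 or hidden_size < 1:
            raise ValueError("hidden_size, batch_size and epochs must be >= 1")
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.consistency_weight = consistency_weight
        self.aux_classify_weight = aux_classify_weight
        self.classify_task = classify_task
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.seed = seed

    # -- sklearn-compatible parameter plumbing ------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "hidden_size", "learning_rate", "batch_size", "epochs",
                "consistency_weight", "aux_classify_weight", "classify_task",
                "validation_fraction", "patience", "seed",
            )
        }

    def set_params(self, **params) -> "RecurrentImputer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------- fit
    def fit(self, panel: CohortPanel, y=None) -> "RecurrentImputer":
        if panel.n_waves < 2:
            raise ValueError("imputer needs at least two waves")
        mask = panel.observed_mask
        for f in range(panel.n_features):
            if not mask[:, :, f].any():
                raise ValueError(
                    f"feature {panel.feature_names[f]!r} is entirely missing; "
                    "cannot be imputed"
                )
        rng = np.random.default_rng(self.seed)
        self.feature_names_ = list(panel.feature_names)

        raw = np.where(mask, panel.values, 0.0)
        self.mean_ = np.array(
            [raw[:, :, f][mask[:, :, f]].mean() for f in range(panel.n_features)]
        )
        self.scale_ = np.array(
            [
                max(raw[:, :, f][mask[:, :, f]].std(), 1e-8)
                for f in range(panel.n_features)
            ]
        )
        x = np.where(mask, (panel.values - self.mean_) / self.scale_, 0.0)

        # hide a fraction of observed entries from training for early stopping
        val_mask = mask & (rng.random(mask.shape) < self.validation_fraction)
        if not val_mask.any():
            val_mask = np.zeros_like(mask)
        train_mask = mask & ~val_mask
        x_train = np.where(train_mask, x, 0.0)
        m_train = train_mask.astype(float)

        self._net = _ImputerNet(panel.n_features, self.hidden_size, rng)
        labels = None
        if self.classify_task is not None:
            labels = panel.labels[self.classify_task].astype(float)
            self._head = Dense(2 * self.hidden_size, 1, rng)
            params = self._net.parameters() + self._head.parameters()
        else:
            params = self._net.parameters()
        opt = Adam(params, lr=self.learning_rate)

        n = panel.n_patients
        best_val = np.inf
        best_state = [p.data.copy() for p in params]
        stale = 0
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss = self._loss(
                    x_train[idx], m_train[idx],
                    None if labels is None else labels[idx],
                )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(idx)
            val_mae = self._validation_mae(x_train, m_train, x, val_mask)
            self.history_.append((epoch_loss / n, val_mae))
            if val_mae < best_val - 1e-6:
                best_val = val_mae
                best_state = [p.data.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        for p, a in zip(params, best_state):
            p.data = a
        return self

    def _loss(self, x, m, labels) -> Tensor:
        recon = Tensor(0.0)
        combined_by_dir = []
        hidden_by_dir = []
        m_sum = max(m.sum(), 1.0)
        for reverse in (False, True):
            estimates, h_last = self._net.run(x, m, reverse)
            for t, (x_hist, x_feat, comb) in enumerate(estimates):
                x_t, m_t = Tensor(x[:, t, :]), Tensor(m[:, t, :])
                for est in (x_hist, x_feat, comb):
                    recon = recon + ((x_t - est).abs() * m_t).sum()
            combined_by_dir.append(estimates)
            hidden_by_dir.append(h_last)
        total = recon * (1.0 / (6.0 * m_sum))
        cons = Tensor(0.0)
        for t in range(x.shape[1]):
            cons = cons + (
                combined_by_dir[0][t][2] - combined_by_dir[1][t][2]
            ).abs().mean()
        total = total + self.consistency_weight * (1.0 / x.shape[1]) * cons
        if labels is not None:
            logit = self._head(concat(hidden_by_dir, axis=-1)).reshape(-1)
            p = sigmoid(logit)
            y = Tensor(labels)
            eps = 1e-7
            bce = -(y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log()).mean()
            total = total + self.aux_classify_weight * bce
        return total

    def _validation_mae(self, x_train, m_train, x_full, val_mask) -> float:
        if not val_mask.any():
            return float(self.history_[-1][0]) if self.history_ else 0.0
        est = self._estimate(x_train, m_train)
        return float(np.abs(est[val_mask] - x_full[val_mask]).mean())

    def _estimate(self, x, m) -> np.ndarray:
        """Combined bidirectional estimate in standardized space."""
        fwd, _ = self._net.run(x, m, reverse=False)
        bwd, _ = self._net.run(x, m, reverse=True)
        t_steps = x.shape[1]
        out = np.empty_like(x)
        for t in range(t_steps):
            out[:, t, :] = 0.5 * (fwd[t][2].data + bwd[t][2].data)
        return out

    # ------------------------------------------------------------- transform
    def transform(self, panel: CohortPanel) -> CohortPanel:
        if not hasattr(self, "mean_"):
            raise RuntimeError("imputer is not fitted")
        if list(panel.feature_names) != self.feature_names_:
            raise ValueError("feature set differs from the panel the imputer was fit on")
        mask = panel.observed_mask
        x = np.where(mask, (panel.values - self.mean_) / self.scale_, 0.0)
        est = self._estimate(x, mask.astype(float))
        filled = est * self.scale_ + self.mean_
        out = panel.copy()
        out.values = np.where(mask, panel.values, filled)
        if not np.isfinite(out.values).all():
            raise FloatingPointError("imputer produced non-finite values")
        out.observed_mask = np.ones_like(mask)
        return out

    def fit_transform(self, panel: CohortPanel, y=None) -> CohortPanel:
        return self.fit(panel).transform(panel)
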