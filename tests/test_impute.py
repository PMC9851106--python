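"""Imputation: mean baseline arithmetic, MAE/MRE formulas, recurrent
imputer pass-through, determinism and quality."""

import numpy as np
import pytest

from chronomt import (
    CohortPanel,
    RecurrentImputer,
    apply_missingness,
    ar1_panel,
    evaluate_imputation,
    mean_impute,
)


def panel_from(values, mask):
    values = np.asarray(values, dtype=float)
    return CohortPanel(
        values=np.where(mask, values, np.nan),
        observed_mask=np.asarray(mask, dtype=bool),
        feature_names=[f"f{i}" for i in range(values.shape[2])],
        labels={},
    )


class TestMeanImpute:
    def test_cell_mean(self):
        values = np.array([[[2.0]], [[4.0]], [[0.0]]])
        mask = np.array([[[True]], [[True]], [[False]]])
        out = mean_impute(panel_from(values, mask))
        assert out.values[2, 0, 0] == 3.0
        assert out.observed_mask.all()

    def test_no_missing_is_identity(self, small_panel):
        out = mean_impute(small_panel)
        assert np.array_equal(out.values, small_panel.values)

    def test_empty_cell_falls_back_to_global_mean(self):
        values = np.array([[[7.0], [0.0]], [[7.0], [0.0]]])  # wave 2 all missing
        mask = np.array([[[True], [False]], [[True], [False]]])
        out = mean_impute(panel_from(values, mask))
        assert np.allclose(out.values[:, 1, 0], 7.0)

    def test_fully_missing_feature_errors(self):
        values = np.zeros((2, 2, 1))
        mask = np.zeros((2, 2, 1), dtype=bool)
        with pytest.raises(ValueError, match="no observed"):
            mean_impute(panel_from(values, mask))


class TestEvaluateImputation:
    def test_perfect_imputation(self):
        v = np.arange(6.0).reshape(1, 2, 3) + 1
        truth = panel_from(v, np.ones_like(v, dtype=bool))
        rep = evaluate_imputation(truth, truth, np.ones_like(v, dtype=bool))
        assert rep.mae == 0 and rep.mre == 0

    def test_stated_formulas(self):
        truth = panel_from(np.array([[[2.0, 4.0]]]), np.ones((1, 1, 2), bool))
        imp = panel_from(np.array([[[3.0, 3.0]]]), np.ones((1, 1, 2), bool))
        rep = evaluate_imputation(truth, imp, np.ones((1, 1, 2), bool))
        assert rep.mae == pytest.approx(1.0)
        assert rep.mre == pytest.approx(2.0 / 6.0)
        assert rep.n_evaluated == 2

    def test_brute_force_agreement(self, rng):
        shape = (5, 4, 3)
        truth = panel_from(rng.standard_normal(shape), np.ones(shape, bool))
        imp = panel_from(rng.standard_normal(shape), np.ones(shape, bool))
        hold = rng.random(shape) < 0.4
        rep = evaluate_imputation(truth, imp, hold)
        diffs = [
            abs(truth.values[i, t, f] - imp.values[i, t, f])
            for i in range(5) for t in range(4) for f in range(3)
            if hold[i, t, f]
        ]
        denom = sum(
            abs(truth.values[i, t, f])
            for i in range(5) for t in range(4) for f in range(3)
            if hold[i, t, f]
        )
        assert rep.mae == pytest.approx(np.mean(diffs))
        assert rep.mre == pytest.approx(np.sum(diffs) / denom)

    def test_empty_holdout_errors(self, small_panel):
        with pytest.raises(ValueError, match="empty holdout"):
            evaluate_imputation(
                small_panel, small_panel, np.zeros_like(small_panel.observed_mask)
            )

    def test_zero_truth_denominator(self):
        z = np.zeros((1, 2, 1))
        truth = panel_from(z, np.ones_like(z, dtype=bool))
        with pytest.raises(ZeroDivisionError):
            evaluate_imputation(truth, truth, np.ones_like(z, dtype=bool))


class TestRecurrentImputer:
    def test_observed_entries_pass_through_bitwise(self):
        panel = ar1_panel(40, 6, 4, rho=0.7, seed=0)
        masked = apply_missingness(panel, 0.25, "MCAR", seed=1)
        out = RecurrentImputer(epochs=3, seed=0).fit_transform(masked)
        obs = masked.observed_mask
        assert np.array_equal(out.values[obs], masked.values[obs])
        assert out.observed_mask.all()
        assert np.isfinite(out.values).all()

    def test_complete_panel_transform_is_identity(self):
        panel = ar1_panel(30, 5, 3, rho=0.5, seed=2)
        out = RecurrentImputer(epochs=2, seed=0).fit_transform(panel)
        assert np.array_equal(out.values, panel.values)

    def test_deterministic_given_seed(self):
        panel = ar1_panel(40, 6, 3, rho=0.7, seed=3)
        masked = apply_missingness(panel, 0.2, "MCAR", seed=4)
        a = RecurrentImputer(epochs=5, seed=9).fit_transform(masked)
        b = RecurrentImputer(epochs=5, seed=9).fit_transform(masked)
        assert np.array_equal(a.values, b.values)

    def test_constant_series_gap_recovered(self):
        values = np.full((30, 6, 2), 5.0)
        mask = np.ones_like(values, dtype=bool)
        mask[:, 3, 0] = False  # interior gap in feature 0
        panel = CohortPanel(
            values=np.where(mask, values, np.nan),
            observed_mask=mask,
            feature_names=["a", "b"],
            labels={},
        )
        out = RecurrentImputer(epochs=30, seed=0).fit_transform(panel)
        assert np.allclose(out.values[:, 3, 0], 5.0, rtol=0.05)

    def test_entirely_missing_feature_named_in_error(self):
        values = np.random.default_rng(0).standard_normal((10, 4, 2))
        mask = np.ones_like(values, dtype=bool)
        mask[:, :, 1] = False
        panel = CohortPanel(
            values=np.where(mask, values, np.nan),
            observed_mask=mask, feature_names=["ok", "gone"], labels={},
        )
        with pytest.raises(ValueError, match="gone"):
            RecurrentImputer(epochs=1, seed=0).fit(panel)

    def test_feature_set_mismatch_rejected(self):
        panel = ar1_panel(20, 4, 3, rho=0.5, seed=5)
        other = ar1_panel(20, 4, 2, rho=0.5, seed=5)
        imp = RecurrentImputer(epochs=1, seed=0).fit(panel)
        with pytest.raises(ValueError, match="feature set"):
            imp.transform(other)

    def test_beats_mean_imputation_on_autocorrelated_panel(self):
        """Temporal structure should let the recurrent imputer dominate the
        per-(feature, wave) mean on an AR(1) panel (single-seed check; the
        multi-seed version runs in the acceptance suite)."""
        panel = ar1_panel(150, 8, 6, rho=0.8, seed=0)
        masked = apply_missingness(panel, 0.2, "MCAR", seed=100)
        hold = masked.metadata["holdout_mask"]
        rec = RecurrentImputer(epochs=40, seed=0).fit_transform(masked)
        rec_mae = evaluate_imputation(panel, rec, hold).mae
        mean_mae = evaluate_imputation(panel, mean_impute(masked), hold).mae
        assert rec_mae < mean_mae
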