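"""Feature selection: missingness screen, diagnostic exclusion, lasso
solver oracles, CV selection and tensor assembly."""

import numpy as np
import pytest

from chronomt import (
    SelectionConfig,
    apply_missingness,
    build_tensor,
    exclude_diagnostic,
    generate_panel,
    lasso_path,
    make_planted_selection_data,
    missingness_filter,
    select_features,
    select_from_matrix,
    SyntheticSpec,
)


def orthonormal_design(n, p, seed=0):
    """Columns with X'X = n*I so the lasso solution is the soft threshold."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    return q * np.sqrt(n)


class TestMissingnessFilter:
    def test_exactly_80_percent_at_one_wave_removed(self, small_panel):
        panel = small_panel.copy()
        f = 4
        n = panel.n_patients
        k = int(round(0.8 * n))
        panel.observed_mask[:k, 2, f] = False
        survivors = missingness_filter(panel, 0.8)
        assert panel.feature_names[f] not in survivors

    def test_79_percent_everywhere_retained(self, small_panel):
        panel = small_panel.copy()
        f = 3
        n = panel.n_patients
        k = int(np.floor(0.79 * n))
        panel.observed_mask[:k, :, f] = False
        assert panel.feature_names[f] in missingness_filter(panel, 0.8)

    def test_fully_observed_retains_all_and_order(self, small_panel):
        assert missingness_filter(small_panel, 0.8) == small_panel.feature_names

    def test_idempotent(self, small_panel):
        panel = apply_missingness(small_panel, 0.3, "MCAR", seed=0)
        once = missingness_filter(panel, 0.5)
        again = missingness_filter(panel.subset_features(once), 0.5)
        assert once == again


class TestExcludeDiagnostic:
    def test_own_diagnostics_removed_other_retained(self):
        config = SelectionConfig()
        feats = ["glucose_analog", "sbp_analog", "dbp_analog", "bmi"]
        dm = exclude_diagnostic(feats, "diabetes", config)
        assert "glucose_analog" not in dm
        assert "sbp_analog" in dm and "dbp_analog" in dm
        htn = exclude_diagnostic(feats, "hypertension", config)
        assert htn == ["glucose_analog", "bmi"]

    def test_empty_list_is_identity(self):
        config = SelectionConfig(diagnostic_features={"t": []})
        assert exclude_diagnostic(["a", "b"], "t", config) == ["a", "b"]

    def test_unknown_task(self):
        with pytest.raises(KeyError):
            exclude_diagnostic(["a"], "gout", SelectionConfig())


class TestLassoPath:
    def test_matches_soft_threshold_on_orthonormal_design(self):
        n, p = 200, 6
        X = orthonormal_design(n, p, seed=1)
        rng = np.random.default_rng(2)
        y = X @ rng.uniform(-1, 1, p) + 0.1 * rng.standard_normal(n)
        b_ols = X.T @ y / n
        for alpha in (0.01, 0.1, 0.3):
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - alpha, 0.0)
            assert np.allclose(lasso_path(X, y, alpha), expected, atol=1e-6)

    def test_alpha_zero_matches_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(lasso_path(X, y, 0.0), ols, atol=1e-5)

    def test_large_alpha_shrinks_all_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        alpha = np.abs(X.T @ y).max() / len(y) * 1.01
        assert np.allclose(lasso_path(X, y, alpha), 0.0)

    def test_sparsity_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 20))
        y = X[:, :4] @ np.ones(4) + rng.standard_normal(100)
        counts = [
            np.sum(np.abs(lasso_path(X, y, a)) > 1e-12)
            for a in (0.001, 0.01, 0.05, 0.2, 1.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            lasso_path(X, np.array([1.0, 0.0]), 0.1)


class TestSelection:
    def test_planted_recovery_single_seed(self):
        X, y, truth = make_planted_selection_data(500, 50, 10, 0.8, seed=1)
        res = select_from_matrix(X, y, SelectionConfig(seed=1))
        selected = {int(s[1:]) for s in res.selected_features}
        tp = len(selected & set(truth))
        assert tp / 10 >= 0.9
        assert tp / len(selected) >= 0.6
        assert res.best_alpha in res.alpha_grid

    def test_null_response_selects_few(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 40))
            y = rng.integers(0, 2, 300)
            try:
                res = select_from_matrix(X, y, SelectionConfig(seed=seed))
                n_sel = len(res.selected_features)
            except ValueError:
                n_sel = 0
            hits += n_sel <= 0.05 * 40
        assert hits >= 4

    def test_duplicated_informative_column_survives(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(400)
        X = np.column_stack([base + 0.01 * rng.standard_normal(400) for _ in range(6)])
        y = (base > 0).astype(int)
        res = select_from_matrix(X, y, SelectionConfig(seed=0))
        assert len(res.selected_features) >= 1

    def test_panel_selection_finds_informative_features(self):
        panel = generate_panel(
            SyntheticSpec(n_patients=600, n_features=24, n_shared_informative=6,
                          n_task_specific=2, seed=3)
        )
        config = SelectionConfig(seed=3)
        res = select_features(panel, "diabetes", config)
        informative = set(
            panel.metadata["informative_features"]["shared"]
            + panel.metadata["informative_features"]["diabetes"]
        ) - {"glucose_analog"}
        hit = len(set(res.selected_features) & informative) / len(informative)
        assert hit >= 0.5
        assert "glucose_analog" not in res.selected_features
        # the other task's diagnostics remain legal candidates
        assert res.per_fold_scores.shape == (len(config.alpha_grid), config.cv_folds)

    def test_requires_imputed_panel(self, small_panel):
        masked = apply_missingness(small_panel, 0.2, "MCAR", seed=0)
        with pytest.raises(ValueError, match="imputed"):
            select_features(masked, "diabetes", SelectionConfig())


class TestBuildTensor:
    def test_shape_contract(self, small_panel):
        feats = small_panel.feature_names[:10]
        ds = build_tensor(small_panel, feats, 7, "diabetes")
        assert ds.X.shape == (small_panel.n_patients, 7, 10)
        assert len(ds.y) == small_panel.n_patients

    def test_two_waves_selects_last_two_input_waves(self, small_panel):
        ds = build_tensor(small_panel, small_panel.feature_names, 2, "diabetes")
        # 8 waves: label wave is 8; inputs are waves 6 and 7 (0-based 5, 6)
        assert np.array_equal(ds.X, small_panel.values[:, 5:7, :])

    def test_all_features_full_input_equals_panel(self, small_panel):
        ds = build_tensor(small_panel, small_panel.feature_names, 7, "hypertension")
        assert np.array_equal(ds.X, small_panel.values[:, :7, :])
        assert np.array_equal(ds.y, small_panel.labels["hypertension"])

    def test_unknown_feature_rejected(self, small_panel):
        with pytest.raises(KeyError):
            build_tensor(small_panel, ["nope"], 3, "diabetes")

    def test_too_many_waves_rejected(self, small_panel):
        with pytest.raises(ValueError):
            build_tensor(small_panel, small_panel.feature_names, 8, "diabetes")
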