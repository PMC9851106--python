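"""Synthetic cohort generator: calibration, determinism, missingness and
eligibility behavior."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import cross_val_score

from chronomt import (
    SyntheticSpec,
    apply_missingness,
    eligibility_filter,
    generate_panel,
)


def spec(n=2000, **kw):
    kw.setdefault("seed", 7)
    return SyntheticSpec(n_patients=n, **kw)


def test_prevalence_hits_targets_within_one_point():
    panel = generate_panel(spec(n=5000, seed=1))
    assert abs(panel.labels["diabetes"].mean() - 0.1643) < 0.01
    assert abs(panel.labels["hypertension"].mean() - 0.3261) < 0.01


def test_prevalence_calibration_across_seeds():
    errs = {"diabetes": [], "hypertension": []}
    for seed in range(20):
        panel = generate_panel(spec(n=5000, seed=seed))
        errs["diabetes"].append(abs(panel.labels["diabetes"].mean() - 0.1643))
        errs["hypertension"].append(abs(panel.labels["hypertension"].mean() - 0.3261))
    assert np.mean(errs["diabetes"]) < 0.005
    assert np.mean(errs["hypertension"]) < 0.005


def test_same_seed_bitwise_identical():
    a = generate_panel(spec())
    b = generate_panel(spec())
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(a.labels["diabetes"], b.labels["diabetes"])


def test_zero_effect_size_gives_chance_auc():
    panel = generate_panel(spec(n=1500, effect_size=0.0))
    X = panel.values.reshape(panel.n_patients, -1)
    auc = cross_val_score(
        LogisticRegression(max_iter=500), X, panel.labels["diabetes"],
        cv=3, scoring="roc_auc",
    ).mean()
    assert abs(auc - 0.5) < 0.06


def test_signal_monotone_in_effect_size():
    """A logistic probe's AUC on informative features grows with effect size."""
    aucs = []
    for effect in (0.0, 0.5, 1.5):
        per_seed = []
        for seed in range(5):
            panel = generate_panel(spec(n=800, effect_size=effect, seed=seed))
            names = panel.metadata["informative_features"]
            feats = names["shared"] + names["diabetes"]
            idx = [panel.feature_index(f) for f in feats]
            X = panel.values[:, :, idx].reshape(panel.n_patients, -1)
            per_seed.append(
                cross_val_score(
                    LogisticRegression(max_iter=500), X, panel.labels["diabetes"],
                    cv=3, scoring="roc_auc",
                ).mean()
            )
        aucs.append(np.mean(per_seed))
    assert aucs[0] < aucs[1] < aucs[2]


def test_task_labels_positively_correlated():
    panel = generate_panel(spec(n=4000))
    a, b = panel.labels["diabetes"], panel.labels["hypertension"]
    phi = np.corrcoef(a, b)[0, 1]
    assert phi > 0.1


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(n_patients=100, n_features=10, n_shared_informative=20)
    with pytest.raises(ValueError):
        SyntheticSpec(n_patients=100, target_prevalence={"diabetes": 1.2,
                                                         "hypertension": 0.3})
    with pytest.raises(ValueError):
        SyntheticSpec(n_patients=0)


class TestMissingness:
    def test_rate_zero_is_identity(self, small_panel):
        out = apply_missingness(small_panel, 0.0, "MCAR", seed=1)
        assert np.array_equal(out.observed_mask, small_panel.observed_mask)

    def test_mcar_marginal_rate(self):
        panel = generate_panel(spec(n=2300, n_features=56))  # > 1e6 entries
        out = apply_missingness(panel, 0.2, "MCAR", seed=5)
        cleared = 1.0 - out.observed_mask.mean()
        assert abs(cleared - 0.2) < 0.002

    def test_monotone_dropout_structure(self, small_panel):
        out = apply_missingness(small_panel, 0.3, "monotone_dropout", seed=2)
        mask = out.observed_mask
        # once a patient's whole wave is missing, later waves stay missing
        wave_all_missing = ~mask.any(axis=2)
        for t in range(out.n_waves - 1):
            assert not (wave_all_missing[:, t] & mask[:, t + 1, :].any(axis=1)).any()

    def test_truth_retained_and_values_hidden(self, small_panel):
        out = apply_missingness(small_panel, 0.2, "MCAR", seed=3)
        hold = out.metadata["holdout_mask"]
        assert hold.sum() > 0
        assert np.isnan(out.values[hold]).all()
        assert np.array_equal(out.metadata["truth_values"], small_panel.values)

    def test_invalid_rate(self, small_panel):
        with pytest.raises(ValueError):
            apply_missingness(small_panel, 1.0, "MCAR", seed=1)


class TestEligibility:
    def test_sbp_150_at_baseline_excluded(self, small_panel):
        panel = small_panel.copy()
        f = panel.feature_index("sbp_analog")
        panel.values[0, 0, f] = 150.0
        out = eligibility_filter(panel, "hypertension")
        assert panel.patient_ids[0] not in out.patient_ids

    def test_glucose_126_exact_at_wave2_excluded(self, small_panel):
        panel = small_panel.copy()
        f = panel.feature_index("glucose_analog")
        panel.values[:, :2, f] = 100.0  # clear baseline positives
        panel.values[3, 1, f] = 126.0  # boundary: rule is >=
        out = eligibility_filter(panel, "diabetes")
        assert panel.patient_ids[3] not in out.patient_ids
        assert out.n_patients == panel.n_patients - 1

    def test_no_rule_fires_retains_all(self, small_panel):
        panel = small_panel.copy()
        for f in ("glucose_analog", "sbp_analog", "dbp_analog"):
            panel.values[:, :, panel.feature_index(f)] = 50.0
        for task in ("diabetes", "hypertension"):
            assert eligibility_filter(panel, task).n_patients == panel.n_patients

    def test_rule_ignores_later_waves(self, small_panel):
        panel = small_panel.copy()
        f = panel.feature_index("glucose_analog")
        panel.values[:, :2, f] = 100.0
        panel.values[5, 4, f] = 300.0  # diseased later, still eligible
        out = eligibility_filter(panel, "diabetes")
        assert panel.patient_ids[5] in out.patient_ids

    def test_unknown_task_rejected(self, small_panel):
        with pytest.raises(KeyError):
            eligibility_filter(small_panel, "gout")

    def test_cohorts_overlap_but_differ(self):
        panel = generate_panel(spec(n=3000))
        a = set(eligibility_filter(panel, "diabetes").patient_ids.tolist())
        b = set(eligibility_filter(panel, "hypertension").patient_ids.tolist())
        assert a != b and len(a & b) > 0
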