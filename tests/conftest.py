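import numpy as np
import pytest

from chronomt import CohortPanel, SyntheticSpec, generate_panel


@pytest.fixture(scope="session")
def small_panel() -> CohortPanel:
    """Fully observed 300-patient, 8-wave panel with both task labels."""
    return generate_panel(SyntheticSpec(n_patients=300, n_features=20,
                                        n_shared_informative=6, n_task_specific=2,
                                        seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def tiny_datasets(n_a=120, n_b=80, n_waves=4, n_features=5, seed=0):
    """Two tiny correlated task datasets for fast trainer tests."""
    from chronomt import TaskDataset

    rng = np.random.default_rng(seed)
    out = {}
    for task, n in (("diabetes", n_a), ("hypertension", n_b)):
        X = rng.standard_normal((n, n_waves, n_features))
        w = np.zeros(n_features)
        w[0] = 1.5
        y = ((X[:, -1, :] @ w + 0.5 * rng.standard_normal(n)) > 0.3).astype(int)
        out[task] = TaskDataset(task, X, y, [f"x{i}" for i in range(n_features)],
                                np.arange(n))
    return out
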