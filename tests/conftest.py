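import numpy as np
import pandas as pd
import pytest

import wmconn as w


@pytest.fixture(scope="session")
def conn_registry():
    return w.build_registry("connectivity-16")


@pytest.fixture(scope="session")
def act_registry():
    return w.build_registry("activation-86")


def toy_registry(n_rois: int = 8, n_subrois: int = 4) -> "w.ROIRegistry":
    """Small custom registry for fast statistical simulations."""
    table = pd.DataFrame(
        {
            "name": [f"R{i:02d}" for i in range(n_rois)],
            "area": [f"A{i:02d}" for i in range(n_rois)],
            "hemisphere": ["left", "right"] * (n_rois // 2) + ["left"] * (n_rois % 2),
            "n_subrois": [n_subrois] * n_rois,
        }
    )
    return w.registry_from_frame(table, mode="custom")


@pytest.fixture(scope="session")
def toy_reg():
    return toy_registry()


@pytest.fixture(scope="session")
def schedule():
    return w.generate_trial_schedule(seed=123)


@pytest.fixture(scope="session")
def toy_session(toy_reg, schedule):
    """One signal-free toy subject (32 subROIs), shared across tests."""
    truth = w.GroundTruth()
    return w.simulate_session(toy_reg, schedule, w.AcqConfig(), truth, seed=7)


def separable_features(n_runs=4, n_classes=6, noise=0.01, seed=0):
    """Class-coded orthogonal feature vectors plus tiny noise: decodable at 1.0."""
    rng = np.random.default_rng(seed)
    rows, labels, runs = [], [], []
    for r in range(n_runs):
        for c in range(n_classes):
            v = np.zeros(n_classes)
            v[c] = 1.0
            rows.append(v + noise * rng.normal(size=n_classes))
            labels.append(c)
            runs.append(r)
    return np.asarray(rows), np.asarray(labels), np.asarray(runs)
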