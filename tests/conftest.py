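import numpy as np
import pytest

from fsvmd.containers import Recording, TrialSet


@pytest.fixture(scope="session")
def fs() -> float:
    return 100.0


@pytest.fixture()
def two_tone(fs):
    """Noise-free 2 Hz + 24 Hz mixture, 10 s."""
    t = np.arange(1000) / fs
    x = np.cos(2 * np.pi * 2 * t) + np.cos(2 * np.pi * 24 * t)
    return x, t


@pytest.fixture()
def small_recording(fs):
    rng = np.random.default_rng(7)
    data = rng.standard_normal((350, 4))
    return Recording(data, fs, ["C3", "Cz", "C4", "Pz"])


@pytest.fixture()
def tiny_trials(fs):
    rng = np.random.default_rng(3)
    data = rng.standard_normal((6, 3, 350))
    labels = np.array(["RH", "RF"] * 3)
    return TrialSet(data, labels, fs, ["C3", "Cz", "C4"])


@pytest.fixture()
def gaussian_table():
    """Two-class table: feature 0 separates (d'=2), features 1-4 are noise."""
    from fsvmd.containers import FeatureTable

    rng = np.random.default_rng(11)
    n = 100
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 5))
    X[:, 0] += np.where(y == 0, -1.0, 1.0)
    return FeatureTable(X, [f"f{i}" for i in range(5)], y)
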