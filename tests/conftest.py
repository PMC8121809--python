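import numpy as np
import pytest

from cyclefit.dataset import SpectralDataset
from cyclefit.kinetics import KineticScheme
from cyclefit.synthetic import default_gtacr1_model, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    """5 channels x 8 times, smooth deterministic values."""
    axis = np.array([1100.0, 1200.0, 1300.0, 1400.0, 1500.0])
    times = np.geomspace(1e-6, 1.0, 8)
    values = np.outer(np.linspace(-1, 1, 5), np.exp(-times / 0.01)) + 0.05
    return SpectralDataset(axis=axis, times=times, values=values)


@pytest.fixture
def decay_chain():
    """Irreversible chain A -> B -> ground with well-separated rates."""
    return KineticScheme(
        states=("ground", "A", "B"),
        rates=(("A", "B", 100.0), ("B", "ground", 3.0)),
        initial={"A": 1.0},
    )


@pytest.fixture(scope="session")
def gtacr1_model():
    return default_gtacr1_model()


@pytest.fixture(scope="session")
def gtacr1_noiseless_small():
    """Noiseless default-model dataset on a coarser grid (fast tests)."""
    model = default_gtacr1_model()
    axis = np.arange(1100.0, 1801.0, 4.0)
    times = np.geomspace(1e-7, 20.0, 80)
    return simulate_dataset(model, axis=axis, times=times)
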