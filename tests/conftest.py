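import numpy as np
import pytest

from curegee import ClusteredDataset, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_dataset():
    """Six subjects in two clusters, mixed censoring, by hand."""
    return ClusteredDataset(
        cluster_id=np.array(["A", "A", "A", "B", "B", "B"]),
        time=np.array([1.2, 0.8, 3.5, 2.0, 0.5, 4.1]),
        event=np.array([1, 0, 1, 1, 0, 0]),
        Z=np.array([[1.0], [0.0], [1.0], [0.0], [1.0], [0.0]]),
        X=np.array([[0.5], [-0.2], [0.1], [0.9], [-0.5], [0.3]]),
        z_names=["z1"],
        x_names=["x1"],
    )


@pytest.fixture(scope="session")
def medium_dataset():
    """One simulated dataset at the study's default conditions."""
    return simulate_dataset(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def independent_dataset():
    """Simulated data with no within-cluster association."""
    return simulate_dataset(SimConfig(zeta=0.0, tau=0.0, K=200), seed=7)
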