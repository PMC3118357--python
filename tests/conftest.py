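import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wdcm

settings.register_profile(
    "wdcm",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("wdcm")


@pytest.fixture(scope="session")
def four_blob_sim() -> wdcm.SimulatedData:
    """Reference condition: 4 well-separated parameter blobs, 75 genes each,
    50 samples, no contamination or missingness."""
    return wdcm.simulate_matrix(wdcm.SimConfig(seed=1))


@pytest.fixture(scope="session")
def four_blob_screen(four_blob_sim) -> wdcm.ScreenResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return wdcm.screen_genes(four_blob_sim.matrix)


@pytest.fixture(scope="session")
def four_blob_partition(four_blob_screen) -> wdcm.Partition:
    return wdcm.hub_cluster(four_blob_screen.params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_partition(
    rng: np.random.Generator, n_genes: int, max_k: int
) -> wdcm.Partition:
    genes = [f"g{i}" for i in range(n_genes)]
    labels = rng.integers(0, max_k, size=n_genes)
    return wdcm.Partition.from_labels(genes, labels.tolist())
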