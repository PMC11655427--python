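import numpy as np
import pytest

from npqunmix import decompose, generate_dataset

GRID = np.arange(10.0, 601.0, 10.0)


@pytest.fixture(scope="session")
def wt_preset():
    """The wild-type study design: 85 curves, 17 intensity levels, seed 1."""
    return generate_dataset(seed=1, genotype="wt")


@pytest.fixture(scope="session")
def npq1_preset():
    return generate_dataset(seed=1, genotype="npq1")


@pytest.fixture(scope="session")
def wt_result(wt_preset):
    dataset, _ = wt_preset
    return decompose(dataset)


@pytest.fixture(scope="session")
def npq1_result(npq1_preset):
    dataset, _ = npq1_preset
    return decompose(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
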