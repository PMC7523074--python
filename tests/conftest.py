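import numpy as np
import pytest
from hypothesis import settings

from prepromine.pipeline import scan_records
from prepromine.synthetic_data import generate_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """The benchmark condition: 20 planted precursors among 200 decoys,
    no substitution noise."""
    records, manifest = generate_dataset(20, 200, seed=1)
    return records, manifest


@pytest.fixture(scope="session")
def zero_noise_scan(zero_noise_dataset):
    records, _ = zero_noise_dataset
    return scan_records(records)


@pytest.fixture(scope="session")
def small_dataset():
    records, manifest = generate_dataset(5, 10, seed=7)
    return records, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
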