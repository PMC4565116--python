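import numpy as np
import pytest

import splicessl as ssl


@pytest.fixture(scope="session")
def sim_records():
    """A degree-5 synthetic dataset: 300 positives + 1500 decoys."""
    return ssl.simulate_records(
        ssl.SimulationConfig(n_pos=300, degree=5, signal=0.6, seed=11))


@pytest.fixture(scope="session")
def sim_data(sim_records):
    return ssl.encode_dataset(sim_records)


@pytest.fixture(scope="session")
def sim_split(sim_data):
    """5 labeled positives + 25 labeled negatives; the rest unlabeled."""
    labels = sim_data.labels
    pos = np.flatnonzero(labels == ssl.POSITIVE)
    neg = np.flatnonzero(labels == ssl.NEGATIVE)
    labeled = np.concatenate([pos[:5], neg[:25]])
    unlabeled = np.setdiff1d(np.arange(len(sim_data)), labeled)
    return ssl.SplitDataset(sim_data, labeled, unlabeled)


@pytest.fixture
def tiny_spec():
    return ssl.ViewSpec(window_length=5, dimer_start=2)
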