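import numpy as np
import pytest

from painbci import pipeline, synthetic


@pytest.fixture(scope="session")
def healthy_schedule():
    return synthetic.make_event_schedule(synthetic.ProtocolSpec(), seed=0)


@pytest.fixture(scope="session")
def healthy_eeg(healthy_schedule):
    return synthetic.synth_eeg(healthy_schedule, seed=0)


@pytest.fixture(scope="session")
def healthy_sc(healthy_schedule):
    return synthetic.synth_sc(healthy_schedule, seed=1)


@pytest.fixture(scope="session")
def eeg_table(healthy_eeg, healthy_schedule):
    return pipeline.eeg_feature_table(healthy_eeg, healthy_schedule)


@pytest.fixture(scope="session")
def sc_table(healthy_sc, healthy_schedule):
    return pipeline.sc_feature_table(healthy_sc, healthy_schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
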