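import numpy as np
import pytest

import fallseg as fs
from fallseg.nn import TrainConfig


@pytest.fixture(scope="session")
def quiet_subject():
    """A low-noise synthetic subject: 20 trials, reproducible."""
    params = fs.SubjectParams(seed=7, noise_sd=0.1)
    return fs.generate_subject(params)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small network + few epochs, for structural pipeline tests."""
    return fs.ExperimentConfig(
        train=TrainConfig(hidden_units=5, max_epochs=10, patience=5),
        ica_restarts=2,
        master_seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
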