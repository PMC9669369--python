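import numpy as np
import pytest

from myodyn import SynthConfig, make_dataset, process_recording
from myodyn.synth import generate_trajectory


@pytest.fixture(scope="session")
def small_cfg():
    """Short recording for fast unit tests (8 s keeps every stage sub-second)."""
    return SynthConfig(duration=8.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return make_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_envelope(small_dataset):
    raw, _ = small_dataset
    return process_recording(raw)


@pytest.fixture(scope="session")
def small_trajectory(small_cfg):
    return generate_trajectory(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
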