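import numpy as np
import pytest

from seizelect.data_io import EEGRecord
from seizelect.montage import DEFAULT_SCHEME, N_CHANNELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(samples: np.ndarray, fs: float = 256.0,
                record_id: str = "test_01") -> EEGRecord:
    return EEGRecord("test", record_id, fs, samples, DEFAULT_SCHEME)


@pytest.fixture
def noise_record(rng) -> EEGRecord:
    """10 s of 21-channel white noise at 256 Hz, microvolt scale."""
    return make_record(rng.normal(0.0, 20.0, size=(N_CHANNELS, 2560)))


@pytest.fixture(scope="session")
def synthetic_patient():
    """One default synthetic patient, shared across tests (read-only)."""
    from seizelect.synthetic import SyntheticConfig, generate_patient

    return generate_patient(SyntheticConfig(seed=7))
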