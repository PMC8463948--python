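import numpy as np
import pytest

from asyncecg import SynthConfig, generate_dataset
from asyncecg.nn import AsyncEcgClassifier, tiny_config


@pytest.fixture(scope="session")
def clean_records():
    """Noise-free synthetic records: limb-lead identities hold exactly."""
    cfg = SynthConfig(n_records=12, prevalence=0.5, noise_sd=0.0, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_records():
    cfg = SynthConfig(n_records=20, prevalence=0.3, noise_sd=0.05, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def tiny_model():
    return AsyncEcgClassifier(tiny_config(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
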