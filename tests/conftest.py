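import numpy as np
import pytest

import fasd_eeg as fe


@pytest.fixture(scope="session")
def tiny_config() -> fe.SimConfig:
    """A desk-scale cohort: 6+6 subjects, 10 s each."""
    return fe.SimConfig(n_control=6, n_fasd=6, duration_s=10.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config) -> list[fe.Recording]:
    return fe.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort) -> fe.FeatureMatrix:
    return fe.extract_features(tiny_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
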