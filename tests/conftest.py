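import numpy as np
import pytest

from eegfocus import SynthConfig, extract_feature_matrix, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12 records per class, 2 s at 512 Hz — enough for CV at 3 folds."""
    return generate_dataset(SynthConfig(n_per_class=12, duration=2.0, seed=7))


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """Entropy features of the small dataset at Q = r = 3, J = 8."""
    return extract_feature_matrix(small_dataset, Q=3, r=3, J=8)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
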