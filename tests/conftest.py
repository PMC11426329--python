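import numpy as np
import pytest

from motifprofiler import AlignConfig, load_matrices, sample_family
from motifprofiler.synth import KINK_TURN_LIKE


@pytest.fixture(scope="session")
def matrices():
    return load_matrices()


@pytest.fixture(scope="session")
def cfg():
    return AlignConfig()


@pytest.fixture(scope="session")
def cfg_raw():
    """Literal raw-count weighted scores (no motif-count normalization)."""
    return AlignConfig(normalize_counts=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240926)


@pytest.fixture(scope="session")
def kink_family():
    return sample_family(KINK_TURN_LIKE, 5, seed=42)
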