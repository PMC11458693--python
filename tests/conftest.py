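import numpy as np
import pytest

from scftir.features import build_feature_matrix, detect_peaks
from scftir.preprocess import PreprocessConfig, preprocess_cohort
from scftir.simulate import noise_free_design, simulate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Two identical noise-free cells with the default 14-band composition."""
    return simulate_cohort(noise_free_design(n_cells=2))


@pytest.fixture(scope="session")
def noise_free_chain(noise_free_cohort):
    """(processed absorbance, second derivative) of the noise-free cohort."""
    return preprocess_cohort(noise_free_cohort, PreprocessConfig(apply_emsc=False))


@pytest.fixture(scope="session")
def consensus_peaks(noise_free_chain):
    _, deriv = noise_free_chain
    return detect_peaks(deriv)


@pytest.fixture(scope="session")
def noise_free_features(noise_free_chain, consensus_peaks):
    processed, deriv = noise_free_chain
    return build_feature_matrix(processed, deriv, consensus_peaks)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
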