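import numpy as np
import pytest

from cytonuclei import ISBI_PARAMS, ParameterSet, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ParameterSet()


@pytest.fixture
def isbi_params():
    return ISBI_PARAMS


@pytest.fixture(scope="session")
def clean_fixture():
    """One noise-free synthetic image with 5 nuclei and no distractors."""
    spec = SyntheticSpec(
        image_size=(192, 192), n_nuclei=(5, 5), noise_sd=0.0,
        n_artifacts=0, n_speckles=0, seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def noisy_fixture():
    """A default-condition synthetic image (noise, artifacts, speckles)."""
    return generate(SyntheticSpec(seed=42))
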