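import numpy as np
import pytest

from fcaunet.synthetic import PhantomSpec, generate_dataset, low_contrast_fixture


@pytest.fixture(scope="session")
def easy_dataset():
    """Small easy-mode phantom set shared across tests (24 per class)."""
    return generate_dataset(24, PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def dark_fixture():
    return low_contrast_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
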