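import numpy as np
import pytest
from hypothesis import settings

import vplatelet as vp

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rates():
    """Shipped calibrated rate set."""
    return vp.default_rates()


@pytest.fixture(scope="session")
def human():
    return vp.human_baseline()


@pytest.fixture(scope="session")
def mouse():
    return vp.mouse_baseline()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
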