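import numpy as np
import pytest

from ferropoiesis import default_parameters, presets


@pytest.fixture(scope="session")
def params():
    """Finalised default parameter set (session-wide: it is immutable)."""
    return default_parameters()


@pytest.fixture(scope="session")
def scenario_lib():
    return presets()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)
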