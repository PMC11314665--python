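import numpy as np
import pytest

from gaitcontext import load_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy("builtin")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
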