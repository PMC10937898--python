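import numpy as np
import pytest
from hypothesis import settings

from drrc.codec import build_code_table

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table():
    return build_code_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
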