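import numpy as np
import pytest

from crisprattn.synthetic import gen_toy_fixtures


@pytest.fixture(scope="session")
def toy():
    """Hand-computable micro-fixtures (6-gene network, 5 guides, perfect pair)."""
    return gen_toy_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
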