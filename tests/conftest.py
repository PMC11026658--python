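import numpy as np
import pytest

from blt.task import build_schedule


@pytest.fixture(scope="session")
def schedule():
    """Standard 80-trial, 80/20, four-reversal schedule."""
    return build_schedule(seed=11)


@pytest.fixture(scope="session")
def bernoulli_schedule():
    return build_schedule(realization="bernoulli", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
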