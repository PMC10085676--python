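import numpy as np
import pytest

from epbarriers import perfect_invader, wt_construct


@pytest.fixture(scope="session")
def wt():
    return wt_construct()


@pytest.fixture(scope="session")
def perfect(wt):
    construct, _ = perfect_invader(wt)
    return construct


@pytest.fixture()
def rng():
    return np.random.default_rng(20230302)
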