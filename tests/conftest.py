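import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pairflow.synthetic_data import FishPairParams, generate_pair
from pairflow.trajectory_io import SymbolSeries


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def following_pair():
    """One deterministic following-mode pair (leader = agent 0)."""
    return generate_pair(FishPairParams(mode="following", seed=7))


@pytest.fixture(scope="session")
def anticipatory_pair():
    return generate_pair(FishPairParams(mode="anticipatory", seed=7))


@pytest.fixture(scope="session")
def independent_pair():
    return generate_pair(FishPairParams(mode="independent", seed=7))


def make_symbols(values, bits=1, dt=1.0):
    return SymbolSeries(symbols=np.asarray(values), bits=bits, time_step_s=dt)
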