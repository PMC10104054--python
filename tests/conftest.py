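import numpy as np
import pytest

from beliefrnn.beliefs import build_babayan_space, build_starkweather_space
from beliefrnn.tasks import BabayanConfig, StarkweatherConfig, generate_session


@pytest.fixture(scope="session")
def space1():
    return build_starkweather_space(1)


@pytest.fixture(scope="session")
def space2():
    return build_starkweather_space(2)


@pytest.fixture(scope="session")
def space_b():
    return build_babayan_space()


@pytest.fixture(scope="session")
def session1():
    return generate_session(StarkweatherConfig(variant=1), 400, 11)


@pytest.fixture(scope="session")
def session2():
    return generate_session(StarkweatherConfig(variant=2), 400, 22)


@pytest.fixture(scope="session")
def session_b():
    return generate_session(BabayanConfig(), 200, 33)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
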