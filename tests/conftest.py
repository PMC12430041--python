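import numpy as np
import pytest

from wheatsa import (
    WheatEmulator,
    build_treatment,
    generate_weather,
    load_bounds,
    midpoint_defaults,
)


@pytest.fixture(scope="session")
def specs():
    return load_bounds()


@pytest.fixture(scope="session")
def midpoints(specs):
    return midpoint_defaults(specs)


@pytest.fixture(scope="session")
def weathers():
    """The three study seasons (one seeded weather series per year)."""
    return {2023 + i: generate_weather(seed=101 + i) for i in range(3)}


@pytest.fixture(scope="session")
def weather(weathers):
    return weathers[2023]


@pytest.fixture(scope="session")
def plans():
    return [build_treatment(c) for c in ("W1", "W2", "W3", "W4", "W5", "W6")]


@pytest.fixture(scope="session")
def plan_w1(plans):
    return plans[0]


@pytest.fixture(scope="session")
def emulator(specs):
    return WheatEmulator(specs=specs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
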