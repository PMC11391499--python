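import numpy as np
import pytest

from egoallo.geometry import build_port_wall, session_design
from egoallo.simulate import generate_population, generate_session


@pytest.fixture(scope="session")
def wall():
    return build_port_wall()


@pytest.fixture(scope="session")
def reference_design(wall):
    return session_design("reference", wall)


@pytest.fixture(scope="session")
def reference_trials(reference_design):
    return generate_session(reference_design, 480, seed=11)


@pytest.fixture(scope="session")
def small_mixed_population():
    """A reference session with a few neurons of each pure tuning kind."""
    return generate_population(
        {"start": 6, "direction": 6, "target": 6, "none": 6},
        design="reference", n_trials=480, seed=23,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
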