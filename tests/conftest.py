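import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import statewalk as sw

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return sw.AngularGrid(72)


@pytest.fixture(scope="session")
def crw_species():
    """Single-state correlated random walk: rho 0.95, step 10, range 200."""
    return sw.Species(
        (sw.state_crw(0.95, 10.0, 200.0),),
        sw.make_transition_matrix([[0.0]]),
        name="crw",
    )


@pytest.fixture(scope="session")
def two_state_species():
    """Compound RW + CRW walker with symmetric 0.01 switching."""
    return sw.Species(
        (sw.state_rw(10.0, 200.0), sw.state_crw(0.95, 10.0, 200.0)),
        sw.make_transition_matrix([[0.0, 0.01], [0.01, 0.0]]),
        name="levy_like",
    )


@pytest.fixture(scope="session")
def river_raster():
    """Binary meandering channel, 6 cells wide, in an impassable matrix."""
    spec = sw.SyntheticLandscapeSpec(kind="river_corridor", seed=3)
    return sw.make_landscape(spec)


@pytest.fixture(scope="session")
def corridor_raster():
    """Straight east-west channel of zero resistance, 3 cells wide, amid 1s."""
    values = np.ones((9, 21))
    values[3:6, :] = 0.0
    return sw.ResistanceRaster(values, 0.0, 0.0, 10.0)
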