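import numpy as np
import pytest

from atriasim.engine import SolverConfig, pace
from atriasim.geometry import build_geometry
from atriasim.params import Parameters
from atriasim.state import default_initial_state


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def geom():
    return build_geometry()


@pytest.fixture(scope="session")
def packed(params, geom):
    return params.pack(geom)


@pytest.fixture(scope="session")
def y_steady():
    """Cached 1 Hz paced steady state of the default (vCa) variant."""
    return default_initial_state("vCa")


@pytest.fixture(scope="session")
def steady_trace(y_steady, params):
    """Three steady 1 Hz beats, shared by AP/Ca metric tests."""
    return pace(y_steady, 1000.0, 3, params=params)


@pytest.fixture(scope="session")
def fine_trace(y_steady, params):
    """One beat recorded at 0.1 ms everywhere, for bookkeeping integrals."""
    solver = SolverConfig(sample_ms=0.1, fine_sample_ms=0.02)
    return pace(y_steady, 1000.0, 1, params=params, solver=solver)
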