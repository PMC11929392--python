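import numpy as np
import pytest

from dsirep.gridworld import build_room
from dsirep.successor import compute_psi, occupancy, sr_analytic


@pytest.fixture(scope="session")
def open_room_10():
    return build_room(10, 10)


@pytest.fixture(scope="session")
def analytic_psi_10(open_room_10):
    """Exact PSI of the 10x10 open room under the default policy."""
    T = open_room_10.transition_matrix()
    return compute_psi(sr_analytic(T, 0.99), occupancy(T)).values


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
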