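import numpy as np
import pytest

from phipflow.chip_transport import TransportConfig, build_geometry
from phipflow.reaction_kinetics import build_network


@pytest.fixture(scope="session")
def calibrated_network():
    """Clamped-hydrogen network at the calibrated constants (tube model)."""
    return build_network(hydrogen_clamp=20.0)


@pytest.fixture(scope="session")
def tube_initial_state():
    return {"1": 5.0, "3": 20.0, "2": 20.0}


@pytest.fixture
def small_geometry():
    """A short chip variant for fast transport tests (same topology)."""
    return build_geometry(
        channel_length_mm=10.0,
        membrane_start_mm=1.0,
        membrane_length_mm=5.0,
        chamber_start_mm=7.0,
        chamber_length_mm=1.5,
    )


@pytest.fixture
def small_config():
    return TransportConfig(flow_uL_min=2.0, dx_mm=0.25, n_across_channel=4, n_across_upper=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
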