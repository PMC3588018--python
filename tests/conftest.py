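import pytest

from mlpb.grid import build_grid
from mlpb.parameters import dppc_gel, dppc_liquid
from mlpb.solver import solve_mlpb


@pytest.fixture(scope="session")
def gel_params():
    """DPPC gel phase at 310 K (a0 = 0.48 nm^2)."""
    return dppc_gel()


@pytest.fixture(scope="session")
def liquid_params():
    """DPPC liquid-crystalline phase at 323 K (a0 = 0.60 nm^2)."""
    return dppc_liquid()


@pytest.fixture(scope="session")
def room_params():
    """Gel-phase areas at 298 K, for bulk-permittivity and screening checks."""
    return dppc_gel(298.0)


@pytest.fixture(scope="session")
def gel_state(gel_params):
    return solve_mlpb(gel_params, build_grid(gel_params, 4000))


@pytest.fixture(scope="session")
def liquid_state(liquid_params):
    return solve_mlpb(liquid_params, build_grid(liquid_params, 4000))
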