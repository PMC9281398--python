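import numpy as np
import pytest

from lols import Dihedral, MoleculeSpec, make_synthetic_pes
from lols.energy_backend import SyntheticPES, bruteforce_minima


@pytest.fixture(scope="session")
def chain_spec():
    """Acyclic 8-carbon zig-zag chain with 5 free backbone dihedrals."""
    n = 8
    coords = np.zeros((n, 3))
    for i in range(1, n):
        coords[i] = coords[i - 1] + (1.2, 0.9 * (-1) ** i, 0.0)
    return MoleculeSpec(
        symbols=["C"] * n,
        coords=coords,
        dihedrals=[Dihedral((i, i + 1, i + 2, i + 3)) for i in range(5)],
        name="chain8",
    )


@pytest.fixture(scope="session")
def pes2():
    """2-D coupled multi-well test landscape."""
    return make_synthetic_pes(2, 4, seed=3)


@pytest.fixture(scope="session")
def pes2_separable():
    """Separable 2-D landscape with per-dimension minima at 60 and 240 deg.

    cos(2u + pi/3) has minima where 2u + pi/3 = pi (mod 2pi), i.e.
    u = pi/3 and u = 4pi/3: exactly 60 and 240 deg.  No tilt, no coupling.
    """
    return SyntheticPES(
        dim=2,
        counts=[2, 2],
        amplitudes=[0.2, 0.25],
        phases=[np.pi / 3, np.pi / 3],
        tilt_amps=[0.0, 0.0],
        tilt_phases=[0.0, 0.0],
        couplings=[(0, 1, 1.0, 0.0)],
        coupling_strength=0.0,
        base_energy=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def pes5():
    """The 5-D benchmark landscape."""
    return make_synthetic_pes(5, 10, seed=1)


@pytest.fixture(scope="session")
def oracle2(pes2):
    return bruteforce_minima(pes2, 24)
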