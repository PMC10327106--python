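import numpy as np
import pytest

from memfield.membrane import HydrationModel, MembraneFrame
from memfield.scoring import MembraneSystem
from memfield.structure import build_ideal_helix


@pytest.fixture(scope="session")
def dlpc_system():
    return MembraneSystem.for_lipid("DLPC")


@pytest.fixture(scope="session")
def frame():
    return MembraneFrame(half_thickness=10.8)


@pytest.fixture(scope="session")
def hydration(frame):
    return HydrationModel(frame)


@pytest.fixture(scope="session")
def ala20():
    return build_ideal_helix("A" * 20)


@pytest.fixture()
def apolar_probe(ala20):
    """Chargeless helix with strictly positive transfer energies everywhere.

    The idealized 'all-polar' probe: no Coulomb terms, every atom prefers
    water, so the zero-energy aqueous state is the global optimum.
    """
    st = ala20.copy()
    st.charge[:] = 0.0
    st.dg_wl = np.abs(st.dg_wl) + 0.1
    return st
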