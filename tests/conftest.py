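import numpy as np
import pytest

from fockforge.geometry import Geometry
from fockforge.scf import build_ao_context, reference_scf


@pytest.fixture(scope="session")
def h2():
    r = 1.4 * 0.52917721092  # the textbook bond length, 1.4 bohr
    return Geometry(("H", "H"), [[0, 0, 0], [r, 0, 0]])


@pytest.fixture(scope="session")
def h2_ctx(h2):
    return build_ao_context(h2)


@pytest.fixture(scope="session")
def h2_scf(h2_ctx):
    return reference_scf(h2_ctx)


@pytest.fixture(scope="session")
def lif():
    return Geometry(("Li", "F"), [[0, 0, 0], [1.45, 0, 0]])


@pytest.fixture(scope="session")
def lif_ctx(lif):
    return build_ao_context(lif)


@pytest.fixture(scope="session")
def lif_scf(lif_ctx):
    return reference_scf(lif_ctx)


@pytest.fixture(scope="session")
def ch4():
    from fockforge.structures import initial_structure

    return initial_structure("CH4")


@pytest.fixture(scope="session")
def ch4_ctx(ch4):
    return build_ao_context(ch4)


@pytest.fixture(scope="session")
def ch4_scf(ch4_ctx):
    return reference_scf(ch4_ctx)


@pytest.fixture(scope="session")
def water():
    ang = np.deg2rad(104.4776)
    return Geometry(
        ("O", "H", "H"),
        [[0, 0, 0], [0.9578, 0, 0], [0.9578 * np.cos(ang), 0.9578 * np.sin(ang), 0]],
    )
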