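import numpy as np
import pytest

from pistack import CFHPotential, HSPotential
from pistack.fixtures import load_fixture
from pistack.geometry import dimer_family
from pistack.surface import scan

X_VALUES = np.round(np.arange(-4.0, 4.0001, 0.1), 10)
Z_VALUES = np.round(np.arange(3.0, 6.0001, 0.05), 10)


@pytest.fixture(scope="session")
def benzene():
    return load_fixture("benzene")


@pytest.fixture(scope="session")
def pyridine():
    return load_fixture("pyridine")


@pytest.fixture(scope="session")
def triazine():
    return load_fixture("s-triazine")


@pytest.fixture(scope="session")
def hs_benzene(benzene):
    return HSPotential(benzene.chargeset, benzene.chargeset, benzene.vdw_params)


@pytest.fixture(scope="session")
def cfh_benzene(benzene):
    return CFHPotential(benzene.cfh_params)


@pytest.fixture(scope="session")
def parallel_family(benzene):
    return dimer_family(benzene.monomer, benzene.monomer, "parallel")


@pytest.fixture(scope="session")
def hs_parallel_grid(parallel_family, hs_benzene):
    """Full reference scan of the parallel benzene dimer, sigma/pi model."""
    return scan(parallel_family, hs_benzene, X_VALUES, Z_VALUES)


@pytest.fixture(scope="session")
def cfh_parallel_grid(parallel_family, cfh_benzene):
    """Full reference scan of the parallel benzene dimer, Gaussian-Pauli model."""
    return scan(parallel_family, cfh_benzene, X_VALUES, Z_VALUES)
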