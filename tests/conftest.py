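import pytest

from rgcsim.membrane import DistributionTable
from rgcsim.morphology import Compartment, Morphology, Region
from rgcsim.simulator import SimulationConfig
from rgcsim.synthetic import reference_fixture


@pytest.fixture(scope="session")
def fixture_cell():
    """The canonical compliant reference morphology (axon attached)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def soma_only():
    """A bare 20 x 20 um soma cylinder."""
    return Morphology([Compartment(1, None, Region.SOMA, 20.0, 20.0)])


@pytest.fixture()
def passive_table():
    """Channel table with every active conductance removed (leak only)."""
    return DistributionTable(
        g_Na=(0.0,) * 6, g_Ca=(0.0,) * 6, g_K=(0.0,) * 6, g_KA=(0.0,) * 6,
        g_KCa_max=(0.0,) * 6)


@pytest.fixture()
def soma_config():
    return SimulationConfig(record_sites=("soma",))


@pytest.fixture(scope="session")
def binary_tree():
    """Soma with one primary dendrite bifurcating twice: 4 tips, 3 branch
    points."""
    comps = [Compartment(1, None, Region.SOMA, 20.0, 20.0)]
    nid = 2
    # primary
    comps.append(Compartment(2, 1, Region.DENDRITE, 50.0, 2.0))
    # two children, each with two children
    layout = [(3, 2), (4, 2), (5, 3), (6, 3), (7, 4), (8, 4)]
    for cid, parent in layout:
        comps.append(Compartment(cid, parent, Region.DENDRITE, 40.0, 1.0))
    return Morphology(comps)
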