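import numpy as np
import pytest

from vndconf import (AngleGrid, EnergyModel, make_alkane,
                     partition_rigid_bodies)


@pytest.fixture(scope="session")
def alkane6():
    system = make_alkane(6)
    graph = partition_rigid_bodies(system)
    model = EnergyModel(system)
    return system, graph, model


@pytest.fixture(scope="session")
def grid12():
    return AngleGrid.uniform(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
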