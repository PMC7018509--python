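import numpy as np
import pytest

from neocolumn.cells import build_cell_template
from neocolumn.network import build_network


@pytest.fixture(scope="session")
def l5_template():
    return build_cell_template("L5Pyr")


@pytest.fixture(scope="session")
def l23_template():
    return build_cell_template("L23Pyr")


@pytest.fixture(scope="session")
def basket_template():
    return build_cell_template("Basket")


@pytest.fixture(scope="session")
def tiny_network():
    """3x3 pyramidal grid with the default connectivity (fast to simulate)."""
    return build_network(3, 3)


@pytest.fixture(scope="session")
def tiny_compiled(tiny_network):
    from neocolumn.engine import CompiledNetwork

    return CompiledNetwork(tiny_network.cells, tiny_network.synapses)


@pytest.fixture(scope="session")
def erp_model_small():
    """The packaged evoked-response scenario at reduced (5x5) scale."""
    from neocolumn.model import ColumnModel

    return ColumnModel.from_scenario("erp", n_pyr=5, seed=3)


@pytest.fixture(scope="session")
def erp_result_small(erp_model_small):
    return erp_model_small.simulate()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
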