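import numpy as np
import pytest

from agegrn import (ParameterSet, build_ageing_network, delete_edges,
                    P53_INACTIVATION_EDGES)


@pytest.fixture(scope="session")
def ageing():
    return build_ageing_network()


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def perturbed(ageing):
    """Ageing network with the p53-inactivating edges removed."""
    return delete_edges(ageing, P53_INACTIVATION_EDGES)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
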