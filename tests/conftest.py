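import numpy as np
import pytest

from labeldyn.calibrate import REF_CONC, default_parameters
from labeldyn.labeling import LabelModel
from labeldyn.network import build_network, default_network, integrate_to_steady_state


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def params(network):
    return default_parameters(network, "control")


@pytest.fixture(scope="session")
def steady(network, params):
    state = integrate_to_steady_state(network, params, c0=REF_CONC)
    assert state.steady
    return state


@pytest.fixture(scope="session")
def label_model(network, steady):
    return LabelModel(network, steady)


@pytest.fixture(scope="session")
def trajectory(label_model):
    return label_model.simulate(2880.0)


@pytest.fixture()
def pdh_toy_config():
    """v0 -> pyr -> accoa -> : constant input of fully labelled pyruvate."""
    return {
        "metabolites": [
            {"name": "pyr", "carbons": 3},
            {"name": "accoa", "carbons": 2},
        ],
        "reactions": [
            {"name": "v0", "kind": "const", "product": "pyr",
             "labeling": "111", "map": {"pyr": "000"}},
            {"name": "pdh", "kind": "mm", "substrate": "pyr",
             "product": "accoa", "km": 0.5,
             "map": {"pyr": "abc", "accoa": "bc"}},
            {"name": "efflux", "kind": "mm", "substrate": "accoa", "km": 0.5,
             "map": {"accoa": "ab"}},
        ],
    }


@pytest.fixture()
def pdh_toy(pdh_toy_config):
    return build_network(pdh_toy_config)


def rng(seed=0):
    return np.random.default_rng(seed)
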