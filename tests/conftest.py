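import numpy as np
import pytest

from fluxent import build_polytope, make_toy_network
from fluxent.model_io import StoichiometricModel


@pytest.fixture(scope="session")
def interval():
    model, gt = make_toy_network("interval")
    return model, gt, build_polytope(model)


@pytest.fixture(scope="session")
def simplex3():
    model, gt = make_toy_network("simplex", dim=3)
    return model, gt, build_polytope(model)


@pytest.fixture(scope="session")
def triangle():
    """2-simplex: {v1, v2 >= 0, v1 + v2 <= 1} with growth lambda = v1."""
    model, gt = make_toy_network("simplex", dim=2)
    return model, gt, build_polytope(model)


@pytest.fixture(scope="session")
def diamond():
    model, gt = make_toy_network("diamond")
    return model, gt


@pytest.fixture()
def unit_square():
    """Two independent fluxes on [0,1]^2, growth = first coordinate."""
    model = StoichiometricModel([], ["x", "y"], np.zeros((0, 2)),
                                [0.0, 0.0], [1.0, 1.0], [1.0, 0.0])
    return model, build_polytope(model)
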