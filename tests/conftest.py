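import numpy as np
import pytest

import gridfield as gf

#: W0 value used by the reference homogeneous-problem experiments.  Taken as
#: a given input of those experiments (the quadrature of the tanh kernel
#: itself is checked separately).
W0_REFERENCE = -20.6711
B_REFERENCE = 3.0


@pytest.fixture(scope="session")
def phi_eps():
    return gf.smooth_product(0.01)


@pytest.fixture(scope="session")
def shifts():
    return gf.ShiftSet()  # z = 2/128


@pytest.fixture(scope="session")
def sheet64():
    return gf.SheetGrid(64)


@pytest.fixture(scope="session")
def tanh_conn_256():
    """Reference tanh kernel sampled at high resolution (for quadrature/modes)."""
    return gf.eval_connectivity("tanh_bump", gf.SheetGrid(256))


@pytest.fixture(scope="session")
def tanh_conn_64(sheet64):
    return gf.eval_connectivity("tanh_bump", sheet64)


@pytest.fixture(scope="session")
def fig2_state(phi_eps):
    """Homogeneous stationary state at the reference parameters, sigma=0.03."""
    return gf.solve_consistency(phi_eps, W0_REFERENCE, B_REFERENCE, 0.03)
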