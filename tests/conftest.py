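import numpy as np
import pytest

from foamsim.constitutive import MaterialParams
from foamsim.foam_geometry import build_kelvin_cell


@pytest.fixture(scope="session")
def table_cell():
    """The published H20 foam cell: theta = 65.92 deg, L = 0.58 mm, r = 50.44 um."""
    return build_kelvin_cell(65.92, 0.58e-3, 50.44e-6)


@pytest.fixture(scope="session")
def table_params():
    """Default (literal-table) material parameter set."""
    return MaterialParams()


@pytest.fixture(scope="session")
def viscous_params():
    """A parameter set whose Maxwell branch is unfloored (3 mu/lam < Es),
    used by the relaxation and Jacobian oracles."""
    return MaterialParams(Eh=4.0e6, El=2.03e6, mu_h=2.0e5, mu_l=1.0e5,
                          mu_units="Pa_s", lam_h=1.0, lam_l=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
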