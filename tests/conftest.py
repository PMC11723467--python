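import numpy as np
import pytest

from lamigrind import CutterSpec, ForceCoefficients, MillingPlan, NormalizationParams
from lamigrind.phantom import make_lamina_phantom, make_step_phantom


@pytest.fixture(scope="session")
def spec():
    return CutterSpec()


@pytest.fixture(scope="session")
def coeffs():
    return ForceCoefficients()


@pytest.fixture(scope="session")
def norm():
    return NormalizationParams()


@pytest.fixture(scope="session")
def step_vol():
    return make_step_phantom()


@pytest.fixture(scope="session")
def lamina_vol():
    return make_lamina_phantom(seed=7)


@pytest.fixture(scope="session")
def table_plan():
    """Reference milling plan: 3 layers x 4 paths of 12 mm on the stepped block."""
    return MillingPlan(workspace_origin=np.array([0.0, 1.8, 6.0]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
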