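import numpy as np
import pytest

from nucleopos import GrowthCurveModel
from nucleopos.simulate import default_plate_config, simulate_plate

# One fixed-seed realisation of the default simulated experiment, shared by
# the growth, effects and acceptance tests (simulation + fit is the slow part).
PLATE_SEED = 20240917


@pytest.fixture(scope="session")
def default_plate():
    return simulate_plate(default_plate_config(seed=PLATE_SEED))


@pytest.fixture(scope="session")
def fitted_default(default_plate):
    plate, truth = default_plate
    return GrowthCurveModel(plate).fit(), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
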