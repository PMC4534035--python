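import warnings

import pytest

from standclim.climate import SyntheticClimateParams, generate_synthetic_climate
from standclim.config import default_config
from standclim import simulator


@pytest.fixture(scope="session")
def ref5():
    """Five synthetic reference years (small enough for fast unit tests)."""
    return generate_synthetic_climate(SyntheticClimateParams(), 5, seed=11)


@pytest.fixture(scope="session")
def cfg5():
    return default_config(reference_years=5, run_years=10, seed=11)


@pytest.fixture(scope="session")
def cal5(ref5, cfg5):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulator.calibrate(ref5, cfg5)
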