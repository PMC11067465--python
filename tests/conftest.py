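import numpy as np
import pytest

import schoolsim as ss


@pytest.fixture(scope="session")
def table_params() -> ss.ModelParams:
    """Calibrated N=39 school parameters."""
    return ss.ModelParams()


@pytest.fixture(scope="session")
def short_standard_run() -> ss.TrajectoryEnsemble:
    """Short ordered-phase standard-model run shared across suites."""
    return ss.simulate(ss.ModelParams(seed=7), 3500, 500)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
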