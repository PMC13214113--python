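import numpy as np
import pytest

from vigorcoh.bands import BAND_PRESETS
from vigorcoh.synth import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = SimulationConfig(n_subjects=6, n_trials_per_condition=20,
                           rng_seed=2024)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=list(BAND_PRESETS))
def band(request):
    return BAND_PRESETS[request.param]
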