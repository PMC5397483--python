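import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import streamseg as ss

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def a1_params():
    return ss.A1Params()


@pytest.fixture(scope="session")
def net_params():
    return ss.NetworkParams()


@pytest.fixture(scope="session")
def small_ensemble(a1_params, net_params):
    """60-trial adapting-input ensemble at DF 7, 8 triplets."""
    tl = ss.make_triplet_sequence(8, 7.0)
    trace = ss.compute_input_trace(tl, a1_params, net_params.dt)
    bank = ss.NoiseBank(n_trials=60, master_seed=123)
    return ss.run_ensemble(trace, net_params, bank)


@pytest.fixture(scope="session")
def battery500():
    """The full property battery at the published ensemble size (n = 500)."""
    return ss.run_property_battery(n_trials=500, master_seed=20)
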