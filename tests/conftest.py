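import numpy as np
import pytest

from recallsim.config import ClinicConfig, ServiceTimeSpec
from recallsim.experiments import run_matrix


@pytest.fixture(scope="session")
def default_matrix():
    """The full 8-scenario experiment: 365 weekdays x 10 seeds per scenario."""
    return run_matrix(days=365, seeds=range(10))


@pytest.fixture(scope="session")
def sensitivity_matrix():
    """The same matrix with recall rates proportionally scaled to 15% overall."""
    return run_matrix(days=365, seeds=range(10), recall_scale_to=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def deterministic_config():
    """Clinic with every service-time SD zeroed: queue-free days are exactly
    the sum of stage means, which makes path lengths hand-checkable."""
    cfg = ClinicConfig()
    cfg.service_times = {
        k: ServiceTimeSpec(v.mean, 0.0) for k, v in cfg.service_times.items()
    }
    cfg.no_show_rate = 0.0
    return cfg
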