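import numpy as np
import pytest

from tunlsim.engine import SimConfig, run_simulation
from tunlsim.protocol import DAY, PhaseId


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_cohort_run():
    """One-day cohort run over the early curriculum (T1-T3), calibrated
    agents -- shared across engine/analysis tests."""
    cfg = SimConfig(seed=7, duration=1 * DAY + DAY // 2,
                    curriculum=(PhaseId.T1, PhaseId.T2, PhaseId.T3))
    log, result = run_simulation(cfg, "calibrated")
    return cfg, log, result
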