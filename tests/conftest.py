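import numpy as np
import pytest

from stn_gammaburst import SimConfig, generate_session
from stn_gammaburst.kinematics import extract_trials


@pytest.fixture(scope="session")
def default_session():
    """One default ON session (both electrodes) shared across tests."""
    cfg = SimConfig(seed=11)
    rec, truth = generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def default_trials(default_session):
    _, rec, _ = default_session
    return extract_trials(rec)


@pytest.fixture(scope="session")
def quiet_session():
    """Session with no oscillatory events: background + line noise only."""
    from stn_gammaburst.config import BetaParams, BurstParams, ThetaParams
    cfg = SimConfig(
        seed=7, electrodes=("contra",),
        beta=BetaParams(amplitude=0.0),
        theta=ThetaParams(ers_amplitude=0.0),
        bursts=BurstParams(amplitude_mean=1e-6, baseline_rate_per_halfs=1e-3,
                           movement_gain_by_condition=(0.0, 0.0, 0.0),
                           velocity_coupling=0.0),
    )
    rec, truth = generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
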