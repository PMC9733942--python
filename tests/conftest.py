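import numpy as np
import pytest

import thetastim as th


@pytest.fixture(scope="session")
def session_m03():
    """One moderately sized synthetic session with 30% theta-phase
    modulation of both EP components (shared across tests)."""
    cfg = th.SynthConfig(n_pulses=600, modulation_depth=0.3)
    rec, gt = th.generate_session(cfg, np.random.default_rng(42))
    return rec, gt


@pytest.fixture(scope="session")
def stim_trials_m03(session_m03):
    rec, _ = session_m03
    ts, report = th.stim_trialset(rec, 0)
    return ts, report
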