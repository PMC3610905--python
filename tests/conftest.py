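import numpy as np
import pytest
from hypothesis import settings

import wormstates as ws

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def three_states():
    """Canonical well-separated roaming/dwelling/quiescence triplet."""
    states, lifetimes = ws.three_state_example()
    return states, lifetimes


@pytest.fixture(scope="session")
def switching_series(three_states):
    """A 3-state characteristic series with strong temporal structure."""
    states, lifetimes = three_states
    cfg = ws.SimConfig(states=states, lifetimes=lifetimes, duration=1800,
                       seed=42)
    seq = ws.simulate_state_sequence(cfg)
    return ws.simulate_characteristics(states, seq, seed=43), seq


@pytest.fixture(scope="session")
def two_state_pair():
    """Two well-separated states and a series generated from them."""
    states = [
        ws.StateDescription(p_rev=0.05, mu_s=0.5, mu_a=0.5, var_s=0.05,
                            var_a=0.05, var_ar=0.02),
        ws.StateDescription(p_rev=0.30, mu_s=3.0, mu_a=1.5, var_s=0.10,
                            var_a=0.10, var_ar=0.05),
    ]
    cfg = ws.SimConfig(states=states, lifetimes=[80.0, 80.0], duration=2400,
                       seed=7)
    seq = ws.simulate_state_sequence(cfg)
    series = ws.simulate_characteristics(states, seq, seed=8)
    return states, seq, series


def random_series(n, seed, m_feature_scale=1.0):
    """I.i.d. featureless series (no temporal structure)."""
    rng = np.random.default_rng(seed)
    obs = rng.normal(1.0, m_feature_scale, size=(n, 3))
    return ws.MotionSeries(
        times=np.arange(n, dtype=float),
        valid=np.ones(n, bool),
        r=rng.integers(0, 2, n),
        s=obs[:, 0],
        a_t=obs[:, 1],
        a_r=obs[:, 2],
        s_hat=obs[:, 0],
        a_hat=obs[:, 1],
        ar_hat=obs[:, 2],
    )
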