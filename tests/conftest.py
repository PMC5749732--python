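import numpy as np
import pytest

from circabiolum import OscillatorParams, Trace, make_protocol, simulate_population


@pytest.fixture
def t20_protocol():
    return make_protocol(20, 10, 4, 6, 72)


@pytest.fixture
def t24_protocol():
    return make_protocol(24, 12, 4, 6, 72)


def make_cosine_trace(a=30.0, tau=24.0, theta=1.0, offset=100.0,
                      duration_h=96.0, dt=0.5, noise_sd=0.0, seed=0,
                      cell_id="c0"):
    t = np.arange(0.0, duration_h + 1e-9, dt)
    v = a * np.cos(2 * np.pi * t / tau - theta) + offset
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return Trace(cell_id, t, v)


@pytest.fixture
def cosine_trace():
    return make_cosine_trace()


@pytest.fixture(scope="session")
def free_running_cells():
    """Twenty quiet free-running oscillators with ground truth (session cache)."""
    params = OscillatorParams(tau_sd=1.0, noise_phase_sd=0.02, noise_obs_sd=1.0,
                              seed=42)
    return simulate_population(20, params, None, duration_h=192.0)
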