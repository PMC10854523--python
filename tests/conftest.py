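import numpy as np
import pytest

from pacnav import PacSimConfig, simulate_pac_signal


@pytest.fixture(scope="session")
def coupled_signal():
    """10 s strongly coupled signal (depth 0.9, f_p = 6 Hz, f_A = 150 Hz)."""
    cfg = PacSimConfig(seed=11, depth=0.9, noise_sd=5.0)
    return simulate_pac_signal(cfg).data[:, 0], cfg


@pytest.fixture(scope="session")
def uncoupled_signal():
    """Same generator and seed with depth 0: constant fast-band envelope."""
    cfg = PacSimConfig(seed=11, depth=0.0, noise_sd=5.0)
    return simulate_pac_signal(cfg).data[:, 0], cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
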