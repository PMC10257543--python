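import numpy as np
import pytest

import qamskit as qk


@pytest.fixture(scope="session")
def panel():
    return qk.default_panel()


@pytest.fixture(scope="session")
def ffa_noise_free():
    cfg = qk.example_ffa_config(seed=42, noise_sd=0.0, baseline_drift=0.0)
    return qk.simulate_chromatogram(cfg)


@pytest.fixture(scope="session")
def ffa_default_noise():
    return qk.simulate_chromatogram(qk.example_ffa_config(seed=42))


@pytest.fixture(scope="session")
def rfa_default_noise():
    return qk.simulate_chromatogram(qk.example_rfa_config(seed=42))


@pytest.fixture(scope="session")
def single_gaussian():
    """One isolated unit-area Gaussian at 10 min on a 20-min axis."""
    t = np.linspace(0.0, 20.0, 2001)
    sigma = 0.1
    y = np.exp(-0.5 * ((t - 10.0) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return qk.Chromatogram(t, y)
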