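import numpy as np
import pytest

from obcode.synth import SynthConfig, generate_session_pair


@pytest.fixture(scope="session")
def noiseless_pair():
    """Small paired session with zero noise and a 0.5 quench factor."""
    cfg = SynthConfig(n_cells=8, n_odors=4, seed=7, noise_sd=0.0, quench_factor=0.5)
    return cfg, *generate_session_pair(cfg)


@pytest.fixture(scope="session")
def null_pair():
    """Low-noise paired session with no true change between conditions."""
    cfg = SynthConfig(n_cells=12, n_odors=5, seed=3, noise_sd=0.02, quench_factor=1.0)
    return cfg, *generate_session_pair(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201117)
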