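import numpy as np
import pytest

import spikefield as sf


@pytest.fixture(scope="session")
def coupled_session():
    """80-s resting session: 3 Type A units beta-coupled at kappa=2,
    2 uncoupled Type B units.  Shared across tests (read-only)."""
    cfg = sf.default_session_config(
        duration=80.0, n_type_a=3, n_type_b=2, kappa=2.0, coupled_band="beta",
        seed=11,
    )
    session, truth = sf.generate_session(cfg)
    return session, truth


@pytest.fixture(scope="session")
def uncoupled_session():
    """80-s resting session with kappa = 0 everywhere (null coupling)."""
    cfg = sf.default_session_config(
        duration=80.0, n_type_a=3, n_type_b=2, kappa=0.0, coupled_band="beta",
        seed=12,
    )
    session, truth = sf.generate_session(cfg)
    return session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
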