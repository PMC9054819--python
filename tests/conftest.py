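import numpy as np
import pytest

import fiberquant as fq


@pytest.fixture
def clean_session():
    """Noise-free simulated session with a handful of transients."""
    cfg = fq.PhotomSimConfig(
        duration_s=60.0,
        event_rate_hz=0.1,
        event_amplitude_dff=0.05,
        noise_sd=0.0,
        seed=7,
    )
    return fq.simulate_session(cfg)


@pytest.fixture
def channel_pair(clean_session):
    session, _ = clean_session
    return fq.deinterleave(session)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
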