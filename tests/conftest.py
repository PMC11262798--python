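import numpy as np
import pytest

import thetabmi as tb
from thetabmi.coherence import WindowSpec, compute_baseline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def window_spec():
    return WindowSpec()


@pytest.fixture(scope="session")
def coupled_pair():
    """A 1 kHz coupled LFP pair with alternating high/low states, plus
    baselines (shared across tests to amortize generation)."""
    spec = tb.OscillatorSpec(sampling_rate=1000.0)
    states = tb.CoherenceStateTrack.alternating(40, 3.0, 3.0)
    x, y = tb.gen_coupled_lfp(spec, spec, states, seed=101)
    return x, y, states, compute_baseline(x), compute_baseline(y)


@pytest.fixture(scope="session")
def theta_lfp():
    """A strongly theta-dominant single-site LFP at 1 kHz for spike tests."""
    spec = tb.OscillatorSpec(sampling_rate=1000.0, delta_amp=0.0, noise_sd=40.0)
    states = tb.CoherenceStateTrack(("high",), (120.0,))
    x, _ = tb.gen_coupled_lfp(spec, spec, states, seed=202)
    return x
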