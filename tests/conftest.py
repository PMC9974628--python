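import numpy as np
import pytest

from caepdetect import ContinuousRecording, EpochEnsemble, SimulationConfig, simulate_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_ensemble(rng):
    """A 20-epoch, 700 ms / 500 Hz noise ensemble (no response)."""
    return EpochEnsemble(rng.standard_normal((20, 350)) * 10.0, fs=500.0)


@pytest.fixture
def simulated_h0(rng):
    """One simulated null experiment: continuous trace + windowed ensemble."""
    cfg = SimulationConfig(n_epochs=20)
    return simulate_ensemble(cfg, rng)


@pytest.fixture
def white_recording(rng):
    return ContinuousRecording(rng.standard_normal(20000), fs=500.0)
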