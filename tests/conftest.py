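import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mmpipe.synthgen import SimConfig, make_population, simulate_session


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulation config shared by unit tests."""
    return SimConfig(n_sites=1, neurons_per_site=12, session_length_s=240)


@pytest.fixture(scope="session")
def closed_am_session(small_sim):
    neurons = make_population(small_sim, seed=10)
    return simulate_session(small_sim, 0, neurons, "closed", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tensor(data, fs=15.0, window=(-2.0, 5.0), site=None, event="test"):
    """Build a TrialTensor from raw snippets, applying the baseline
    subtraction the constructor asserts."""
    import pandas as pd

    from mmpipe.responses import TrialTensor, _window_frames, BASELINE_WINDOW

    data = np.asarray(data, float)
    offsets = np.arange(int(round(window[0] * fs)), int(round(window[1] * fs)))
    assert data.shape[2] == offsets.size
    base = _window_frames(BASELINE_WINDOW, fs, offsets)
    data = data - data[:, :, base].mean(axis=2, keepdims=True)
    meta = pd.DataFrame({"onset_s": np.zeros(data.shape[0]),
                         "event_type": event})
    if site is None:
        site = np.zeros(data.shape[1], int)
    return TrialTensor(data=data, time_s=(offsets + 0.5) / fs, fs=fs,
                       alignment_event=event, trial_meta=meta,
                       neuron_site=np.asarray(site))
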