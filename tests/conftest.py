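"""Shared fixtures: scaled-down synthetic sessions (fewer channels/trials
than a real acquisition) so every stage is exercised quickly."""

import numpy as np
import pytest

from minf import SimulationConfig, simulate_recording
from minf.preprocessing import (
    OFFLINE_HIGHPASS,
    OFFLINE_LOWPASS,
    baseline_correct,
    epoch_data,
    fir_filter,
)


@pytest.fixture(scope="session")
def small_config():
    """One 20-trial run, 16 channels, strong lateralized ERD, high SNR."""
    return SimulationConfig(
        n_channels=16,
        n_blocks=1,
        n_runs_per_block=1,
        n_trials_per_run=20,
        erd_depth_mu=0.4,
        erd_depth_beta=0.3,
        snr=10.0,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return simulate_recording(small_config)


@pytest.fixture(scope="session")
def band_epochs(small_recording):
    """Epochs of the 8-30 Hz zero-phase-filtered recording, baseline-corrected."""
    filtered = fir_filter(fir_filter(small_recording, OFFLINE_HIGHPASS),
                          OFFLINE_LOWPASS)
    ep = epoch_data(filtered, filtered.events, (-7.0, 9.0))
    return baseline_correct(ep)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
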