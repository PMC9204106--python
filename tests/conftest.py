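import numpy as np
import pytest

from mobigait import synthetic as syn
from mobigait import workflows as wf


@pytest.fixture(scope="session")
def leadfield():
    """Shared 32-channel lead field over the 100-voxel test grid."""
    return syn.make_lead_field(32, (5, 5, 4), 6.0, seed=0)


@pytest.fixture(scope="session")
def timeline():
    return syn.make_timeline(cadence=1.0, n_cycles=60, duration_cv=0.03,
                             seed=11)


@pytest.fixture(scope="session")
def body_sim(timeline):
    return syn.simulate_body(timeline, noise_sd=0.1, seed=11)


@pytest.fixture(scope="session")
def study24():
    """Full simulated group study (24 participants) shared across tests.

    This is the expensive end-to-end run: simulate -> detect gait events ->
    clean EEG (ground-truth decomposition) -> eLORETA -> ROI spectrograms ->
    NKC/NMC band connectivity, for each participant.
    """
    return wf.run_study(n_participants=24, seed=7)


def rng(seed=0):
    return np.random.default_rng(seed)
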