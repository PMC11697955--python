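"""Shared fixtures: short synthetic sessions and recordings.

Everything is generated programmatically at test time; fixtures use
shortened stimulus blocks so the suite stays desk-scale while exercising
the same code paths as the full protocol.
"""

import numpy as np
import pytest

from gapassr.stimgen import GapAssrSpec, NoiseBurstSpec, SessionSchedule, schedule_session
from gapassr.synth import AnimalParams, simulate_recording

FS = 1024.0


@pytest.fixture(scope="session")
def short_schedule():
    """Stimulus specs for a ~2.5 min session (30 ERP trials, ~8/width gaps)."""
    nb = NoiseBurstSpec(repetition_rate_hz=0.5)
    ga = GapAssrSpec()
    ss = SessionSchedule(rest_min=2 / 60, gapassr_min=1.0, noise_min=1.0)
    return nb, ga, ss


@pytest.fixture(scope="session")
def short_events(short_schedule):
    nb, ga, ss = short_schedule
    return schedule_session(nb, ga, ss, seed=42)


@pytest.fixture(scope="session")
def sim_recording(short_events):
    """One simulated wild-type recording for IO/ERP plumbing tests."""
    return simulate_recording(AnimalParams(), short_events, fs=FS, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
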