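"""Shared fixtures: small and full-scale simulated sessions.

Sessions are generated once per test run; the "big" session mirrors the
standard synthetic study conditions (12 movements x 10 attempts, 20
channels, SNR 10, reaction delays N(500, 100) ms onset / N(330, 100) ms
offset) and is shared by the alignment-recovery and end-to-end tests.
"""

import numpy as np
import pytest

from emgsleeve import orchestrate, simdata

BIG_MOVEMENTS = [f"M{i:02d}" for i in range(12)]
SMALL_MOVEMENTS = ["Grasp", "Point", "Open"]


@pytest.fixture(scope="session")
def small_layout():
    return simdata.SleeveLayout.custom(8)


@pytest.fixture(scope="session")
def small_gestures(small_layout):
    return simdata.make_gesture_set(SMALL_MOVEMENTS, small_layout, seed=11)


@pytest.fixture(scope="session")
def small_session(small_layout, small_gestures):
    """3 movements x 10 attempts on an 8-channel mini sleeve."""
    schedule = simdata.make_sequential_schedule(SMALL_MOVEMENTS, reps=10, seed=11)
    return orchestrate.simulate_session(
        schedule, small_gestures, small_layout, seed=12, snr=10.0
    )


@pytest.fixture(scope="session")
def big_session():
    """Standard synthetic study conditions: 12 movements, 10 attempts, 20 ch."""
    layout = simdata.SleeveLayout.custom(20)
    gestures = simdata.make_gesture_set(BIG_MOVEMENTS, layout, seed=101)
    schedule = simdata.make_sequential_schedule(BIG_MOVEMENTS, reps=10, seed=101)
    return orchestrate.simulate_session(
        schedule, gestures, layout, seed=102, snr=10.0,
        reaction_model=(500.0, 330.0, 100.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
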