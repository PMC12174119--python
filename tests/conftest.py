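import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import graphomark as gm


@pytest.fixture(scope="session")
def params():
    return gm.default_params()


@pytest.fixture(scope="session")
def mci_session(params):
    return gm.simulate_session(params, "MCI", seed=7)


@pytest.fixture(scope="session")
def hc_session(params):
    return gm.simulate_session(params, "HC", seed=11)


@pytest.fixture
def toy_session():
    """Two strokes: [2, 3] s and [5, 7] s, session start at 0.

    Forced values: J=2, initial pause 2 s, one gap of 2 s, total time 7 s.
    """
    events = [
        (2000, 10.0, 10.0, "down"),
        (2500, 30.0, 10.0, "move"),
        (3000, 50.0, 10.0, "up"),
        (5000, 10.0, 40.0, "down"),
        (6000, 40.0, 40.0, "move"),
        (7000, 70.0, 40.0, "up"),
    ]
    return gm.WritingSession.from_events("toy", events)


@pytest.fixture(scope="session")
def small_cohort(params):
    """One simulated 38/34 cohort with extracted biomarkers."""
    sessions, meta = gm.simulate_cohort(params, 38, 34, seed=20)
    return gm.extract_cohort(sessions, metadata=meta)
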