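"""Shared fixtures: seeded synthetic sessions and their analysis products.

The full study-shaped session (supine control with three 30-s breath-holds,
then head-down tilt with an elevated tidal wave) is generated once per test
run; most downstream tests read from it.
"""

import pandas as pd
import pytest

from rheopulse import preprocess, pulses, synth


@pytest.fixture(scope="session")
def study_scenario() -> synth.Scenario:
    return synth.default_session_scenario(seed=1)


@pytest.fixture(scope="session")
def study_session(study_scenario):
    record, truth = synth.generate_session(study_scenario)
    return record, truth


@pytest.fixture(scope="session")
def smoothed_session(study_session):
    record, truth = study_session
    return preprocess.smooth_running_average(record), truth


@pytest.fixture(scope="session")
def session_timeline(smoothed_session) -> pd.DataFrame:
    smoothed, _ = smoothed_session
    return pulses.feature_timeline(smoothed, "bifrontal")


@pytest.fixture(scope="session")
def sine_pair_record():
    """Bench sine pair: 25 min, middle segment phase-inverted."""
    return synth.generate_sine_pair(
        duration_s=1500.0, inversion_intervals=[(600.0, 1200.0)]
    )
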