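"""Shared fixtures: one noiseless and one realistic synthetic session."""

from __future__ import annotations

import pytest

from vimreach.kinematics import compute_features
from vimreach.rates import unit_rate_function
from vimreach.reaches import DetectionConfig, curate_reaches, detect_reaches
from vimreach.synthetic import (
    MotorParams,
    TaskConfig,
    UnitGroundTruth,
    generate_session,
)

QUIET_MOTOR = MotorParams(
    tremor_amplitude_mm=0.0, noise_sd_mm=0.0, dropped_frame_prob=0.0
)


@pytest.fixture(scope="session")
def quiet_session():
    """Noiseless minimum-jerk session: 8 targets, 24 sequences, 3 units."""
    units = [
        UnitGroundTruth("flat", baseline_rate=20.0),
        UnitGroundTruth("vel", baseline_rate=20.0, coupling={"vx": 5.0, "vy": 3.0},
                        true_lag_s=2 / 120),
        UnitGroundTruth("dir", baseline_rate=20.0, direction_gain=12.0,
                        preferred_direction=(1.0, 0.0, 0.0)),
    ]
    return generate_session(TaskConfig(), QUIET_MOTOR, units, seed=11)


@pytest.fixture(scope="session")
def noisy_session():
    """Realistic session: hold tremor, positional noise, dropped frames."""
    return generate_session(TaskConfig(), MotorParams(), seed=7)


@pytest.fixture(scope="session")
def quiet_features(quiet_session):
    """15 ms-smoothed features (detection / regression grade)."""
    return compute_features(quiet_session.trajectory, 15.0)


@pytest.fixture(scope="session")
def quiet_reaches(quiet_session, quiet_features):
    detected = detect_reaches(
        quiet_features, quiet_session.events, quiet_session.config, DetectionConfig()
    )
    curated, ok = curate_reaches(detected)
    assert ok
    return curated


@pytest.fixture(scope="session")
def noisy_features(noisy_session):
    return compute_features(noisy_session.trajectory, 15.0)


@pytest.fixture(scope="session")
def noisy_reaches(noisy_session, noisy_features):
    detected = detect_reaches(
        noisy_features, noisy_session.events, noisy_session.config, DetectionConfig()
    )
    curated, ok = curate_reaches(detected)
    assert ok
    return curated


@pytest.fixture(scope="session")
def session_span(quiet_session):
    t = quiet_session.trajectory.t
    return float(t[0]), float(t[-1])


@pytest.fixture(scope="session")
def quiet_rate50(quiet_session, session_span):
    """50 ms-smoothed rate of the velocity-coupled unit."""
    return unit_rate_function(
        quiet_session.spikes["vel"], session_span, 50.0, unit_id="vel"
    )
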