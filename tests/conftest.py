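import numpy as np
import pytest

from pelviscreen import (
    AccelTrace,
    DeviceNoise,
    Position,
    PositionCapture,
    SessionRecord,
    simulate_trace,
)

NOISELESS = DeviceNoise(
    accel_white_sd=0.0, sway_amplitude=0.0, sway_freq_hz=0.0,
    knock_prob=0.0, knock_magnitude=0.0,
)


def gravity_trace(pitch_deg: float, duration_s: float = 5.0,
                  sample_rate_hz: float = 200.0, roll_deg: float = 0.0) -> AccelTrace:
    """Pure-gravity constant trace at a known pitch."""
    return simulate_trace(pitch_deg, duration_s, NOISELESS, seed=0,
                          sample_rate_hz=sample_rate_hz, roll_deg=roll_deg)


def make_session(baseline_deg: float, fs_deg: float = None, su_deg: float = None,
                 patient_id: str = "p0", duration_s: float = 5.0) -> SessionRecord:
    """Protocol-ordered noiseless session with the given absolute pitches."""
    captures = []
    if fs_deg is not None:
        captures += [
            PositionCapture(Position.STANDING, gravity_trace(baseline_deg, duration_s)),
            PositionCapture(Position.FLEXED_SEATED, gravity_trace(fs_deg, duration_s)),
        ]
    if su_deg is not None:
        captures += [
            PositionCapture(Position.STANDING, gravity_trace(baseline_deg, duration_s)),
            PositionCapture(Position.STEP_UP, gravity_trace(su_deg, duration_s)),
        ]
    return SessionRecord(patient_id, tuple(captures))


def random_trace(rng: np.random.Generator, duration_s: float = 1.5,
                 sample_rate_hz: float = 200.0) -> AccelTrace:
    """A wobbly but physical trace: gravity under a random smooth pitch path
    plus white noise — used to exercise window selection."""
    n = int(duration_s * sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    pitch = (
        rng.uniform(-45, 45)
        + rng.uniform(0, 10) * np.sin(2 * np.pi * rng.uniform(0.1, 2.0) * t + rng.uniform(0, 7))
    )
    p = np.radians(pitch)
    a_x = -np.sin(p) + rng.normal(0, 0.02, n)
    a_y = rng.normal(0, 0.02, n)
    a_z = np.cos(p) + rng.normal(0, 0.02, n)
    return AccelTrace(t=t, a_x=a_x, a_y=a_y, a_z=a_z, sample_rate_hz=sample_rate_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
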