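"""Gravity-vector inclinometry for static accelerometer captures.

A triaxial accelerometer held still measures only the gravity vector, so the
sensor's orientation in the sagittal plane (pitch) and frontal plane (roll)
can be recovered by trigonometry on the three acceleration channels:

    pitch  theta = atan( -a_x / sqrt(a_y**2 + a_z**2) )
    roll   phi   = atan2( a_y, a_z )

Real captures are contaminated by postural sway, sensor noise and occasional
knocks, so a single tilt estimate is taken from the *most stable* segment of
the capture: the channels are smoothed with a zero-phase moving average, a
per-sample pitch series is computed, and the fixed-length window (default
300 ms, evaluated on a 0.1 s hop grid) with the lowest pitch standard
deviation is selected.  The reported tilt is the mean smoothed pitch over
that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AccelTrace",
    "TiltEstimate",
    "pitch_from_accel",
    "roll_from_accel",
    "smooth_zero_phase",
    "select_stable_window",
]

DEFAULT_SAMPLE_RATE_HZ = 200.0
DEFAULT_WINDOW_S = 0.3
DEFAULT_HOP_S = 0.1
DEFAULT_FILTER_LEN_S = 0.05


@dataclass(frozen=True)
class AccelTrace:
    """One static capture: timestamps plus three acceleration channels in g.

    Axis convention: X sagittal (anterior positive when tilted forward the
    X channel picks up -sin(pitch)), Y frontal, Z completes the right-handed
    triad (gravity along +Z when the sensor is level).
    """

    t: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    a_z: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        for name in ("t", "a_x", "a_y", "a_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 1:
            raise ValueError("AccelTrace requires at least one sample")
        for name in ("a_x", "a_y", "a_z"):
            if getattr(self, name).size != n:
                raise ValueError(
                    f"channel {name!r} has {getattr(self, name).size} samples, "
                    f"timestamps have {n}"
                )
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")
        for name in ("t", "a_x", "a_y", "a_z"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name!r}")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        """Capture duration including the final sample period."""
        return float(len(self) / self.sample_rate_hz)


@dataclass(frozen=True)
class TiltEstimate:
    """Tilt summary of the most stable window of a capture.

    ``window_sd_deg`` is the standard deviation of the smoothed pitch series
    inside the selected window — the stability score that window minimised.
    """

    pitch_deg: float
    roll_deg: float
    window_start_s: float
    window_end_s: float
    window_sd_deg: float


def pitch_from_accel(a_x, a_y, a_z):
    """Pitch (degrees) of a static sensor from its acceleration vector.

    theta = atan(-a_x / sqrt(a_y^2 + a_z^2)); invariant under positive
    scaling of the input, so raw un-normalised readings work too.  Accepts
    scalars or broadcastable arrays.

    Raises
    ------
    ValueError
        If any input vector is exactly zero (no gravity component; the
        orientation is unphysical for a static capture).
    """
    a_x, a_y, a_z = np.asarray(a_x, float), np.asarray(a_y, float), np.asarray(a_z, float)
    norm_yz = np.hypot(a_y, a_z)
    if np.any((norm_yz == 0) & (a_x == 0)):
        raise ValueError("zero acceleration vector: no gravity component to orient against")
    out = np.degrees(np.arctan2(-a_x, norm_yz))
    return float(out) if out.ndim == 0 else out


def roll_from_accel(a_x, a_y, a_z):
    """Roll (degrees) of a static sensor: phi = atan2(a_y, a_z).

    ``a_x`` is accepted for interface symmetry but does not enter the
    formula.  Raises ValueError when a_y = a_z = 0 (roll undefined).
    """
    del a_x
    a_y, a_z = np.asarray(a_y, float), np.asarray(a_z, float)
    if np.any((a_y == 0) & (a_z == 0)):
        raise ValueError("a_y = a_z = 0: roll is undefined")
    out = np.degrees(np.arctan2(a_y, a_z))
    return float(out) if out.ndim == 0 else out


def _filter_samples(filter_len_s: float, sample_rate_hz: float) -> int:
    m = max(1, int(round(filter_len_s * sample_rate_hz)))
    return m


def _zero_phase_ma(x: np.ndarray, m: int) -> np.ndarray:
    """Box moving average applied forward then backward.

    Equivalent to one pass with the symmetric (2m-1)-tap triangular kernel
    box*box; reflect padding keeps the output length equal to the input and
    avoids endpoint transients.
    """
    if m == 1:
        return x.copy()
    if x.size < m:
        raise ValueError(f"trace has {x.size} samples, shorter than the {m}-sample filter")
    kernel = np.convolve(np.full(m, 1.0 / m), np.full(m, 1.0 / m))
    pad = m - 1
    padded = np.pad(x, pad, mode="reflect") if x.size > 1 else np.repeat(x, 2 * pad + 1)
    return np.convolve(padded, kernel, mode="valid")


def smooth_zero_phase(trace: AccelTrace, filter_len_s: float = DEFAULT_FILTER_LEN_S) -> AccelTrace:
    """Smooth each acceleration channel with a zero-phase moving average.

    The box filter runs forward then backward, so the net phase shift is
    zero and a constant channel is returned unchanged.  Output length equals
    input length.
    """
    m = _filter_samples(filter_len_s, trace.sample_rate_hz)
    if len(trace) < m:
        raise ValueError(
            f"trace has {len(trace)} samples, shorter than the {m}-sample filter"
        )
    return AccelTrace(
        t=trace.t,
        a_x=_zero_phase_ma(trace.a_x, m),
        a_y=_zero_phase_ma(trace.a_y, m),
        a_z=_zero_phase_ma(trace.a_z, m),
        sample_rate_hz=trace.sample_rate_hz,
    )


def select_stable_window(
    trace: AccelTrace,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    filter_len_s: float = DEFAULT_FILTER_LEN_S,
) -> TiltEstimate:
    """Tilt estimate from the most stable fixed-length window of a capture.

    The trace is smoothed (zero-phase moving average), a per-sample pitch
    series is computed, and candidate windows of ``window_s`` starting at
    multiples of ``hop_s`` are scored by the standard deviation of pitch
    within the window.  The window with the lowest SD wins; ties go to the
    earliest start.  Returned pitch and roll are means over that window.

    Raises
    ------
    ValueError
        If the trace is shorter than ``window_s``.
    """
    fs = trace.sample_rate_hz
    win_n = max(1, int(round(window_s * fs)))
    hop_n = max(1, int(round(hop_s * fs)))
    if len(trace) < win_n:
        raise ValueError(
            f"trace duration {trace.duration_s:.3f} s is shorter than the "
            f"required window of {window_s:.3f} s"
        )
    smoothed = smooth_zero_phase(trace, filter_len_s)
    pitch = pitch_from_accel(smoothed.a_x, smoothed.a_y, smoothed.a_z)
    roll = roll_from_accel(smoothed.a_x, smoothed.a_y, smoothed.a_z)
    pitch = np.atleast_1d(pitch)
    roll = np.atleast_1d(roll)

    starts = np.arange(0, len(trace) - win_n + 1, hop_n)
    windows = np.lib.stride_tricks.sliding_window_view(pitch, win_n)[starts]
    sds = windows.std(axis=1)
    best = int(starts[np.argmin(sds)])  # argmin returns first minimum: earliest tie wins

    sel = slice(best, best + win_n)
    return TiltEstimate(
        pitch_deg=float(pitch[sel].mean()),
        roll_deg=float(roll[sel].mean()),
        window_start_s=float(trace.t[best]),
        window_end_s=float(trace.t[best] + win_n / fs),
        window_sd_deg=float(pitch[sel].std()),
    )
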