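"""Functional-position screening protocol for pelvic mobility.

A screening session records a patient in three postures — standing,
flexed-seated (FS) and step-up (SU) — with a fresh standing capture taken
before each functional position to serve as its baseline.  Pelvic mobility
is quantified as the change in sagittal tilt (pitch) between a functional
position and its preceding standing baseline; patients whose flexed-seated
change reaches 13 degrees (in either the anterior or posterior direction)
are flagged as having high pelvic mobility and referred for detailed
pre-surgical planning.

Working with tilt *changes* rather than absolute tilt removes the need to
align the sensor axes with the pelvis: any constant mounting offset cancels
in the subtraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .imu_core import (
    DEFAULT_FILTER_LEN_S,
    DEFAULT_HOP_S,
    DEFAULT_WINDOW_S,
    AccelTrace,
    TiltEstimate,
    select_stable_window,
)

__all__ = [
    "Position",
    "PositionCapture",
    "SessionRecord",
    "TiltChangeResult",
    "ScreeningReport",
    "ProtocolError",
    "tilt_change",
    "classify_mobility",
    "screen_session",
    "HIGH_MOBILITY_THRESHOLD_DEG",
    "RECOMMENDED_CAPTURE_S",
]

HIGH_MOBILITY_THRESHOLD_DEG = 13.0
RECOMMENDED_CAPTURE_S = 5.0

FUNCTIONAL_POSITIONS = ("flexed_seated", "step_up")


class Position(str, Enum):
    STANDING = "standing"
    FLEXED_SEATED = "flexed_seated"
    STEP_UP = "step_up"


class ProtocolError(ValueError):
    """The session violates the capture protocol (missing/unordered captures)."""


@dataclass(frozen=True)
class PositionCapture:
    """A labelled capture: posture, its accelerometer trace, and optionally a
    paired reference (radiographic) tilt for validation."""

    position: Position
    trace: AccelTrace
    reference_tilt_deg: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", Position(self.position))
        # one sample period of slack absorbs rate round-off on re-read traces
        if self.trace.duration_s < RECOMMENDED_CAPTURE_S - 1.0 / self.trace.sample_rate_hz:
            warnings.warn(
                f"{self.position.value} capture lasts {self.trace.duration_s:.2f} s; "
                f"captures of at least {RECOMMENDED_CAPTURE_S:.0f} s are recommended",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SessionRecord:
    """Ordered captures for one patient, with optional covariates."""

    patient_id: str
    captures: tuple[PositionCapture, ...]
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "captures", tuple(self.captures))
        for pos in self.functional_positions():
            self._preceding_standing_index(self.captures.index(self._functional_capture(pos)))

    def functional_positions(self) -> tuple[Position, ...]:
        return tuple(c.position for c in self.captures if c.position != Position.STANDING)

    def _functional_capture(self, position: Position) -> PositionCapture:
        for cap in self.captures:
            if cap.position == position:
                return cap
        raise ProtocolError(
            f"session {self.patient_id!r} has no {Position(position).value} capture"
        )

    def _preceding_standing_index(self, idx: int) -> int:
        for j in range(idx - 1, -1, -1):
            if self.captures[j].position == Position.STANDING:
                return j
        raise ProtocolError(
            f"session {self.patient_id!r}: no standing baseline precedes the "
            f"{self.captures[idx].position.value} capture at index {idx}"
        )


@dataclass(frozen=True)
class TiltChangeResult:
    """Signed tilt change of one functional position vs its standing baseline.

    Positive values mean increased anterior pelvic tilt.  ``high_mobility``
    applies the screening threshold to ``delta_pitch_deg``.
    """

    position: Position
    delta_pitch_deg: float
    high_mobility: bool
    baseline_pitch_deg: float
    functional_pitch_deg: float
    baseline_estimate: TiltEstimate
    functional_estimate: TiltEstimate


@dataclass(frozen=True)
class ScreeningReport:
    """Per-position results plus the overall screening decision."""

    patient_id: str
    results: tuple[TiltChangeResult, ...]
    high_mobility: bool
    threshold_deg: float
    fs_only: bool


def classify_mobility(
    delta_pitch_deg: float,
    threshold_deg: float = HIGH_MOBILITY_THRESHOLD_DEG,
    signed: bool = False,
) -> bool:
    """Apply the high-pelvic-mobility rule to a tilt change.

    Default (``signed=False``): high mobility iff |delta| >= threshold —
    movement in either the anterior or posterior direction counts, boundary
    inclusive.  ``signed=True`` flags only delta >= threshold.
    """
    if not math.isfinite(delta_pitch_deg):
        raise ValueError(f"tilt change must be finite, got {delta_pitch_deg}")
    value = delta_pitch_deg if signed else abs(delta_pitch_deg)
    return value >= threshold_deg


def tilt_change(
    session: SessionRecord,
    position: Position,
    threshold_deg: float = HIGH_MOBILITY_THRESHOLD_DEG,
    signed: bool = False,
    invert_pitch_sign: bool = False,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    filter_len_s: float = DEFAULT_FILTER_LEN_S,
) -> TiltChangeResult:
    """Tilt change of ``position`` relative to its nearest preceding standing
    baseline.

    Both captures are reduced to single tilt values by stable-window
    selection; the result is functional minus baseline (positive = more
    anterior tilt).  ``invert_pitch_sign`` flips the device pitch for
    mountings where the sensor X axis points the opposite way.

    Raises
    ------
    ProtocolError
        If the functional capture is missing or no standing capture
        precedes it.
    """
    position = Position(position)
    if position == Position.STANDING:
        raise ProtocolError("standing is the baseline, not a functional position")
    functional = session._functional_capture(position)
    idx = session.captures.index(functional)
    baseline = session.captures[session._preceding_standing_index(idx)]

    sign = -1.0 if invert_pitch_sign else 1.0
    est_base = select_stable_window(baseline.trace, window_s, hop_s, filter_len_s)
    est_func = select_stable_window(functional.trace, window_s, hop_s, filter_len_s)
    base_pitch = sign * est_base.pitch_deg
    func_pitch = sign * est_func.pitch_deg
    delta = func_pitch - base_pitch
    return TiltChangeResult(
        position=position,
        delta_pitch_deg=delta,
        high_mobility=classify_mobility(delta, threshold_deg, signed),
        baseline_pitch_deg=base_pitch,
        functional_pitch_deg=func_pitch,
        baseline_estimate=est_base,
        functional_estimate=est_func,
    )


def screen_session(
    session: SessionRecord,
    threshold_deg: float = HIGH_MOBILITY_THRESHOLD_DEG,
    fs_only: bool = False,
    signed: bool = False,
    invert_pitch_sign: bool = False,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    filter_len_s: float = DEFAULT_FILTER_LEN_S,
) -> ScreeningReport:
    """Screen a whole session: compute the tilt change for every functional
    capture and combine per-position flags into an overall decision.

    The overall flag is an OR over positions (screening favours
    sensitivity); with ``fs_only=True`` the decision rests on the
    flexed-seated change alone, matching the classifier the device was
    validated with, though all positions are still reported.
    """
    results = []
    for pos in session.functional_positions():
        results.append(
            tilt_change(
                session,
                pos,
                threshold_deg=threshold_deg,
                signed=signed,
                invert_pitch_sign=invert_pitch_sign,
                window_s=window_s,
                hop_s=hop_s,
                filter_len_s=filter_len_s,
            )
        )
    if not results:
        raise ProtocolError(f"session {session.patient_id!r} has no functional captures")
    if fs_only:
        decisive = [r for r in results if r.position == Position.FLEXED_SEATED]
        if not decisive:
            raise ProtocolError(
                f"session {session.patient_id!r}: fs_only screening requested but "
                "no flexed_seated capture present"
            )
    else:
        decisive = results
    return ScreeningReport(
        patient_id=session.patient_id,
        results=tuple(results),
        high_mobility=any(r.high_mobility for r in decisive),
        threshold_deg=threshold_deg,
        fs_only=fs_only,
    )
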