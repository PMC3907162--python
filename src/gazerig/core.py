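"""Shared domain types and the three unit-conversion layers.

The rig speaks three unit systems that must be bridged exactly once, here:

* visual angle (degrees) <-> pixels, through the display geometry, using the
  exact tangent mapping (no small-angle approximation) so large
  eccentricities stay correct;
* visual angle (degrees) <-> DAC counts, the integer representation of eye
  position the sequencer's window tests operate on;
* milliseconds <-> sequencer steps, the tick units of the sequencer's
  independent 1-microsecond clock.

Conventions: degrees are signed, right/up positive, origin at straight-ahead
gaze; pixel offsets are measured from screen center; session-log times are
integer microseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class UnitError(ValueError):
    """Raised for conversions outside a converter's valid domain or range."""


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical display description used for degree/pixel conversion.

    Parameters
    ----------
    width_cm, height_cm : float
        Physical size of the display surface in centimeters.
    res_x, res_y : int
        Resolution in pixels.  Pixels may be anisotropic: the cm and px
        aspect ratios need not agree.
    distance_cm : float
        Eye-to-screen distance in centimeters along straight-ahead gaze.
    refresh_hz : float
        Vertical refresh rate in Hz; stimulus onsets quantize to this.
    """

    width_cm: float
    height_cm: float
    res_x: int
    res_y: int
    distance_cm: float
    refresh_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "res_x", "res_y", "distance_cm", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DisplayGeometry.{name} must be strictly positive")
        if self.refresh_hz < 1:
            raise ValueError("DisplayGeometry.refresh_hz must be >= 1")

    @property
    def frame_period_us(self) -> float:
        """Frame period in microseconds (1e6 / refresh_hz)."""
        return 1e6 / self.refresh_hz


@dataclass(frozen=True)
class DacCalibration:
    """Linear map from gaze angle (degrees) to DAC counts.

    counts = round(gain * degrees + offset).  The gain/offset of the eye
    signal is rig-specific and fully configurable; defaults assume a 12-bit
    DAC centered at mid-range with 100 counts per degree.
    """

    gain_x: float = 100.0
    gain_y: float = 100.0
    offset_x: float = 2048.0
    offset_y: float = 2048.0
    range: tuple[int, int] = (0, 4095)

    def __post_init__(self) -> None:
        if self.gain_x == 0 or self.gain_y == 0:
            raise ValueError("DacCalibration gain must be nonzero")
        if self.range[0] >= self.range[1]:
            raise ValueError("DacCalibration range must be (lo, hi) with lo < hi")


@dataclass(frozen=True)
class TimeBase:
    """Sequencer clock description.

    tick_us is the hardware tick (1 us by default); steps_per_ms is the
    conversion rate used when user-facing millisecond durations are loaded
    into the sequencer.  Real sequencers may step slower than the tick, so
    both are configurable.
    """

    tick_us: float = 1.0
    steps_per_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.tick_us <= 0:
            raise ValueError("TimeBase.tick_us must be > 0")
        if self.steps_per_ms <= 0:
            raise ValueError("TimeBase.steps_per_ms must be > 0")


@dataclass(frozen=True)
class GazeSample:
    """One eye-position sample: time in microseconds, position in degrees."""

    t: int
    x: float
    y: float


# ---------------------------------------------------------------------------
# degrees <-> pixels


def deg_to_px(geom: DisplayGeometry, angle_x: float, angle_y: float) -> tuple[float, float]:
    """Convert a gaze/stimulus angle to a pixel offset from screen center.

    Uses the exact tangent projection: offset_cm = distance * tan(angle),
    then scales by the pixel density of each axis.

    Raises
    ------
    UnitError
        If either |angle| >= 90 degrees (behind the projection plane).
    """
    if abs(angle_x) >= 90.0 or abs(angle_y) >= 90.0:
        raise UnitError(f"angle out of projection domain: ({angle_x}, {angle_y}) deg")
    off_x_cm = geom.distance_cm * math.tan(math.radians(angle_x))
    off_y_cm = geom.distance_cm * math.tan(math.radians(angle_y))
    return (off_x_cm * geom.res_x / geom.width_cm, off_y_cm * geom.res_y / geom.height_cm)


def px_to_deg(geom: DisplayGeometry, px_x: float, px_y: float) -> tuple[float, float]:
    """Inverse of :func:`deg_to_px`; round-trips within 1e-9 degrees."""
    off_x_cm = px_x * geom.width_cm / geom.res_x
    off_y_cm = px_y * geom.height_cm / geom.res_y
    return (
        math.degrees(math.atan2(off_x_cm, geom.distance_cm)),
        math.degrees(math.atan2(off_y_cm, geom.distance_cm)),
    )


# ---------------------------------------------------------------------------
# degrees <-> DAC counts


def deg_to_dac(cal: DacCalibration, x: float, y: float) -> tuple[int, int]:
    """Convert gaze angle (degrees) to integer DAC counts.

    Out-of-range results raise rather than clamp: silent clamping would make
    off-screen gaze appear pinned to a window edge and corrupt containment
    tests.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise UnitError(f"non-finite angle: ({x}, {y})")
    cx = round(cal.gain_x * x + cal.offset_x)
    cy = round(cal.gain_y * y + cal.offset_y)
    lo, hi = cal.range
    if not (lo <= cx <= hi and lo <= cy <= hi):
        raise UnitError(f"DAC counts ({cx}, {cy}) outside range {cal.range}")
    return (cx, cy)


def dac_to_deg(cal: DacCalibration, cx: float, cy: float) -> tuple[float, float]:
    """Inverse of :func:`deg_to_dac` up to the half-count quantization."""
    return ((cx - cal.offset_x) / cal.gain_x, (cy - cal.offset_y) / cal.gain_y)


# ---------------------------------------------------------------------------
# milliseconds <-> sequencer steps


def ms_to_steps(tb: TimeBase, dur_ms: float) -> int:
    """Convert a duration in milliseconds to integer sequencer steps."""
    if dur_ms < 0:
        raise UnitError(f"negative duration: {dur_ms} ms")
    return round(dur_ms * tb.steps_per_ms)


def steps_to_ms(tb: TimeBase, steps: int) -> float:
    """Inverse of :func:`ms_to_steps` within one step."""
    return steps / tb.steps_per_ms


def steps_to_us(tb: TimeBase, steps: int) -> int:
    """Duration of `steps` sequencer steps in integer microseconds."""
    return round(steps / tb.steps_per_ms * 1000.0)
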