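"""Real-time behavioral monitor: the three-section fixation state machine.

The sequencer evaluates the eye-position stream sample by sample, in DAC
counts, against a rectangular *forgiveness window* and three timing
criteria loaded at trial start:

* **ACQUIRE** — the subject must bring gaze inside the window within
  ``t_acquire`` of target onset ("Time to get on Target");
* **HOLD** — gaze must then stay inside the window for ``t_initial_fix``
  ("Initial Fixation Time");
* **TEST** — after the test stimulus appears, gaze must move into a second
  window the size of the test image and hold it for ``t_reward_fix``
  ("Fixation Time for Reward").

All three phases succeeding triggers a reward pulse of ``reward_steps``
on the reward line; any failure ends the trial immediately.  After either
outcome the state machine resets completely — trials share no state.

Window edges are inclusive on all four sides (forgiveness semantics: a
sample exactly on the edge counts as fixation).  Missing (NaN) samples
count as outside the window, so a signal dropout can never produce a
reward.  Durations are held in sequencer steps and compared against the
1-kHz sample clock through the session :class:`~gazerig.core.TimeBase`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from gazerig.core import TimeBase, steps_to_us
from gazerig.protocol import TTLPulse


class MonitorError(RuntimeError):
    """Raised when a monitoring phase receives unusable input."""


class Phase(enum.Enum):
    BLACK = "BLACK"  # inter-trial black screen / timeout; gaze position noted, not enforced
    FIX = "FIX"  # fixation target on: acquire + initial hold
    TEST = "TEST"  # test stimulus on: acquire + reward hold


class FixState(enum.Enum):
    SUCCESS = "SUCCESS"
    FAILURE = "FAILURE"


class Outcome(enum.Enum):
    REWARDED = "REWARDED"
    FAIL_ACQUIRE = "FAIL_ACQUIRE"
    FAIL_HOLD = "FAIL_HOLD"
    FAIL_TEST = "FAIL_TEST"


@dataclass(frozen=True)
class Window:
    """Rectangular forgiveness window in DAC counts, edges inclusive."""

    x_lo: int
    x_hi: int
    y_lo: int
    y_hi: int

    def __post_init__(self) -> None:
        if self.x_lo >= self.x_hi or self.y_lo >= self.y_hi:
            raise ValueError("window edges must satisfy lo < hi on both axes")


@dataclass(frozen=True)
class MonitorConfig:
    """The sequencer's loaded per-trial variables.

    Durations are in sequencer steps (already converted from the
    user-facing milliseconds); the window is in DAC counts (already
    converted from degrees).
    """

    window: Window
    t_acquire: int
    t_initial_fix: int
    t_reward_fix: int
    reward_steps: int
    timebase: TimeBase = field(default_factory=TimeBase)

    def __post_init__(self) -> None:
        for name in ("t_acquire", "t_initial_fix", "t_reward_fix", "reward_steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"MonitorConfig.{name} must be >= 0")


@dataclass(frozen=True)
class FixationReport:
    """Outcome of one monitoring phase, stamped at the deciding sample."""

    phase: Phase
    state: FixState
    t_event: int  # microseconds on the session clock


@dataclass(frozen=True)
class TrialResult:
    outcome: Outcome
    transcript: tuple[FixationReport, ...]
    reward_pulse: TTLPulse | None = None

    def __post_init__(self) -> None:
        rewarded = self.outcome is Outcome.REWARDED
        if rewarded != (self.reward_pulse is not None):
            raise ValueError("REWARDED iff reward_pulse present")


def in_window(x: float, y: float, window: Window) -> bool:
    """Containment test in DAC counts; edges inclusive; NaN is outside."""
    return bool(
        window.x_lo <= x <= window.x_hi and window.y_lo <= y <= window.y_hi
    )


def _as_arrays(t_us, x, y):
    t_us = np.asarray(t_us, dtype=np.int64)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_us.size == 0:
        raise MonitorError("empty gaze stream")
    if t_us.shape != x.shape or t_us.shape != y.shape:
        raise MonitorError("gaze stream arrays must share a shape")
    return t_us, x, y


def _inside_mask(x: np.ndarray, y: np.ndarray, window: Window) -> np.ndarray:
    # NaN comparisons are False, so dropouts fall outside automatically.
    return (x >= window.x_lo) & (x <= window.x_hi) & (y >= window.y_lo) & (y <= window.y_hi)


def monitor_acquire(
    t_us, x, y, window: Window, t_acquire_steps: int, t_start: int, tb: TimeBase
) -> FixationReport:
    """Phase-entry check: did gaze reach the window within the deadline?

    SUCCESS is stamped at the first sample time inside the window if that
    time is at most ``t_acquire`` after ``t_start`` (deadline inclusive);
    otherwise FAILURE stamped at the deadline.
    """
    t_us, x, y = _as_arrays(t_us, x, y)
    deadline = t_start + steps_to_us(tb, t_acquire_steps)
    inside = _inside_mask(x, y, window)
    eligible = inside & (t_us >= t_start) & (t_us <= deadline)
    idx = np.flatnonzero(eligible)
    if idx.size:
        return FixationReport(Phase.FIX, FixState.SUCCESS, int(t_us[idx[0]]))
    return FixationReport(Phase.FIX, FixState.FAILURE, int(deadline))


def monitor_hold(
    t_us, x, y, window: Window, duration_steps: int, t_start: int, tb: TimeBase
) -> FixationReport:
    """Maintenance check: FAILURE at the first excursion before the
    duration elapses, else SUCCESS stamped at ``t_start + duration``."""
    t_us, x, y = _as_arrays(t_us, x, y)
    t_end = t_start + steps_to_us(tb, duration_steps)
    outside = ~_inside_mask(x, y, window)
    # samples strictly before t_end govern the hold; the sample at t_end
    # belongs to the next phase
    breaking = outside & (t_us >= t_start) & (t_us < t_end)
    idx = np.flatnonzero(breaking)
    if idx.size:
        return FixationReport(Phase.FIX, FixState.FAILURE, int(t_us[idx[0]]))
    return FixationReport(Phase.FIX, FixState.SUCCESS, int(t_end))


def run_trial(
    t_us,
    x,
    y,
    cfg: MonitorConfig,
    test_window: Window,
    t_fix_on: int = 0,
    t_test_on: int | None = None,
    reward_line: str = "reward.dio0",
) -> TrialResult:
    """Run the full three-phase monitor over one trial's gaze stream.

    Parameters
    ----------
    t_us, x, y
        The gaze stream: sample times (microseconds) and eye position in
        DAC counts.
    cfg
        Loaded window/timing variables for the fixation target.
    test_window
        Forgiveness window for the test stimulus, sized to the image.
    t_fix_on
        Session time of fixation-target onset; ACQUIRE starts here.
    t_test_on
        Session time of test-stimulus onset.  Defaults to the HOLD success
        time (the instant the scenario advances); the closed-loop runner
        passes the frame-quantized onset instead.

    Notes
    -----
    The TEST phase reuses ``t_acquire`` as its own acquisition deadline
    before the ``t_reward_fix`` hold, mirroring the acquire/hold split of
    the fixation phases.  The returned reward pulse (duration
    ``reward_steps``) is present iff all phases succeed.  The function is
    pure: the state machine resets by construction between calls.
    """
    tb = cfg.timebase
    transcript: list[FixationReport] = []

    acq = monitor_acquire(t_us, x, y, cfg.window, cfg.t_acquire, t_fix_on, tb)
    transcript.append(acq)
    if acq.state is FixState.FAILURE:
        return TrialResult(Outcome.FAIL_ACQUIRE, tuple(transcript))

    hold = monitor_hold(t_us, x, y, cfg.window, cfg.t_initial_fix, acq.t_event, tb)
    transcript.append(hold)
    if hold.state is FixState.FAILURE:
        return TrialResult(Outcome.FAIL_HOLD, tuple(transcript))

    test_start = hold.t_event if t_test_on is None else t_test_on
    tacq = monitor_acquire(t_us, x, y, test_window, cfg.t_acquire, test_start, tb)
    tacq = FixationReport(Phase.TEST, tacq.state, tacq.t_event)
    transcript.append(tacq)
    if tacq.state is FixState.FAILURE:
        return TrialResult(Outcome.FAIL_TEST, tuple(transcript))

    thold = monitor_hold(t_us, x, y, test_window, cfg.t_reward_fix, tacq.t_event, tb)
    thold = FixationReport(Phase.TEST, thold.state, thold.t_event)
    transcript.append(thold)
    if thold.state is FixState.FAILURE:
        return TrialResult(Outcome.FAIL_TEST, tuple(transcript))

    pulse = TTLPulse(
        t=thold.t_event,
        line=reward_line,
        duration_ms=max(steps_to_us(tb, cfg.reward_steps) / 1000.0, 1e-3),
    )
    return TrialResult(Outcome.REWARDED, tuple(transcript), reward_pulse=pulse)
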