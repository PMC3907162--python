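"""The session brain: trial planning, the six-case dispatch table, scenarios.

A *scenario* is one of the behavioral tasks built on the sound–image
association family:

1. **ASSOCIATION** — a sound plays while its associated image appears at
   screen center.
2. **LEFT_RIGHT** — the image appears at a user-set eccentricity, side
   drawn uniformly at random each trial.
3. **SINGLE_DISTRACTER** — a green dot holds the center while the target
   image and one distracter appear on opposite sides, sides randomized.
4. **MULTI_DISTRACTER** — target plus several distracters at user-fixed
   positions.
5. **CALIBRATION_WALK** — the fixation dot steps through a configured list
   of positions (one parameterized walk).

During a trial the controller runs a looping do-case keyed on the fixation
state the sequencer reports per phase.  There are exactly three failure
and three success situations; each maps to one presentation command, sent
over the bus and acknowledged before the state is returned to the
sequencer (the lockstep that keeps all three programs aligned):

=====  ==============================  ========================
case   situation                        command
=====  ==============================  ========================
F1     black screen, no target yet      present fixation target
F2     fixation lost / never acquired   present black screen
F3     test fixation failed             present black screen
S1     gaze already at target location  present fixation target
S2     initial fixation complete        present test stimulus
S3     test fixation complete (reward)  reset to black screen
=====  ==============================  ========================

Scenario switching closes and names the current data file and opens a
fresh one, so no trial is ever recorded in two files.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gazerig.protocol import Bus, Token
from gazerig.sequencer import FixState, Phase, TrialResult

BLACK_TOKEN = "blkscrn"
FIXATION_TOKEN = "grendot"


class ConfigError(ValueError):
    """Invalid task or session configuration."""


class TaskKind(enum.Enum):
    ASSOCIATION = "ASSOCIATION"
    LEFT_RIGHT = "LEFT_RIGHT"
    SINGLE_DISTRACTER = "SINGLE_DISTRACTER"
    MULTI_DISTRACTER = "MULTI_DISTRACTER"
    CALIBRATION_WALK = "CALIBRATION_WALK"


@dataclass(frozen=True)
class StimulusPair:
    """One checkbox row of the pairing dialog: a sound and its image."""

    sound: str
    image: str


@dataclass(frozen=True)
class TaskSpec:
    kind: TaskKind
    pairs: tuple[StimulusPair, ...] = ()
    offset_deg: float = 8.0
    distracter_positions: tuple[tuple[float, float], ...] = ()
    walk_positions: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    # the three user-facing timing criteria, milliseconds
    t_acquire_ms: float = 500.0
    t_initial_fix_ms: float = 300.0
    t_reward_fix_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.kind is not TaskKind.CALIBRATION_WALK and not self.pairs:
            raise ConfigError(f"{self.kind.value} task requires at least one stimulus pair")
        if self.kind is TaskKind.MULTI_DISTRACTER and not self.distracter_positions:
            raise ConfigError("MULTI_DISTRACTER requires fixed distracter positions")


class Side(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    CENTER = "CENTER"


@dataclass(frozen=True)
class TrialPlan:
    """Stimuli, positions and randomization outcome for one trial."""

    fixation_token: str
    test_token: str
    target_pos: tuple[float, float]
    side: Side
    pair_index: int = 0
    distracter_tokens: tuple[str, ...] = ()
    distracter_positions: tuple[tuple[float, float], ...] = ()


def _test_token(pair_index: int, n_pairs: int) -> str:
    # the single-pair association scenario keeps the classic word verbatim
    return "SndPICn" if n_pairs == 1 else f"SndPIC{pair_index + 1}"


def plan_trial(task: TaskSpec, rng: np.random.Generator, trial_index: int = 0) -> TrialPlan:
    """Draw one trial's randomization and lay out its stimuli.

    Draw order is fixed and documented for reproducibility: pair identity
    first, then side, then distracter identity.  All draws consume `rng`,
    so a seeded generator makes the whole session reproducible.
    """
    if task.kind is TaskKind.CALIBRATION_WALK:
        pos = task.walk_positions[trial_index % len(task.walk_positions)]
        return TrialPlan(
            fixation_token=FIXATION_TOKEN,
            test_token=FIXATION_TOKEN,
            target_pos=tuple(pos),
            side=Side.CENTER,
        )

    n = len(task.pairs)
    pair_index = int(rng.integers(n)) if n > 1 else 0
    token = _test_token(pair_index, n)

    if task.kind is TaskKind.ASSOCIATION:
        return TrialPlan(FIXATION_TOKEN, token, (0.0, 0.0), Side.CENTER, pair_index)

    if task.kind is TaskKind.LEFT_RIGHT:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        x = -task.offset_deg if side is Side.LEFT else task.offset_deg
        return TrialPlan(FIXATION_TOKEN, token, (x, 0.0), side, pair_index)

    if task.kind is TaskKind.SINGLE_DISTRACTER:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        x = -task.offset_deg if side is Side.LEFT else task.offset_deg
        others = [i for i in range(n) if i != pair_index]
        d_index = int(rng.choice(others)) if others else pair_index
        return TrialPlan(
            FIXATION_TOKEN,
            token,
            (x, 0.0),
            side,
            pair_index,
            distracter_tokens=(f"dist{d_index + 1}",),
            distracter_positions=((-x, 0.0),),  # opposite side of the green dot
        )

    if task.kind is TaskKind.MULTI_DISTRACTER:
        # positions are deliberately fixed in this task: copied verbatim
        others = [i for i in range(n) if i != pair_index] or [pair_index]
        d_tokens = tuple(
            f"dist{int(rng.choice(others)) + 1}" for _ in task.distracter_positions
        )
        return TrialPlan(
            FIXATION_TOKEN,
            token,
            (task.offset_deg, 0.0),
            Side.RIGHT,
            pair_index,
            distracter_tokens=d_tokens,
            distracter_positions=tuple(tuple(p) for p in task.distracter_positions),
        )

    raise ConfigError(f"unhandled task kind {task.kind}")


# ---------------------------------------------------------------------------
# do-case dispatch

# (phase, fixation state) -> command role; exactly the six defined cases
DISPATCH_TABLE: dict[tuple[Phase, FixState], str] = {
    (Phase.BLACK, FixState.FAILURE): "fixation",  # F1: black screen, no target
    (Phase.FIX, FixState.FAILURE): "black",  # F2: fixation never acquired / lost
    (Phase.TEST, FixState.FAILURE): "black",  # F3: test fixation failed
    (Phase.BLACK, FixState.SUCCESS): "fixation",  # S1: gaze at target location, none shown
    (Phase.FIX, FixState.SUCCESS): "test",  # S2: show the test stimulus
    (Phase.TEST, FixState.SUCCESS): "black",  # S3: reset for the refresh period
}


def dispatch_word(phase: Phase, state: FixState, plan: TrialPlan) -> str:
    """Pure lookup from the six-case table to a command token word."""
    try:
        role = DISPATCH_TABLE[(phase, state)]
    except KeyError:
        raise ConfigError(f"undefined dispatch case ({phase}, {state})") from None
    if role == "fixation":
        return plan.fixation_token
    if role == "test":
        return plan.test_token
    return BLACK_TOKEN


class Controller:
    """Bus-attached do-case dispatcher for one endpoint pair."""

    def __init__(self, bus: Bus, endpoint: str = "control", presenter: str = "presenter"):
        self.bus = bus
        self.endpoint = endpoint
        self.presenter = presenter

    def dispatch(self, phase: Phase, state: FixState, plan: TrialPlan) -> Token:
        """Send the command for (phase, state) and block for the reply."""
        word = dispatch_word(phase, state, plan)
        return self.bus.send_command(self.endpoint, self.presenter, Token(word))


# ---------------------------------------------------------------------------
# session state and data-file rollover

TRIAL_CSV_FIELDS = ["trial_id", "outcome", "t_acquire_event", "t_fail", "reward_t"]


@dataclass
class SessionState:
    """Open data file, trial counter, and the persistent parameter set."""

    subject: str
    scenario: str
    out_dir: Path
    window_deg: float = 2.0
    reward_ms: float = 50.0
    trial_counter: int = 0
    timestamp: str = "00000000T000000"
    _file: object = field(default=None, repr=False)
    _writer: object = field(default=None, repr=False)
    closed_files: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self._open_file()

    @property
    def data_file(self) -> Path:
        return self.out_dir / f"{self.subject}_{self.scenario}_{self.timestamp}.csv"

    def _open_file(self) -> None:
        self._file = open(self.data_file, "w", newline="")
        self._writer = csv.writer(self._file)
        self._writer.writerow(TRIAL_CSV_FIELDS)
        self._file.flush()

    def record_trial(self, result: TrialResult) -> None:
        if self._file is None:
            raise ConfigError("session has ended; no open data file")
        acquire = next(
            (r.t_event for r in result.transcript if r.state is FixState.SUCCESS), ""
        )
        fail = next(
            (r.t_event for r in result.transcript if r.state is FixState.FAILURE), ""
        )
        reward = result.reward_pulse.t if result.reward_pulse else ""
        self._writer.writerow(
            [self.trial_counter, result.outcome.value, acquire, fail, reward]
        )
        self._file.flush()
        self.trial_counter += 1

    def _close_file(self) -> None:
        if self._file is not None:
            self._file.flush()
            self._file.close()
            self.closed_files.append(self.data_file)
            self._file = None
            self._writer = None


def switch_scenario(session: SessionState, new_scenario: str, timestamp: str) -> SessionState:
    """Close and keep the current data file; start a fresh one.

    The current file is flushed and closed under its
    ``subject_scenario_timestamp`` name, the trial counter resets, and
    collection continues into the new file — already-written trials are
    never lost or duplicated.
    """
    session._close_file()
    session.scenario = new_scenario
    session.timestamp = timestamp
    session.trial_counter = 0
    session._open_file()
    return session


def quit_session(session: SessionState) -> list[Path]:
    """Save the current data file and end the session; returns all files."""
    session._close_file()
    return list(session.closed_files)
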