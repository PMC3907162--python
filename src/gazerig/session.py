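"""Closed-loop session runner tying controller, sequencer, presenter and rig.

One call to :func:`run_session` plays out a whole experimental session on
the shared microsecond clock:

1. each trial opens on the black screen (the configured timeout/refresh
   period, 2 s by default), after which the controller's do-case issues
   the fixation-target command (F1, or S1 when the simulated gaze already
   rests at the target location);
2. the presenter answers the token, frame-quantizes the onset, replies
   and stamps the TTL; the virtual subject produces a 1-kHz gaze trace;
3. the sequencer monitors acquire / initial hold on the forgiveness
   window in DAC counts; success advances the scenario (S2: test
   stimulus), failure resets it (F2: black screen);
4. the test stimulus is monitored against a window the size of the image;
   full success fires the reward pulse and resets via S3.

Trial outcomes append to the scenario's data file; switching scenarios
mid-session rolls the file over.  Spike trains for the configured neuron
models are generated after the behavioral loop from the accumulated event
times, and everything is multiplexed into a :class:`RigRecording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gazerig.controller import (
    Controller,
    SessionState,
    TaskKind,
    TaskSpec,
    plan_trial,
    switch_scenario,
    quit_session,
)
from gazerig.core import DacCalibration, DisplayGeometry, TimeBase, ms_to_steps
from gazerig.presenter import Presenter, StimulusObject
from gazerig.protocol import Bus, Clock
from gazerig.rigsim import (
    EYE_RATE_HZ,
    Archetype,
    GazeTrace,
    NeuronModel,
    SubjectPolicy,
    generate_spikes,
    generate_gaze,
    von_mises_gain,
)
from gazerig.sequencer import (
    FixState,
    MonitorConfig,
    Outcome,
    Phase,
    TrialResult,
    Window,
    in_window,
    run_trial,
)


@dataclass
class SessionConfig:
    """Everything a reproducible session needs, mirroring the setup dialogs."""

    subject: str = "subj1"
    geometry: DisplayGeometry = field(
        default_factory=lambda: DisplayGeometry(
            width_cm=121.0, height_cm=68.0, res_x=1920, res_y=1080,
            distance_cm=121.92, refresh_hz=60.0,
        )
    )
    calibration: DacCalibration = field(default_factory=DacCalibration)
    timebase: TimeBase = field(default_factory=TimeBase)
    policy: SubjectPolicy = field(default_factory=SubjectPolicy)
    neurons: dict[str, NeuronModel] = field(default_factory=dict)
    window_deg: float = 2.0  # forgiveness-window half-width
    image_size_deg: tuple[float, float] = (8.0, 8.0)  # test image, -> test window
    reward_ms: float = 50.0
    timeout_ms: float = 2000.0  # black-screen refresh between trials
    seed: int = 0
    out_dir: Path = Path("gazerig_out")
    # ordered scenario schedule: (scenario name, task, number of trials)
    schedule: list[tuple[str, TaskSpec, int]] = field(default_factory=list)


@dataclass
class SessionRun:
    """Artifacts of one completed session."""

    bus: Bus
    presenter: Presenter
    trial_results: list[TrialResult]
    data_files: list[Path]
    eye_t_us: np.ndarray
    eye_x_deg: np.ndarray
    eye_y_deg: np.ndarray
    events: list[tuple[int, str]]  # (t_us, label)
    spike_trains: dict[str, np.ndarray]
    truth_saccades: list  # GroundTruthSaccade, absolute session times
    duration_us: int

    def event_times(self, label: str) -> np.ndarray:
        return np.array([t for t, lab in self.events if lab == label], dtype=np.int64)


def _window_around(cal: DacCalibration, center_deg, half_deg_x, half_deg_y) -> Window:
    cx = cal.gain_x * center_deg[0] + cal.offset_x
    cy = cal.gain_y * center_deg[1] + cal.offset_y
    return Window(
        x_lo=round(cx - abs(cal.gain_x) * half_deg_x),
        x_hi=round(cx + abs(cal.gain_x) * half_deg_x),
        y_lo=round(cy - abs(cal.gain_y) * half_deg_y),
        y_hi=round(cy + abs(cal.gain_y) * half_deg_y),
    )


def _deg_to_dac_arrays(cal: DacCalibration, x_deg, y_deg):
    return (
        np.rint(cal.gain_x * np.asarray(x_deg) + cal.offset_x),
        np.rint(cal.gain_y * np.asarray(y_deg) + cal.offset_y),
    )


def _register_task_objects(presenter: Presenter, task: TaskSpec) -> None:
    def ensure(obj: StimulusObject) -> None:
        try:
            presenter.register_object(obj)
        except Exception:
            pass  # already registered by an earlier scenario

    ensure(StimulusObject("greendot", "DOT", size=(0.5, 0.5)))
    ensure(StimulusObject("blkscrn", "BLACK"))
    n = len(task.pairs)
    for i, pair in enumerate(task.pairs):
        word = "SndPICn" if n == 1 else f"SndPIC{i + 1}"
        ensure(StimulusObject(word, "IMAGE_SOUND", image=pair.image, sound=pair.sound))
        ensure(StimulusObject(f"dist{i + 1}", "IMAGE", image=pair.image))


def run_session(config: SessionConfig) -> SessionRun:
    """Run the full closed loop and return its artifacts."""
    if not config.schedule:
        raise ValueError("session schedule is empty")
    rng_plan, rng_gaze, rng_spike = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    ]
    clock = Clock()
    bus = Bus(clock)
    presenter = Presenter(
        config.geometry, bus, aliases={"grendot": "greendot"}
    )
    controller = Controller(bus)
    cal = config.calibration
    tb = config.timebase

    state = SessionState(
        subject=config.subject,
        scenario=config.schedule[0][0],
        out_dir=Path(config.out_dir),
        window_deg=config.window_deg,
        reward_ms=config.reward_ms,
        timestamp="s000",
    )

    trial_results: list[TrialResult] = []
    events: list[tuple[int, str]] = []
    segments: list[tuple[int, np.ndarray, np.ndarray]] = []  # (t0_us, x, y)
    truth_saccades: list = []
    last_gaze_deg: tuple[float, float] | None = None
    timeout_us = int(config.timeout_ms * 1000)

    for scen_idx, (scen_name, task, n_trials) in enumerate(config.schedule):
        if scen_idx > 0:
            state = switch_scenario(state, scen_name, f"s{scen_idx:03d}")
        _register_task_objects(presenter, task)
        fix_window = _window_around(cal, (0.0, 0.0), config.window_deg, config.window_deg)
        cfg = MonitorConfig(
            window=fix_window,
            t_acquire=ms_to_steps(tb, task.t_acquire_ms),
            t_initial_fix=ms_to_steps(tb, task.t_initial_fix_ms),
            t_reward_fix=ms_to_steps(tb, task.t_reward_fix_ms),
            reward_steps=ms_to_steps(tb, config.reward_ms),
            timebase=tb,
        )

        for trial in range(n_trials):
            # phase 1: black screen / timeout; behavior not enforced
            clock.advance(timeout_us)

            # S1 vs F1: is resting gaze already at the target location?
            if last_gaze_deg is not None:
                gx, gy = _deg_to_dac_arrays(cal, [last_gaze_deg[0]], [last_gaze_deg[1]])
                pre_state = (
                    FixState.SUCCESS
                    if in_window(float(gx[0]), float(gy[0]), fix_window)
                    else FixState.FAILURE
                )
            else:
                pre_state = FixState.FAILURE

            plan = plan_trial(task, rng_plan, trial_index=trial)
            fix_pos = plan.target_pos if task.kind is TaskKind.CALIBRATION_WALK else (0.0, 0.0)

            controller.dispatch(Phase.BLACK, pre_state, plan)
            fix_event = presenter.events[-1]
            t_fix_on = fix_event.t_onset
            events.append((t_fix_on, "fixation_on"))

            trace: GazeTrace = generate_gaze(
                fixation_pos=fix_pos,
                target_pos=plan.target_pos,
                policy=config.policy,
                rng=rng_gaze,
                t_acquire_ms=task.t_acquire_ms,
                t_initial_fix_ms=task.t_initial_fix_ms,
                t_reward_fix_ms=task.t_reward_fix_ms,
                distracter_pos=(
                    plan.distracter_positions[0] if plan.distracter_positions else None
                ),
            )
            abs_t = trace.t_us + t_fix_on
            segments.append((t_fix_on, trace.x_deg, trace.y_deg))
            for s in trace.saccades:
                truth_saccades.append(
                    type(s)(s.t_onset + t_fix_on, s.t_offset + t_fix_on, s.amplitude, s.angle)
                )
            last_gaze_deg = (float(trace.x_deg[-1]), float(trace.y_deg[-1]))
            dac_x, dac_y = _deg_to_dac_arrays(cal, trace.x_deg, trace.y_deg)

            test_window = _window_around(
                cal,
                plan.target_pos,
                config.image_size_deg[0] / 2.0,
                config.image_size_deg[1] / 2.0,
            )
            if task.kind is TaskKind.CALIBRATION_WALK:
                test_window = _window_around(
                    cal, fix_pos, config.window_deg, config.window_deg
                )
            fix_window_trial = (
                _window_around(cal, fix_pos, config.window_deg, config.window_deg)
                if task.kind is TaskKind.CALIBRATION_WALK
                else fix_window
            )
            cfg_trial = cfg if fix_window_trial is fix_window else MonitorConfig(
                window=fix_window_trial,
                t_acquire=cfg.t_acquire,
                t_initial_fix=cfg.t_initial_fix,
                t_reward_fix=cfg.t_reward_fix,
                reward_steps=cfg.reward_steps,
                timebase=tb,
            )

            # interactive monitoring: run the full sequencer over the trace,
            # then replay the dispatches at the event times it reports
            result = run_trial(
                abs_t, dac_x, dac_y, cfg_trial, test_window, t_fix_on=t_fix_on
            )

            if result.outcome in (Outcome.FAIL_ACQUIRE, Outcome.FAIL_HOLD):
                clock.advance(max(0, result.transcript[-1].t_event - clock.now()))
                controller.dispatch(Phase.FIX, FixState.FAILURE, plan)
                events.append((presenter.events[-1].t_onset, "black_on"))
            else:
                # initial fixation succeeded: advance and show the test stimulus
                hold_t = result.transcript[1].t_event
                clock.advance(max(0, hold_t - clock.now()))
                controller.dispatch(Phase.FIX, FixState.SUCCESS, plan)
                ev = presenter.events[-1]
                t_test_on = ev.t_onset
                events.append((t_test_on, "test_on"))
                if ev.sound_onset is not None:
                    events.append((ev.sound_onset, "sound_on"))
                # re-monitor the test phase against the actual (frame-
                # quantized) onset the presenter reported
                result = run_trial(
                    abs_t, dac_x, dac_y, cfg_trial, test_window,
                    t_fix_on=t_fix_on, t_test_on=t_test_on,
                )
                clock.advance(max(0, result.transcript[-1].t_event - clock.now()))
                if result.outcome is Outcome.REWARDED:
                    pulse = bus.emit_ttl(
                        "reward.dio0",
                        result.reward_pulse.t,
                        result.reward_pulse.duration_ms,
                        endpoint="sequencer",
                    )
                    events.append((pulse.t, "reward"))
                    controller.dispatch(Phase.TEST, FixState.SUCCESS, plan)
                else:
                    controller.dispatch(Phase.TEST, FixState.FAILURE, plan)
                events.append((presenter.events[-1].t_onset, "black_on"))

            state.record_trial(result)
            trial_results.append(result)
            # let the trial's trace play out before the next timeout begins
            clock.advance(max(0, int(abs_t[-1]) + 1000 - clock.now()))

    data_files = quit_session(state)
    duration_us = clock.now() + timeout_us

    # assemble the session-long 1-kHz eye channels (hold last position in gaps)
    n_samples = duration_us // 1000
    eye_x = np.empty(n_samples)
    eye_y = np.empty(n_samples)
    first = segments[0]
    eye_x[:] = first[1][0]
    eye_y[:] = first[2][0]
    cursor = 0
    for t0_us, xs, ys in segments:
        i0 = t0_us // 1000
        i1 = min(n_samples, i0 + len(xs))
        if i0 > cursor:  # hold the previous segment's last sample
            eye_x[cursor:i0] = eye_x[cursor - 1] if cursor else xs[0]
            eye_y[cursor:i0] = eye_y[cursor - 1] if cursor else ys[0]
        eye_x[i0:i1] = xs[: i1 - i0]
        eye_y[i0:i1] = ys[: i1 - i0]
        cursor = i1
    if cursor < n_samples:
        eye_x[cursor:] = eye_x[cursor - 1]
        eye_y[cursor:] = eye_y[cursor - 1]
    eye_t = np.arange(n_samples, dtype=np.int64) * 1000

    spike_trains = _generate_session_spikes(
        config.neurons, events, truth_saccades, duration_us, rng_spike
    )

    return SessionRun(
        bus=bus,
        presenter=presenter,
        trial_results=trial_results,
        data_files=data_files,
        eye_t_us=eye_t,
        eye_x_deg=eye_x,
        eye_y_deg=eye_y,
        events=events,
        spike_trains=spike_trains,
        truth_saccades=truth_saccades,
        duration_us=duration_us,
    )


_ALIGN_LABEL = {
    Archetype.AUDITORY_ONSET: "sound_on",
    Archetype.FIXATION: "fixation_on",
    Archetype.REWARD_EXPECTATION: "reward",
}


def _generate_session_spikes(
    neurons: dict[str, NeuronModel],
    events: list[tuple[int, str]],
    truth_saccades,
    duration_us: int,
    rng: np.random.Generator,
    tuning: dict[str, tuple[float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """One Poisson train per neuron, aligned per its archetype.

    Buildup–burst units align to ground-truth saccade onsets; `tuning`
    optionally maps a neuron name to (preferred angle deg, kappa) for
    direction-dependent burst gain.
    """
    trains: dict[str, np.ndarray] = {}
    for name, model in neurons.items():
        gains = None
        if model.archetype is Archetype.SC_BUILDUP_BURST:
            align = np.array([s.t_onset for s in truth_saccades], dtype=np.int64)
            if tuning and name in tuning:
                pref, kappa = tuning[name]
                gains = von_mises_gain([s.angle for s in truth_saccades], pref, kappa)
        else:
            label = _ALIGN_LABEL[model.archetype]
            align = np.array([t for t, lab in events if lab == label], dtype=np.int64)
        trains[name] = generate_spikes(model, align, duration_us, rng, event_gains=gains)
    return trains
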