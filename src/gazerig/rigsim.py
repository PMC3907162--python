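"""Virtual rig: seedable gaze traces, spike trains, and session recordings.

Stands in for the behaving subject and the acquisition hardware so the
closed loop runs without a rig.  Three generators:

* **gaze** — a behavior policy (probabilities of acquiring and holding
  fixation, of choosing the target over a distracter; reaction-time
  distribution; fixation jitter) drives a kinematic eye-movement model.
  Saccades follow the oculomotor *main sequence* — duration is an affine
  function of amplitude, ``d(A) = d0 + k*A`` (defaults 20 ms + 2 ms/deg,
  standard primate values) — with a raised-cosine velocity profile.
* **spikes** — inhomogeneous Poisson trains by thinning, with four neuron
  archetypes: an auditory onset responder (sharp response at a fixed
  latency after sound onset), a collicular buildup–burst neuron (slow ramp
  then a burst just before saccade initiation), a fixation neuron
  (sustained response after fixation onset beyond a visual delay), and a
  reward-expectation neuron (activity ramping toward reward delivery).
  Spike times land on the acquisition grid of 0.1 ms.
* **recording** — channels multiplexed the way the acquisition device
  stores them: horizontal/vertical eye position at 1 kHz, one raw neural
  waveform channel at 25 or 50 kHz (spike-triggered template plus Gaussian
  noise, so threshold re-extraction is testable), spike timestamps at
  0.1-ms resolution, and the session event log.

Every generator takes a :class:`numpy.random.Generator`; a fixed seed
reproduces every array bit for bit.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field

import h5py
import numpy as np

EYE_RATE_HZ = 1000  # eye channels
SPIKE_GRID_US = 100  # 0.1 ms timestamp resolution


@dataclass(frozen=True)
class SubjectPolicy:
    """Behavioral dial for the simulated subject.

    p_acquire, p_hold, p_target_choice are the per-trial probabilities of
    acquiring the fixation target in time, of holding fixation through the
    initial period, and of saccading to the target rather than a
    distracter.  Reaction times are normal (mean, SD) in ms, floored at
    50 ms; jitter_deg is the SD of fixational noise.
    """

    p_acquire: float = 1.0
    p_hold: float = 1.0
    p_target_choice: float = 1.0
    reaction_ms: tuple[float, float] = (180.0, 30.0)
    jitter_deg: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_acquire", "p_hold", "p_target_choice"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"SubjectPolicy.{name} must be in [0, 1]")
        if self.reaction_ms[1] < 0 or self.jitter_deg < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class SaccadeModel:
    """Main-sequence kinematics: duration affine in amplitude."""

    d0_ms: float = 20.0
    k_ms_per_deg: float = 2.0

    def duration_ms(self, amplitude_deg: float) -> float:
        return self.d0_ms + self.k_ms_per_deg * amplitude_deg

    @staticmethod
    def profile(u: np.ndarray) -> np.ndarray:
        """Normalized displacement for normalized time u in [0, 1].

        Integral of a raised-cosine velocity profile (symmetric, unimodal,
        minimum-jerk-like): s(u) = u - sin(2*pi*u)/(2*pi).
        """
        return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


@dataclass(frozen=True)
class GroundTruthSaccade:
    t_onset: int  # us
    t_offset: int
    amplitude: float  # deg
    angle: float  # deg, 0 rightward, CCW positive


@dataclass
class GazeTrace:
    """A 1-kHz gaze stream in degrees plus its generation ground truth."""

    t_us: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    saccades: list[GroundTruthSaccade] = field(default_factory=list)
    drew_acquire: bool = True
    drew_hold: bool = True
    drew_target: bool = True


class Archetype(enum.Enum):
    AUDITORY_ONSET = "AUDITORY_ONSET"
    SC_BUILDUP_BURST = "SC_BUILDUP_BURST"
    FIXATION = "FIXATION"
    REWARD_EXPECTATION = "REWARD_EXPECTATION"


@dataclass(frozen=True)
class NeuronModel:
    """Rate-profile parameters for one synthetic unit.

    baseline_hz is the spontaneous rate; response_hz the added rate at the
    peak of the archetype profile; latency_ms the delay from the alignment
    event to response onset (onset/fixation archetypes); buildup_ms the
    ramp duration of the buildup–burst archetype; response_dur_ms the
    width of the driven epoch.
    """

    archetype: Archetype
    baseline_hz: float = 10.0
    response_hz: float = 80.0
    latency_ms: float = 21.0
    buildup_ms: float = 70.0
    response_dur_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.baseline_hz < 0 or self.response_hz < 0:
            raise ValueError("rates must be >= 0")
        if self.latency_ms < 0:
            raise ValueError("latency must be >= 0")


# ---------------------------------------------------------------------------
# gaze generation


def _saccade_segment(
    model: SaccadeModel, start: np.ndarray, end: np.ndarray, n_ms: int
) -> np.ndarray:
    """Positions (n_ms, 2) along a saccade sampled at 1 kHz."""
    u = np.linspace(0.0, 1.0, n_ms, endpoint=True)
    s = SaccadeModel.profile(u)[:, None]
    return start[None, :] + (end[None, :] - start[None, :]) * s


def generate_gaze(
    fixation_pos: tuple[float, float],
    target_pos: tuple[float, float],
    policy: SubjectPolicy,
    rng: np.random.Generator,
    t_acquire_ms: float = 500.0,
    t_initial_fix_ms: float = 300.0,
    t_reward_fix_ms: float = 300.0,
    distracter_pos: tuple[float, float] | None = None,
    saccade_model: SaccadeModel = SaccadeModel(),
    tail_ms: float = 500.0,
) -> GazeTrace:
    """Simulate one trial's gaze at 1 kHz, fixation-target onset at t = 0.

    The subject starts at a random eccentric position.  Per-trial
    Bernoulli draws decide whether it acquires the fixation target within
    the deadline, holds through the initial fixation period, and then
    saccades to the target (vs the distracter, or a mirror position when
    no distracter exists).  Failure draws produce traces that violate
    exactly the corresponding monitoring phase.  Every saccade the
    generator injects is returned as ground truth for detector tests.
    """
    fixation = np.asarray(fixation_pos, dtype=float)
    target = np.asarray(target_pos, dtype=float)
    total_ms = int(
        round(t_acquire_ms + t_initial_fix_ms + t_acquire_ms + t_reward_fix_ms + tail_ms)
    )
    n = total_ms
    t_us = (np.arange(n, dtype=np.int64)) * 1000
    xy = np.empty((n, 2), dtype=float)

    # starting position: eccentric, well clear of any forgiveness window
    ang0 = rng.uniform(0.0, 2.0 * np.pi)
    ecc0 = rng.uniform(9.0, 14.0)
    start = np.array([ecc0 * np.cos(ang0), ecc0 * np.sin(ang0)])
    xy[:] = start  # default: never moves

    saccades: list[GroundTruthSaccade] = []
    drew_acquire = bool(rng.random() < policy.p_acquire)
    drew_hold = bool(rng.random() < policy.p_hold)
    drew_target = bool(rng.random() < policy.p_target_choice)
    reaction1 = max(50.0, rng.normal(*policy.reaction_ms))
    reaction2 = max(50.0, rng.normal(*policy.reaction_ms))

    def add_saccade(t0_ms: int, a: np.ndarray, b: np.ndarray) -> int:
        """Write a saccade starting at t0_ms; returns its end sample."""
        amp = float(np.hypot(*(b - a)))
        dur = max(2, int(round(saccade_model.duration_ms(amp))))
        t1 = min(n, t0_ms + dur)
        if t1 - t0_ms >= 2:
            xy[t0_ms:t1] = _saccade_segment(saccade_model, a, b, t1 - t0_ms)
        xy[t1:] = b
        saccades.append(
            GroundTruthSaccade(
                t_onset=int(t0_ms * 1000),
                t_offset=int(t1 * 1000),
                amplitude=amp,
                angle=float(np.degrees(np.arctan2(b[1] - a[1], b[0] - a[0]))),
            )
        )
        return t1

    if not drew_acquire:
        _apply_jitter(xy, policy.jitter_deg, rng, from_ms=0)
        return GazeTrace(t_us, xy[:, 0], xy[:, 1], saccades, drew_acquire, drew_hold, drew_target)

    # cap the reaction so the acquisition saccade always beats the deadline
    amp1 = float(np.hypot(*(fixation - start)))
    dur1 = saccade_model.duration_ms(amp1)
    reaction1 = min(reaction1, max(50.0, t_acquire_ms - dur1 - 30.0))
    t_arrive = add_saccade(int(round(reaction1)), start, fixation)

    if not drew_hold:
        # break fixation partway through the initial hold
        frac = rng.uniform(0.25, 0.75)
        t_break = t_arrive + int(round(frac * t_initial_fix_ms))
        away = start if np.hypot(*(start - fixation)) > 4.0 else fixation + np.array([10.0, 0.0])
        add_saccade(min(t_break, n - 3), fixation.copy(), away)
        _apply_jitter(xy, policy.jitter_deg, rng, from_ms=0)
        return GazeTrace(t_us, xy[:, 0], xy[:, 1], saccades, drew_acquire, drew_hold, drew_target)

    # test-stimulus onset: the scenario advances when the hold completes
    t_test_on = t_arrive + int(round(t_initial_fix_ms))
    if drew_target:
        goal = target
    elif distracter_pos is not None:
        goal = np.asarray(distracter_pos, dtype=float)
    else:
        goal = -target if np.any(target) else np.array([8.0, 0.0])
    amp2 = float(np.hypot(*(goal - fixation)))
    if amp2 > 0.5:
        dur2 = saccade_model.duration_ms(amp2)
        reaction2 = min(reaction2, max(50.0, t_acquire_ms - dur2 - 30.0))
        add_saccade(min(t_test_on + int(round(reaction2)), n - 3), fixation.copy(), goal)
    _apply_jitter(xy, policy.jitter_deg, rng, from_ms=0)
    return GazeTrace(t_us, xy[:, 0], xy[:, 1], saccades, drew_acquire, drew_hold, drew_target)


def _apply_jitter(xy: np.ndarray, sd: float, rng: np.random.Generator, from_ms: int) -> None:
    if sd > 0:
        xy[from_ms:] += rng.normal(0.0, sd, size=xy[from_ms:].shape)


# ---------------------------------------------------------------------------
# spike generation


def rate_profile(
    model: NeuronModel, t_us: np.ndarray, events_us: np.ndarray, gains: np.ndarray | None = None
) -> np.ndarray:
    """Instantaneous firing rate (Hz) at times t_us given alignment events."""
    t = np.asarray(t_us, dtype=float) / 1000.0  # ms
    ev = np.asarray(events_us, dtype=float) / 1000.0
    rate = np.full(t.shape, model.baseline_hz, dtype=float)
    if gains is None:
        gains = np.ones(ev.shape)
    for e, g in zip(ev, gains):
        if model.archetype is Archetype.AUDITORY_ONSET:
            on, off = e + model.latency_ms, e + model.latency_ms + model.response_dur_ms
            rate += g * model.response_hz * ((t >= on) & (t < off))
        elif model.archetype is Archetype.SC_BUILDUP_BURST:
            # slow ramp ending at the burst, burst just prior to saccade onset e
            burst_on = e - model.response_dur_ms
            ramp_on = burst_on - model.buildup_ms
            ramp = (t - ramp_on) / model.buildup_ms
            in_ramp = (t >= ramp_on) & (t < burst_on)
            rate += g * 0.4 * model.response_hz * np.clip(ramp, 0.0, 1.0) * in_ramp
            rate += g * model.response_hz * ((t >= burst_on) & (t < e))
        elif model.archetype is Archetype.FIXATION:
            on = e + model.latency_ms
            off = on + max(model.response_dur_ms, 300.0)
            rate += g * model.response_hz * ((t >= on) & (t < off))
        elif model.archetype is Archetype.REWARD_EXPECTATION:
            ramp_on = e - model.buildup_ms * 10.0
            ramp = (t - ramp_on) / (e - ramp_on)
            rate += g * model.response_hz * np.clip(ramp, 0.0, 1.0) * (t < e)
    return rate


def generate_spikes(
    model: NeuronModel,
    events_us,
    duration_us: int,
    rng: np.random.Generator,
    event_gains=None,
) -> np.ndarray:
    """Inhomogeneous Poisson spike train by thinning.

    Candidate spikes are drawn homogeneously at the profile's ceiling rate
    and accepted with probability rate(t)/ceiling.  Accepted times are
    rounded to the 0.1-ms acquisition grid and deduplicated, so the
    returned int64 microsecond timestamps are strictly increasing.
    """
    events_us = np.asarray(events_us, dtype=np.int64)
    gains = None if event_gains is None else np.asarray(event_gains, dtype=float)
    gmax = 1.0 if gains is None or gains.size == 0 else max(float(np.max(gains)), 1.0)
    ceiling = model.baseline_hz + model.response_hz * gmax
    if ceiling <= 0 or duration_us <= 0:
        return np.empty(0, dtype=np.int64)
    n_cand = rng.poisson(ceiling * duration_us / 1e6)
    t_cand = np.sort(rng.uniform(0.0, duration_us, size=n_cand))
    accept = rng.uniform(0.0, ceiling, size=n_cand) < rate_profile(
        model, t_cand, events_us, gains
    )
    t_keep = t_cand[accept]
    grid = np.unique((np.round(t_keep / SPIKE_GRID_US)).astype(np.int64) * SPIKE_GRID_US)
    return grid[(grid >= 0) & (grid < duration_us)]


def von_mises_gain(angles_deg, preferred_deg: float, kappa: float = 2.0) -> np.ndarray:
    """Directional tuning gain in (0, 1], peaking at the preferred angle."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.exp(kappa * (np.cos(a - np.radians(preferred_deg)) - 1.0))


# ---------------------------------------------------------------------------
# session recording


@dataclass
class RigRecording:
    """Multichannel session record mirroring the acquisition layout."""

    eye_x: np.ndarray  # degrees, 1 kHz
    eye_y: np.ndarray
    eye_rate_hz: int
    neural: np.ndarray  # raw waveform
    neural_rate_hz: int
    spike_times_us: np.ndarray  # int64, 0.1 ms grid
    events: list[tuple[int, str]]  # (t_us, label)

    def duration_us(self) -> int:
        return int(len(self.eye_x) / self.eye_rate_hz * 1e6)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.eye_x, self.eye_y, self.neural, self.spike_times_us):
            h.update(np.ascontiguousarray(arr).tobytes())
        for t, label in self.events:
            h.update(f"{t}:{label};".encode())
        return h.hexdigest()

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name, arr, rate in (
                ("eye_x", self.eye_x, self.eye_rate_hz),
                ("eye_y", self.eye_y, self.eye_rate_hz),
                ("neural", self.neural, self.neural_rate_hz),
            ):
                ds = f.create_dataset(name, data=arr)
                ds.attrs["rate_hz"] = rate
            f.create_dataset("spike_times_us", data=self.spike_times_us)
            f.create_dataset("event_t_us", data=np.array([t for t, _ in self.events], dtype=np.int64))
            f.create_dataset(
                "event_label",
                data=np.array([label for _, label in self.events], dtype=h5py.string_dtype()),
            )

    @classmethod
    def load(cls, path) -> "RigRecording":
        with h5py.File(path, "r") as f:
            events = [
                (int(t), label.decode() if isinstance(label, bytes) else str(label))
                for t, label in zip(f["event_t_us"][...], f["event_label"][...])
            ]
            return cls(
                eye_x=f["eye_x"][...],
                eye_y=f["eye_y"][...],
                eye_rate_hz=int(f["eye_x"].attrs["rate_hz"]),
                neural=f["neural"][...],
                neural_rate_hz=int(f["neural"].attrs["rate_hz"]),
                spike_times_us=f["spike_times_us"][...],
                events=events,
            )


def spike_template(rate_hz: int) -> np.ndarray:
    """Biphasic ~1.2-ms action-potential template at the waveform rate."""
    n = max(8, int(round(1.2e-3 * rate_hz)))
    t = np.linspace(0.0, 1.0, n)
    w = np.sin(2.0 * np.pi * t) * np.exp(-3.0 * t)
    return w / np.abs(w).max()  # unit peak


def record_session(
    eye_x: np.ndarray,
    eye_y: np.ndarray,
    spike_times_us: np.ndarray,
    events: list[tuple[int, str]],
    rng: np.random.Generator,
    neural_rate_hz: int = 25000,
    snr: float = 10.0,
) -> RigRecording:
    """Assemble a full recording, synthesizing the raw waveform channel.

    The waveform is the spike template stamped at each timestamp plus unit
    Gaussian noise scaled by 1/snr, so spikes can be re-extracted by
    threshold and compared with the generator's timestamps.
    """
    duration_us = int(len(eye_x) / EYE_RATE_HZ * 1e6)
    n_wave = int(round(duration_us / 1e6 * neural_rate_hz))
    wave = rng.normal(0.0, 1.0 / snr, size=n_wave)
    tmpl = spike_template(neural_rate_hz)
    for t in np.asarray(spike_times_us, dtype=np.int64):
        i = int(t / 1e6 * neural_rate_hz)
        j = min(n_wave, i + len(tmpl))
        if i < n_wave:
            wave[i:j] += tmpl[: j - i]
    return RigRecording(
        eye_x=np.asarray(eye_x, dtype=float),
        eye_y=np.asarray(eye_y, dtype=float),
        eye_rate_hz=EYE_RATE_HZ,
        neural=wave,
        neural_rate_hz=neural_rate_hz,
        spike_times_us=np.asarray(spike_times_us, dtype=np.int64),
        events=list(events),
    )


def extract_spikes_by_threshold(
    recording: RigRecording, threshold: float = 0.5, refractory_ms: float = 1.0
) -> np.ndarray:
    """Re-derive spike timestamps from the raw channel by level crossing.

    Returns microsecond times of upward threshold crossings separated by
    at least the refractory period — the software analogue of the
    acquisition device's adjustable on-the-fly threshold.
    """
    wave = recording.neural
    above = wave >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        return np.empty(0, dtype=np.int64)
    t = crossings / recording.neural_rate_hz * 1e6
    keep = [t[0]]
    refr_us = refractory_ms * 1000.0
    for ti in t[1:]:
        if ti - keep[-1] >= refr_us:
            keep.append(ti)
    return np.asarray(np.round(keep), dtype=np.int64)
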