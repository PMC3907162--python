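# Methods

## What the engine models

`gazerig` reproduces, entirely in software, the control architecture of a
classic gaze-contingent neurophysiology rig built from three cooperating
programs:

* a **sequencer** running on the acquisition device's own clock (1 µs
  ticks), monitoring eye position sample by sample against a rectangular
  *forgiveness window* expressed in DAC counts, and issuing the reward
  pulse;
* a **control** program running the session logic: trial planning for the
  sound–image association task family, and a looping *do-case* that maps
  the fixation state reported by the sequencer to the next presentation
  command;
* a **presenter** answering newline-terminated serial command words
  (`grendot\n`, `SndPICn\n`, …) by updating the display, replying on the
  serial path and stamping a 1-ms TTL pulse on parallel bit 8 at the
  moment the stimulus appears.

The triad advances in lockstep: one command, one reply, one TTL per
stimulus change. A fourth component, the **virtual rig**, replaces the
behaving subject and the amplifier chain with seedable generators so the
closed loop runs deterministically and its guarantees can be tested.

## Trial structure and monitoring semantics

A trial has three phases: a black-screen timeout (2000 ms default, not
monitored), fixation of a central target, and fixation of a test
stimulus. Fixation monitoring splits each monitored phase into *acquire*
(gaze must enter the window within "Time to get on Target") and *hold*
(gaze must stay inside for "Initial Fixation Time" / "Fixation Time for
Reward"). The test phase reuses the acquire deadline before its hold —
the text describing the original system specifies only "fixation for the
user-defined time" there, so the acquire/hold split mirrors the fixation
phase; the deadline is an ordinary `MonitorConfig` field and can be set
to taste.

Decisions that needed making:

* **Window edges are inclusive** on all four sides. Forgiveness
  semantics: a sample exactly on the edge counts as fixation, and the
  degenerate zero-margin window still contains its center.
* **Acquire deadline inclusive, hold end exclusive.** Success of a hold
  is stamped at exactly `start + duration`; the sample at that instant
  belongs to the next phase.
* **NaN eye samples count as outside** every window. Fail-safe: signal
  dropout can interrupt a hold but can never produce a reward.
* The monitor is evaluated at the eye-channel rate (1 kHz), every
  sample, no decimation. A failure-by-timeout is stamped at the deadline
  itself even when no sample falls exactly there.
* No grace period for leaving and re-entering the window during a hold;
  the first outside sample ends the phase.

An independent sample-by-sample replay simulator (a deliberately naive
per-sample loop kept in the test suite) checks the vectorized monitor:
outcomes and event times must agree exactly on randomized
piecewise-constant traces.

## Units and conversions

Three exact conversion layers, configured once per session: degrees ↔
pixels through the display geometry (exact tangent projection, no
small-angle approximation, so a 45° eccentricity at a matched viewing
distance maps to exactly one viewing-distance of screen); degrees ↔ DAC
counts through a linear calibration (default 100 counts/°, offset 2048 —
mid-range of a 12-bit converter; the hardware scaling of real eye-coil
signals varies by rig and is fully configurable); milliseconds ↔
sequencer steps (default 1000 steps/ms matching the 1-µs tick).
Out-of-range DAC conversions raise instead of clamping — a clamped
off-screen sample would masquerade as gaze pinned to a window edge and
corrupt containment tests.

## Presentation timing

Visual onsets quantize to the vertical refresh: boundaries at
`k·10⁶/refresh_hz` µs, a request lands on the next boundary. At 60 Hz
the worst-case onset error is one truncated frame period, 16 ms. Sound
is modeled as unquantized (starts at the request, plus an optional fixed
audio latency, default 0), so the audiovisual onset offset of a combined
image+sound stimulus is bounded by one frame period; `audit_av_sync`
reports it per event. TTL pulses are stamped at the frame boundary
(`t_onset`), i.e. at presentation time, not at command receipt; the
alternative stamp would differ by less than one frame.

## The virtual subject

`SubjectPolicy` holds three per-trial Bernoulli probabilities —
acquiring the target in time, holding the initial fixation, choosing the
target over a distracter — plus a normal reaction-time distribution
(mean 180 ms, SD 30 ms, floored at 50 ms) and Gaussian fixational
jitter (SD 0.1° default). The trace generator draws the trial's fate
first, then lays down a trajectory that satisfies or violates exactly
the corresponding monitoring phase: a failure to acquire leaves gaze at
its eccentric starting point; a hold failure breaks fixation at a
uniform 25–75% of the hold period; a distracter choice saccades to the
distracter position at test onset. With probabilities (0.8, 0.9, 1.0)
the rewarded fraction is their product, 0.72 — the closed loop recovers
this within binomial error over 400 trials.

Saccades follow the oculomotor main sequence, duration = 20 ms +
2 ms/° · amplitude (standard primate values, configurable), with a
raised-cosine velocity profile (minimum-jerk-like; the literature the
rig emulates does not prescribe one). Every injected saccade is kept as
ground truth so detector tests never depend on the detector itself.

What the generator does **not** emulate: drift and microsaccades during
fixation (jitter is white), blinks and lid artifacts, saccadic
curvature/overshoot, vergence and torsion, reaction-time dependence on
stimulus eccentricity, and any learning across trials. Passing tests
therefore certify the control and analysis logic, not robustness to
every artifact of real oculomotor data.

## Synthetic neurons

Spike trains are inhomogeneous Poisson by thinning, timestamps on the
0.1-ms acquisition grid. Four archetypes cover the response classes the
rig is used to study: an auditory **onset** responder (response stepping
up a fixed latency, ~21 ms, after sound onset), a collicular
**buildup–burst** unit (a slow ~70-ms ramp ending in a burst just before
saccade initiation, optionally direction-tuned by a von Mises gain), a
**fixation** unit (sustained elevation beyond a >20 ms visual delay
after fixation onset), and a **reward-expectation** unit (rate ramping
toward reward delivery). The raw waveform channel is synthesized as a
unit-peak biphasic template stamped at each spike plus Gaussian noise
(1/SNR), so threshold re-extraction can be validated against the
generator's own timestamps (≥99% recovery at SNR 10).

## Analysis choices

* **Saccade detection**: radial speed from a Savitzky–Golay quadratic
  derivative over a 25-ms window, boxcar-smoothed, thresholded at
  30 °/s; events shorter than 6 ms or smaller than 0.5° are discarded.
  A plain finite difference at 1 kHz with 0.3° jitter carries tens of
  °/s of velocity noise; polynomial differentiation keeps the noise
  floor near 10 °/s so the conventional 30 °/s threshold works.
  Amplitude and direction are measured between median positions shortly
  before onset and after offset.
* **PSTH**: fixed 10-ms bins; counts conserve the aligned spike total
  exactly; rate = counts / (trials · bin width).
* **Spike density**: per-trial delta trains convolved with a unit-area
  Gaussian (SD 10 ms, matching the PSTH bin scale), averaged, in
  spikes/s, on a grid padded by 8 SD so the waveform's integral equals
  the mean per-trial count to numerical precision.
* **First-peak latency**: criterion = baseline mean + 3 baseline SD
  (the conventional rule); the first post-event supra-criterion bin is
  refined below bin width by rising-edge occupancy — the bin's excess
  rate relative to the following plateau estimates the fraction of the
  bin the response occupied. This is exact for step-like onsets (a peak
  -locating parabolic fit was measurably biased for onset estimation)
  and recovers 15–30 ms latencies with a mean absolute error well under
  half a bin.
* **Preferred saccade vector**: per-saccade firing rate in a burst
  window around saccade onset, binned over (amplitude, 45° direction
  sectors); the preferred direction/amplitude is the rate-weighted
  circular mean of the saccades inside the supra-median bins (finer
  than using bin centers). Reliability is the resultant length over
  *all* occupied bins — computing it over the supra-median subset alone
  would inflate it for untuned units; below 0.1 the direction is
  flagged unreliable. Requires ≥20 saccades spanning ≥90° of directions
  (span = 360° minus the largest empty angular gap).

## Problem sizes and statistical power

Validation experiments use sizes a single recording session would
yield: 500 random traces for the oracle equivalence, 200-trial sessions
for protocol checks, 400 trials for behavioral statistics, 40 repeats
per PSTH, 10 onset units for latency recovery, and 300 saccades for
preferred-vector recovery. The saccade count is a power choice: with
broad (von Mises κ = 2) tuning and a ~100 Hz burst, the direction
estimator's sampling error is ~2–3° at n = 300, comfortably inside the
10° recovery tolerance, whereas n ≈ 100 leaves the estimate
tolerance-limited. Sessions of a few hundred trials run in about a
second, so none of these sizes stress a laptop.

## Known limitations

* The serial/parallel transport is an in-memory queue; real COM-port
  framing, baud limits and byte loss are out of scope (the transport
  interface is a stub for hardware backends).
* Scenario switching and data-file rollover are modeled at the
  file-system level (CSV per scenario + HDF5 recording); there is no
  GUI, and the original dialog cascade is replaced by a declarative
  YAML config.
* The walk-task family is reduced to a single parameterized calibration
  walk.
* No spike sorting or template matching: the analysis starts from
  timestamps (threshold re-extraction is provided only as a
  consistency check on the synthesized waveform channel).
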