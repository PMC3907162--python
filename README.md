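# gazerig

A hardware-free, fully testable engine for **gaze-contingent behavioral
experiments** of the kind used in primate auditory/oculomotor
neurophysiology, together with the event-aligned spike analysis that goes
with them.

Laboratories classically build these rigs from three cooperating
programs: a real-time *sequencer* on the acquisition device that watches
eye position against a rectangular "forgiveness" window and delivers the
reward; a *control* script that plans trials and maps each fixation
success/failure to the next stimulus command through a six-case do-case
table; and a *presentation* program that answers newline-terminated
command tokens (`grendot\n`, `SndPICn\n`, …) by drawing the stimulus,
replying on the serial line and stamping a 1-ms TTL pulse on the parallel
port so neural data can be aligned to true stimulus onsets. `gazerig`
re-implements that triad as a deterministic closed loop against a
simulated subject, so the whole control architecture — token protocol,
frame-quantized onsets, three-phase fixation monitoring, reward logic,
scenario switching with data-file rollover — runs and is verifiable
without any hardware.

The package is aimed at experimenters who want to prototype and regression
-test task logic before (or instead of) deploying it on a rig, and at
anyone needing a seedable generator of realistic gaze traces, spike
trains and multichannel session recordings for testing analysis code.

## What's in the box

| module | role |
| --- | --- |
| `gazerig.core` | unit systems: degrees ↔ pixels (exact tangent projection), degrees ↔ DAC counts, milliseconds ↔ sequencer steps |
| `gazerig.protocol` | token (word + terminator) and TTL message fabric, lockstep handshake, replayable bus log |
| `gazerig.sequencer` | the three-phase fixation monitor: acquire / hold / test against forgiveness windows, reward pulse, per-trial reset |
| `gazerig.controller` | trial planning for the association-task family, the 3-failure + 3-success dispatch table, scenario switching |
| `gazerig.presenter` | stimulus-object registry, command loop, frame quantization (16 ms worst-case onset error at 60 Hz), AV-sync audit |
| `gazerig.rigsim` | the virtual rig: behavior policies, main-sequence saccade kinematics, four Poisson neuron archetypes, multichannel recordings |
| `gazerig.analysis` | saccade detection, rasters, PSTHs (10-ms bins), spike-density functions, first-peak latency, preferred saccade vector |
| `gazerig.cli` / `gazerig.config` / `gazerig.fixtures` | `gazerig run\|analyze\|fixtures`, YAML session configs, placeholder PNG/WAV assets |

Key quantities, in the field's notation: the monitor checks
`x_lo ≤ x ≤ x_hi ∧ y_lo ≤ y ≤ y_hi` per 1-kHz sample against the three
timing criteria (*time to get on target*, *initial fixation time*,
*fixation time for reward*); saccade durations follow the main sequence
`d(A) = d0 + k·A` (defaults 20 ms + 2 ms/°); spike trains are
inhomogeneous Poisson with rate `λ(t) = λ₀ + r·profile(t − t_event)`;
the PSTH rate is `counts / (n_trials · Δt)` with Δt = 10 ms; first-peak
latency is the first post-event bin exceeding `baseline mean + 3 SD`,
refined below bin width; the preferred saccade vector is the
rate-weighted circular mean of burst-window firing over (amplitude,
direction) bins.

## Worked example

```bash
gazerig fixtures --out demo            # placeholder assets + example config
gazerig run --config demo/example_config.yaml --out demo/out
# -> completed 20 trials (18 rewarded); artifacts in demo/out
gazerig analyze --recording demo/out/recording.h5 --align sound_on --out demo/an
# -> 18 events aligned on 'sound_on'; tables in demo/an
```

The run executes 20 association trials (seed 42) against a subject that
acquires fixation with probability 0.9 and holds it with probability 0.9:
18 of 20 trials end rewarded, matching the 0.81 expected success rate.
`demo/out` contains the bus log (`buslog.jsonl`, one record per token or
TTL pulse), the multichannel recording (`recording.h5`: eye channels at
1 kHz, a raw neural waveform at 25 kHz, spike timestamps at 0.1 ms), the
per-scenario trial CSV, and a `manifest.json` whose seed and hashes
reproduce the run exactly. The analyze step aligns the simulated
auditory-onset neuron on the 18 sound onsets: `psth.csv` holds the 10-ms
-bin histogram (rates near the 10 Hz baseline before onset, stepping up
~21 ms after it), `raster.csv` the per-trial spike times, and
`spike_density.csv` the Gaussian-smoothed rate waveform.

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.

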