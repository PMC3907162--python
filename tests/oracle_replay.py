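"""Independent sample-by-sample replay simulator for the trial monitor.

Deliberately written as a naive per-sample Python loop with explicit
state, sharing no code with the vectorized sequencer implementation, so
the two can cross-check each other on random traces.
"""

from __future__ import annotations

import math


def _contains(win, x, y):
    if math.isnan(x) or math.isnan(y):
        return False
    return win.x_lo <= x <= win.x_hi and win.y_lo <= y <= win.y_hi


def _steps_us(tb, steps):
    return round(steps / tb.steps_per_ms * 1000.0)


def replay_acquire(samples, window, deadline_us, t_start):
    """(state, t_event): first in-window sample time vs deadline."""
    for t, x, y in samples:
        if t < t_start or t > deadline_us:
            continue
        if _contains(window, x, y):
            return "SUCCESS", t
    return "FAILURE", deadline_us


def replay_hold(samples, window, t_start, t_end):
    for t, x, y in samples:
        if t_start <= t < t_end and not _contains(window, x, y):
            return "FAILURE", t
    return "SUCCESS", t_end


def replay_trial(t_us, x, y, cfg, test_window, t_fix_on=0, t_test_on=None):
    """Full three-phase replay; returns (outcome, [event times])."""
    samples = list(zip([int(v) for v in t_us], list(x), list(y)))
    tb = cfg.timebase
    times = []

    state, t_acq = replay_acquire(
        samples, cfg.window, t_fix_on + _steps_us(tb, cfg.t_acquire), t_fix_on
    )
    times.append(t_acq)
    if state == "FAILURE":
        return "FAIL_ACQUIRE", times

    state, t_hold = replay_hold(
        samples, cfg.window, t_acq, t_acq + _steps_us(tb, cfg.t_initial_fix)
    )
    times.append(t_hold)
    if state == "FAILURE":
        return "FAIL_HOLD", times

    start = t_hold if t_test_on is None else t_test_on
    state, t_tacq = replay_acquire(
        samples, test_window, start + _steps_us(tb, cfg.t_acquire), start
    )
    times.append(t_tacq)
    if state == "FAILURE":
        return "FAIL_TEST", times

    state, t_thold = replay_hold(
        samples, test_window, t_tacq, t_tacq + _steps_us(tb, cfg.t_reward_fix)
    )
    times.append(t_thold)
    if state == "FAILURE":
        return "FAIL_TEST", times
    return "REWARDED", times
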