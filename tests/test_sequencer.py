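import numpy as np
import pytest

from conftest import random_trace
from oracle_replay import replay_trial

from gazerig.sequencer import (
    FixState,
    MonitorError,
    Outcome,
    Window,
    in_window,
    monitor_acquire,
    monitor_hold,
    run_trial,
)

CENTER = 2048


def trace_ms(*segments):
    """Build (t_us, x, y) from (duration_ms, x, y) segments."""
    xs, ys = [], []
    for dur, x, y in segments:
        xs += [x] * dur
        ys += [y] * dur
    t = np.arange(len(xs), dtype=np.int64) * 1000
    return t, np.array(xs, float), np.array(ys, float)


class TestInWindow:
    def setup_method(self):
        self.win = Window(1848, 2248, 1848, 2248)

    def test_center_inside(self):
        assert in_window(2048, 2048, self.win)

    @pytest.mark.parametrize("x,y", [(2248, 2048), (1848, 2048), (2048, 2248), (2048, 1848)])
    def test_edges_inclusive(self, x, y):
        assert in_window(x, y, self.win)

    @pytest.mark.parametrize("x,y", [(2249, 2048), (1847, 2048), (2048, 2249)])
    def test_one_count_outside(self, x, y):
        assert not in_window(x, y, self.win)

    def test_nan_counts_as_outside(self):
        assert not in_window(float("nan"), 2048, self.win)

    def test_degenerate_edges_rejected(self):
        with pytest.raises(ValueError):
            Window(2048, 2048, 1848, 2248)


class TestAcquire:
    def test_success_at_first_in_window_sample(self, monitor_cfg, tb):
        t, x, y = trace_ms((150, 3000, 3000), (600, CENTER, CENTER))
        rep = monitor_acquire(t, x, y, monitor_cfg.window, monitor_cfg.t_acquire, 0, tb)
        assert rep.state is FixState.SUCCESS
        assert rep.t_event == 150_000

    def test_never_entering_fails_at_deadline(self, monitor_cfg, tb):
        t, x, y = trace_ms((800, 3000, 3000))
        rep = monitor_acquire(t, x, y, monitor_cfg.window, monitor_cfg.t_acquire, 0, tb)
        assert rep.state is FixState.FAILURE
        assert rep.t_event == 500_000

    def test_entry_exactly_at_deadline_succeeds(self, monitor_cfg, tb):
        t, x, y = trace_ms((500, 3000, 3000), (300, CENTER, CENTER))
        rep = monitor_acquire(t, x, y, monitor_cfg.window, monitor_cfg.t_acquire, 0, tb)
        assert rep.state is FixState.SUCCESS
        assert rep.t_event == 500_000

    def test_empty_stream_is_monitoring_error(self, monitor_cfg, tb):
        with pytest.raises(MonitorError):
            monitor_acquire([], [], [], monitor_cfg.window, 500_000, 0, tb)


class TestHold:
    def test_excursion_fails_at_first_outside_sample(self, monitor_cfg, tb):
        t, x, y = trace_ms((200, CENTER, CENTER), (400, 3000, 3000))
        rep = monitor_hold(t, x, y, monitor_cfg.window, 300_000, 0, tb)
        assert rep.state is FixState.FAILURE
        assert rep.t_event == 200_000

    def test_zero_duration_is_immediate_success(self, monitor_cfg, tb):
        t, x, y = trace_ms((10, 3000, 3000))
        rep = monitor_hold(t, x, y, monitor_cfg.window, 0, 0, tb)
        assert rep.state is FixState.SUCCESS
        assert rep.t_event == 0

    def test_inside_throughout_succeeds_at_duration(self, monitor_cfg, tb):
        t, x, y = trace_ms((400, CENTER, CENTER))
        rep = monitor_hold(t, x, y, monitor_cfg.window, 300_000, 0, tb)
        assert rep.state is FixState.SUCCESS
        assert rep.t_event == 300_000


class TestRunTrial:
    def compliant_trace(self):
        # acquire at 150 ms, hold 300, test saccade immediately in window
        # (association task: target at center), hold through reward
        return trace_ms((150, 3000, 3000), (1400, CENTER, CENTER))

    def test_compliant_trace_rewarded_with_one_pulse(self, monitor_cfg, test_window):
        t, x, y = self.compliant_trace()
        res = run_trial(t, x, y, monitor_cfg, test_window)
        assert res.outcome is Outcome.REWARDED
        assert res.reward_pulse is not None
        assert res.reward_pulse.line == "reward.dio0"
        # acquire 150 ms -> hold ends 450 ms -> test acquire 450 -> reward hold ends 750
        assert res.transcript[-1].t_event == 750_000

    def test_gaze_stuck_on_extinguished_fixation_point_fails_test(self, monitor_cfg):
        # lateral test stimulus at 8 deg (2848 counts), window 4 deg around it;
        # subject keeps fixating the center after the target moves
        lateral = Window(2448, 3248, 1648, 2448)
        t, x, y = trace_ms((150, 3000, 3000), (1800, CENTER, CENTER))
        res = run_trial(t, x, y, monitor_cfg, lateral)
        assert res.outcome is Outcome.FAIL_TEST
        assert res.reward_pulse is None

    def test_nan_dropout_during_hold_is_failsafe(self, monitor_cfg, test_window):
        t, x, y = self.compliant_trace()
        x[300:310] = np.nan
        res = run_trial(t, x, y, monitor_cfg, test_window)
        assert res.outcome is Outcome.FAIL_HOLD

    def test_repeat_runs_are_independent(self, monitor_cfg, test_window):
        t, x, y = self.compliant_trace()
        first = run_trial(t, x, y, monitor_cfg, test_window)
        t2, x2, y2 = trace_ms((800, 3000, 3000))
        second = run_trial(t2, x2, y2, monitor_cfg, test_window)
        third = run_trial(t, x, y, monitor_cfg, test_window)
        assert second.outcome is Outcome.FAIL_ACQUIRE
        assert first == third  # no state leaks between trials


class TestOracleEquivalence:
    def test_matches_replay_simulator_on_random_traces(self, monitor_cfg, test_window):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            t, x, y = random_trace(rng)
            res = run_trial(t, x, y, monitor_cfg, test_window)
            outcome, times = replay_trial(t, x, y, monitor_cfg, test_window)
            assert res.outcome.value == outcome
            assert [r.t_event for r in res.transcript] == times

    def test_window_enlargement_never_breaks_phase_success(self, monitor_cfg, tb):
        # forgiveness monotonicity: with the same phase start, a gaze
        # stream that satisfies acquire/hold in a window also satisfies it
        # in any enclosing window
        rng = np.random.default_rng(7)
        small = monitor_cfg.window
        big = Window(small.x_lo - 150, small.x_hi + 150, small.y_lo - 150, small.y_hi + 150)
        for _ in range(200):
            t, x, y = random_trace(rng)
            acq_s = monitor_acquire(t, x, y, small, monitor_cfg.t_acquire, 0, tb)
            acq_b = monitor_acquire(t, x, y, big, monitor_cfg.t_acquire, 0, tb)
            if acq_s.state is FixState.SUCCESS:
                assert acq_b.state is FixState.SUCCESS
                assert acq_b.t_event <= acq_s.t_event
            hold_s = monitor_hold(t, x, y, small, monitor_cfg.t_initial_fix, 0, tb)
            hold_b = monitor_hold(t, x, y, big, monitor_cfg.t_initial_fix, 0, tb)
            if hold_s.state is FixState.SUCCESS:
                assert hold_b.state is FixState.SUCCESS
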