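import numpy as np
import pytest

from gazerig.controller import StimulusPair, TaskKind, TaskSpec
from gazerig.core import DacCalibration, DisplayGeometry, TimeBase
from gazerig.sequencer import MonitorConfig, Window
from gazerig.session import SessionConfig


@pytest.fixture
def geom():
    return DisplayGeometry(
        width_cm=121.0, height_cm=68.0, res_x=1920, res_y=1080,
        distance_cm=121.92, refresh_hz=60.0,
    )


@pytest.fixture
def cal():
    return DacCalibration()


@pytest.fixture
def tb():
    return TimeBase()


@pytest.fixture
def monitor_cfg(tb):
    # 2 deg half-width window at center with default calibration (100 c/deg,
    # offset 2048); timing: 500 ms acquire, 300 ms holds, 50 ms reward
    return MonitorConfig(
        window=Window(1848, 2248, 1848, 2248),
        t_acquire=500_000,
        t_initial_fix=300_000,
        t_reward_fix=300_000,
        reward_steps=50_000,
        timebase=tb,
    )


@pytest.fixture
def test_window():
    # 4 deg half-width (8 x 8 deg image) at center
    return Window(1648, 2448, 1648, 2448)


def make_session_config(n_trials=20, seed=1, out_dir=".", kind=TaskKind.ASSOCIATION, **kw):
    task = TaskSpec(kind, pairs=(StimulusPair("call1.wav", "img1.png"),))
    return SessionConfig(schedule=[("scen0", task, n_trials)], seed=seed, out_dir=out_dir, **kw)


@pytest.fixture
def session_config_factory(tmp_path):
    def factory(n_trials=20, seed=1, **kw):
        return make_session_config(n_trials=n_trials, seed=seed, out_dir=tmp_path / "out", **kw)

    return factory


def random_trace(rng, n_ms=2000, window_half_counts=200, center=2048):
    """Piecewise-constant random gaze trace in DAC counts for oracle tests."""
    n_seg = rng.integers(2, 10)
    bounds = np.sort(rng.choice(np.arange(1, n_ms), size=n_seg - 1, replace=False))
    bounds = np.concatenate([[0], bounds, [n_ms]])
    x = np.empty(n_ms)
    y = np.empty(n_ms)
    for i in range(n_seg):
        # half the segments sit near the window center, half anywhere
        if rng.random() < 0.5:
            cx = center + rng.integers(-window_half_counts, window_half_counts + 1)
            cy = center + rng.integers(-window_half_counts, window_half_counts + 1)
        else:
            cx = center + rng.integers(-1200, 1201)
            cy = center + rng.integers(-1200, 1201)
        x[bounds[i]:bounds[i + 1]] = cx
        y[bounds[i]:bounds[i + 1]] = cy
    t = np.arange(n_ms, dtype=np.int64) * 1000
    return t, x, y
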