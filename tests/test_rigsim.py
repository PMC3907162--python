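import numpy as np
import pytest
from scipy import stats

from gazerig.analysis import detect_saccades
from gazerig.rigsim import (
    Archetype,
    NeuronModel,
    SaccadeModel,
    SubjectPolicy,
    extract_spikes_by_threshold,
    generate_gaze,
    generate_spikes,
    rate_profile,
    record_session,
)
from gazerig.sequencer import Outcome, Window, run_trial
from gazerig.core import DacCalibration


def score(trace, monitor_cfg, test_window, cal=DacCalibration()):
    x = np.rint(cal.gain_x * trace.x_deg + cal.offset_x)
    y = np.rint(cal.gain_y * trace.y_deg + cal.offset_y)
    return run_trial(trace.t_us, x, y, monitor_cfg, test_window)


class TestGaze:
    def test_fully_compliant_policy_earns_reward(self, monitor_cfg, test_window):
        rng = np.random.default_rng(0)
        trace = generate_gaze((0, 0), (0, 0), SubjectPolicy(1, 1, 1), rng)
        assert score(trace, monitor_cfg, test_window).outcome is Outcome.REWARDED

    def test_zero_acquire_policy_fails_acquisition(self, monitor_cfg, test_window):
        rng = np.random.default_rng(0)
        trace = generate_gaze((0, 0), (0, 0), SubjectPolicy(0, 1, 1), rng)
        assert score(trace, monitor_cfg, test_window).outcome is Outcome.FAIL_ACQUIRE

    def test_zero_hold_policy_fails_hold(self, monitor_cfg, test_window):
        rng = np.random.default_rng(1)
        trace = generate_gaze((0, 0), (0, 0), SubjectPolicy(1, 0, 1), rng)
        assert score(trace, monitor_cfg, test_window).outcome is Outcome.FAIL_HOLD

    def test_distracter_choice_fails_test_phase(self, monitor_cfg):
        rng = np.random.default_rng(2)
        lateral = Window(2448, 3248, 1648, 2448)  # 8 deg target, 4 deg half-width
        trace = generate_gaze(
            (0, 0), (8, 0), SubjectPolicy(1, 1, 0), rng, distracter_pos=(-8.0, 0.0)
        )
        assert score(trace, monitor_cfg, lateral).outcome is Outcome.FAIL_TEST

    def test_rewarded_fraction_tracks_policy_product(self, monitor_cfg, test_window):
        rng = np.random.default_rng(5)
        p = 0.8 * 0.9
        n = 150
        rewarded = sum(
            score(
                generate_gaze((0, 0), (0, 0), SubjectPolicy(0.8, 0.9, 1.0), rng),
                monitor_cfg,
                test_window,
            ).outcome
            is Outcome.REWARDED
            for _ in range(n)
        )
        assert abs(rewarded / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_main_sequence_slope_recovered_from_traces(self):
        # saccade segments laid into the traces follow the configured
        # main sequence: fitted duration-vs-amplitude slope within 10%
        model = SaccadeModel(d0_ms=20.0, k_ms_per_deg=2.0)
        rng = np.random.default_rng(8)
        amps, durs, det_amps = [], [], []
        while len(amps) < 200:
            trace = generate_gaze(
                (0, 0),
                (float(rng.uniform(4, 20)), float(rng.uniform(-6, 6))),
                SubjectPolicy(1, 1, 1, jitter_deg=0.05),
                rng,
                saccade_model=model,
            )
            for s in trace.saccades:
                amps.append(s.amplitude)
                durs.append((s.t_offset - s.t_onset) / 1000.0)
            det = detect_saccades(trace.t_us, trace.x_deg, trace.y_deg)
            det_amps.extend(d.amplitude for d in det)
        slope, _, r, *_ = stats.linregress(amps, durs)
        assert r > 0.95
        assert abs(slope - model.k_ms_per_deg) / model.k_ms_per_deg < 0.10
        # the detector sees essentially the same population of amplitudes
        assert abs(np.mean(det_amps) - np.mean(amps)) < 1.0

    def test_same_seed_reproduces_trace_exactly(self):
        a = generate_gaze((0, 0), (8, 0), SubjectPolicy(0.7, 0.8, 0.9), np.random.default_rng(3))
        b = generate_gaze((0, 0), (8, 0), SubjectPolicy(0.7, 0.8, 0.9), np.random.default_rng(3))
        assert np.array_equal(a.x_deg, b.x_deg) and np.array_equal(a.y_deg, b.y_deg)


class TestSpikes:
    def test_zero_rates_give_empty_train(self):
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=0.0, response_hz=0.0)
        train = generate_spikes(model, [0], 10_000_000, np.random.default_rng(0))
        assert train.size == 0

    def test_homogeneous_50_hz_count_within_poisson_bound(self):
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=50.0, response_hz=0.0)
        train = generate_spikes(model, [], 10_000_000, np.random.default_rng(1))
        assert abs(train.size - 500) < 3 * np.sqrt(500)

    def test_timestamps_on_tenth_ms_grid_and_increasing(self):
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=100.0, response_hz=0.0)
        train = generate_spikes(model, [], 5_000_000, np.random.default_rng(2))
        assert np.all(train % 100 == 0)
        assert np.all(np.diff(train) > 0)

    def test_onset_archetype_has_no_mass_before_latency(self):
        model = NeuronModel(
            Archetype.AUDITORY_ONSET, baseline_hz=0.0, response_hz=80.0, latency_ms=21.0
        )
        events = np.array([1_000_000])
        t = np.arange(0, 2_000_000, 100)
        rate = rate_profile(model, t, events)
        assert np.all(rate[t < 1_021_000] == 0.0)
        assert rate[t == 1_021_000] > 0

    def test_counts_match_integrated_rate_chi2(self):
        # chi-square goodness of fit of window counts against the
        # integrated rate, 100 windows, alpha = 0.01
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=40.0, response_hz=0.0)
        duration = 100_000_000  # 100 s
        train = generate_spikes(model, [], duration, np.random.default_rng(3))
        edges = np.linspace(0, duration, 101)
        counts, _ = np.histogram(train, bins=edges)
        expected = 40.0 * (duration / 100) / 1e6
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 < stats.chi2.ppf(0.99, df=100 - 1)


class TestRecording:
    def make(self, seed=0, n_spikes=200, snr=10.0):
        rng = np.random.default_rng(seed)
        dur_s = 10
        eye = rng.normal(0, 0.1, size=(2, dur_s * 1000))
        spikes = np.sort(
            rng.choice(np.arange(2_000, dur_s * 1_000_000 - 2_000, 100), n_spikes, replace=False)
        ).astype(np.int64)
        # enforce a refractory gap so threshold extraction is well posed
        spikes = spikes[np.concatenate(([True], np.diff(spikes) > 3_000))]
        events = [(1_000_000, "fixation_on"), (2_000_000, "sound_on")]
        return record_session(eye[0], eye[1], spikes, events, rng, snr=snr), spikes

    def test_channel_lengths_match_session_duration(self):
        rec, _ = self.make()
        assert len(rec.eye_x) == 10_000
        assert len(rec.neural) == 10 * 25_000
        assert rec.duration_us() == 10_000_000

    def test_threshold_reextraction_recovers_99_percent(self):
        rec, spikes = self.make(snr=10.0)
        found = extract_spikes_by_threshold(rec, threshold=0.5)
        hits = sum(np.any(np.abs(found - s) < 1_000) for s in spikes)
        assert hits / len(spikes) >= 0.99

    def test_same_seed_identical_recording_hash(self):
        a, _ = self.make(seed=7)
        b, _ = self.make(seed=7)
        c, _ = self.make(seed=8)
        assert a.content_hash() == b.content_hash()
        assert a.content_hash() != c.content_hash()

    def test_hdf5_round_trip(self, tmp_path):
        rec, _ = self.make()
        path = tmp_path / "rec.h5"
        rec.save(path)
        back = rec.load(path)
        assert back.content_hash() == rec.content_hash()
        assert back.events == rec.events
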