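import numpy as np
import pytest

from gazerig.analysis import (
    AnalysisError,
    SaccadeEvent,
    build_psth,
    detect_saccades,
    first_peak_latency,
    preferred_vector,
    spike_density,
)
from gazerig.rigsim import (
    Archetype,
    NeuronModel,
    SubjectPolicy,
    generate_gaze,
    generate_spikes,
    von_mises_gain,
)


class TestDetectSaccades:
    def test_constant_position_yields_no_events(self):
        t = np.arange(1000, dtype=np.int64) * 1000
        assert detect_saccades(t, np.full(1000, 3.0), np.full(1000, -2.0)) == []

    def test_single_10deg_rightward_saccade_measured_accurately(self):
        rng = np.random.default_rng(5)
        trace = generate_gaze((0, 0), (10, 0), SubjectPolicy(1, 1, 1, jitter_deg=0.1), rng)
        events = [e for e in detect_saccades(trace.t_us, trace.x_deg, trace.y_deg)
                  if abs(e.angle) < 45]
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(10.0, abs=0.5)
        assert events[0].angle == pytest.approx(0.0, abs=5.0)

    def test_two_saccades_reported_in_order(self):
        rng = np.random.default_rng(6)
        trace = generate_gaze((0, 0), (10, 0), SubjectPolicy(1, 1, 1, jitter_deg=0.05), rng)
        events = detect_saccades(trace.t_us, trace.x_deg, trace.y_deg)
        assert len(events) == len(trace.saccades) == 2
        assert events[0].t_onset < events[1].t_onset
        for det, truth in zip(events, trace.saccades):
            assert abs(det.t_onset - truth.t_onset) < 30_000


class TestPSTH:
    def test_empty_trains_give_zero_counts(self):
        psth = build_psth([], [1_000_000, 2_000_000])
        assert psth.counts.sum() == 0

    def test_poisson_50hz_40_repeats_half_spike_per_bin(self):
        # 50 Hz x 10 ms bins -> 0.5 spikes per bin per trial
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=50.0, response_hz=0.0)
        rng = np.random.default_rng(11)
        duration = 60_000_000
        train = generate_spikes(model, [], duration, rng)
        aligns = np.arange(40) * 1_000_000 + 500_000
        psth = build_psth(train, aligns, bin_width_ms=10.0, window_ms=(-100, 300))
        per_bin_per_trial = psth.counts / psth.n_trials
        se = np.sqrt(0.5 / 40)
        assert abs(per_bin_per_trial.mean() - 0.5) < 3 * se

    def test_count_conservation_on_random_input(self):
        rng = np.random.default_rng(4)
        train = np.sort(rng.integers(0, 50_000_000, 3000)).astype(np.int64)
        aligns = rng.integers(1_000_000, 49_000_000, 15)
        psth = build_psth(train, aligns, bin_width_ms=10.0, window_ms=(-100, 300))
        expected = sum(
            np.count_nonzero((train >= a - 100_000) & (train < a + 300_000)) for a in aligns
        )
        assert psth.counts.sum() == expected
        assert np.allclose(
            psth.rate_hz, psth.counts / (psth.n_trials * 0.01)
        )

    def test_empty_alignment_list_is_an_error(self):
        with pytest.raises(AnalysisError):
            build_psth([1000], [])


class TestSpikeDensity:
    def test_empty_trains_give_zero_waveform(self):
        sdf = spike_density([], [1_000_000])
        assert np.all(sdf.rate_hz == 0)

    def test_single_spike_peaks_at_zero_with_unit_area(self):
        sdf = spike_density([1_000_000], [1_000_000], sd_ms=10.0)
        assert abs(sdf.time_ms[np.argmax(sdf.rate_hz)]) <= 1.0
        assert sdf.integral_spikes() == pytest.approx(1.0, rel=1e-6)

    def test_integral_equals_mean_count_per_trial(self):
        rng = np.random.default_rng(2)
        train = np.sort(rng.integers(0, 30_000_000, 2000)).astype(np.int64)
        aligns = rng.integers(1_000_000, 29_000_000, 20)
        sdf = spike_density(train, aligns, sd_ms=10.0, window_ms=(-100, 300))
        counts = [
            np.count_nonzero((train >= a - 100_000) & (train < a + 300_000)) for a in aligns
        ]
        assert sdf.integral_spikes() == pytest.approx(np.mean(counts), rel=1e-6)

    def test_20_trials_of_50hz_average_near_50(self):
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=50.0, response_hz=0.0)
        rng = np.random.default_rng(13)
        train = generate_spikes(model, [], 30_000_000, rng)
        aligns = np.arange(20) * 1_200_000 + 500_000
        sdf = spike_density(train, aligns, sd_ms=10.0, window_ms=(-100, 300))
        core = (sdf.time_ms > -80) & (sdf.time_ms < 280)
        se = np.sqrt(50.0 / (20 * 0.4))  # Poisson SE of the window mean
        assert abs(sdf.rate_hz[core].mean() - 50.0) < 3 * se


class TestFirstPeakLatency:
    def make_step_psth(self, latency_ms, rng, baseline=10.0, response=80.0, n_trials=40):
        model = NeuronModel(
            Archetype.AUDITORY_ONSET,
            baseline_hz=baseline,
            response_hz=response,
            latency_ms=latency_ms,
            response_dur_ms=60.0,
        )
        aligns = np.arange(n_trials) * 1_000_000 + 500_000
        train = generate_spikes(model, aligns, int(aligns[-1] + 500_000), rng)
        return build_psth(train, aligns, bin_width_ms=10.0, window_ms=(-100, 300))

    def test_clean_step_at_20ms_recovered_within_half_bin(self):
        rng = np.random.default_rng(21)
        psth = self.make_step_psth(20.0, rng, baseline=5.0, response=200.0, n_trials=200)
        assert first_peak_latency(psth) == pytest.approx(20.0, abs=5.0)

    def test_flat_psth_reports_no_response(self):
        model = NeuronModel(Archetype.AUDITORY_ONSET, baseline_hz=20.0, response_hz=0.0)
        rng = np.random.default_rng(22)
        train = generate_spikes(model, [], 50_000_000, rng)
        psth = build_psth(train, np.arange(40) * 1_000_000 + 500_000)
        assert first_peak_latency(psth) is None

    def test_latency_recovery_over_synthetic_onset_neurons(self):
        rng = np.random.default_rng(23)
        errors = []
        for latency in np.linspace(15, 30, 10):
            psth = self.make_step_psth(float(latency), rng)
            est = first_peak_latency(psth)
            assert est is not None
            errors.append(abs(est - latency))
        assert np.mean(errors) < 5.0


def make_saccade_set(rng, n=120):
    angles = rng.uniform(-180, 180, n)
    amps = rng.uniform(5, 25, n)
    onsets = (np.arange(n) * 1_000_000 + 500_000).astype(np.int64)
    sacs = [
        SaccadeEvent(int(t), int(t + 40_000), float(a), float(g))
        for t, a, g in zip(onsets, amps, angles)
    ]
    return sacs, onsets, angles, amps


class TestPreferredVector:
    def test_tuned_neuron_angle_recovered(self):
        rng = np.random.default_rng(31)
        sacs, onsets, angles, _ = make_saccade_set(rng)
        model = NeuronModel(Archetype.SC_BUILDUP_BURST, baseline_hz=5.0, response_hz=100.0)
        train = generate_spikes(
            model, onsets, int(onsets[-1] + 1_000_000), rng,
            event_gains=von_mises_gain(angles, 137.0, 2.0),
        )
        pv = preferred_vector(train, sacs, burst_window_ms=(-40, 0))
        assert pv.reliable
        assert abs((pv.angle_deg - 137.0 + 180) % 360 - 180) < 10.0

    def test_untuned_neuron_flagged_unreliable(self):
        rng = np.random.default_rng(32)
        sacs, onsets, _, amps = make_saccade_set(rng)
        model = NeuronModel(Archetype.SC_BUILDUP_BURST, baseline_hz=5.0, response_hz=100.0)
        train = generate_spikes(model, onsets, int(onsets[-1] + 1_000_000), rng)
        pv = preferred_vector(train, sacs, burst_window_ms=(-40, 0))
        assert not pv.reliable
        assert pv.amplitude_deg == pytest.approx(np.mean(amps), abs=5.0)

    def test_too_few_saccades_rejected(self):
        rng = np.random.default_rng(33)
        sacs, onsets, *_ = make_saccade_set(rng, n=10)
        with pytest.raises(AnalysisError, match="20"):
            preferred_vector([1_000_000], sacs)

    def test_poor_directional_coverage_rejected(self):
        rng = np.random.default_rng(34)
        n = 40
        onsets = (np.arange(n) * 1_000_000 + 500_000).astype(np.int64)
        sacs = [
            SaccadeEvent(int(t), int(t + 40_000), 10.0, float(rng.uniform(-10, 10)))
            for t in onsets
        ]
        with pytest.raises(AnalysisError, match="coverage"):
            preferred_vector([1_000_000], sacs)

    def test_zero_spikes_is_insufficient_activity(self):
        rng = np.random.default_rng(35)
        sacs, *_ = make_saccade_set(rng)
        with pytest.raises(AnalysisError, match="insufficient activity"):
            preferred_vector([], sacs)
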