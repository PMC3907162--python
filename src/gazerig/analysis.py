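"""Post-hoc analysis of recorded sessions.

Everything here consumes a recording (eye channels, spike timestamps,
event log) and the bus/event timestamps that mark stimulus onsets:

* saccade detection from the 1-kHz eye channels by a smoothed
  radial-velocity threshold;
* event-aligned rasters and peristimulus time histograms (PSTHs) with a
  fixed bin width (10 ms default);
* spike-density functions (per-trial delta trains convolved with a
  unit-area Gaussian kernel, averaged across trials, in spikes/s);
* first-peak response latency from a PSTH against a baseline criterion
  (baseline mean + 3 SD), with sub-bin refinement of the rising edge;
* the preferred saccade vector of a perisaccadically active neuron from
  the burst-window firing rate binned over saccade amplitude and
  direction.

Times are integer microseconds on the session clock at the interfaces;
results are reported in milliseconds and spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter


class AnalysisError(RuntimeError):
    """Unusable input for an analysis (no events, no spikes, poor coverage)."""


@dataclass(frozen=True)
class SaccadeEvent:
    t_onset: int  # us
    t_offset: int  # us
    amplitude: float  # degrees
    angle: float  # degrees, 0 rightward, CCW positive


# ---------------------------------------------------------------------------
# saccade detection


def detect_saccades(
    t_us,
    x_deg,
    y_deg,
    v_thresh: float = 30.0,
    min_amp: float = 0.5,
    smooth_ms: int = 25,
    min_dur_ms: int = 6,
) -> list[SaccadeEvent]:
    """Detect saccades by a radial-velocity threshold on the 1-kHz trace.

    Velocity comes from a Savitzky–Golay derivative (quadratic fit over a
    `smooth_ms` window) — a plain finite difference on a 1-kHz trace with
    realistic fixational jitter is dominated by noise — and the radial
    speed is boxcar-smoothed before thresholding at `v_thresh` (deg/s).
    Supra-threshold runs shorter than `min_dur_ms` and events whose
    amplitude (measured between pre-onset and post-offset fixation
    positions) falls below `min_amp` are discarded, which rejects the
    remaining fixational-noise blips.
    """
    t_us = np.asarray(t_us, dtype=np.int64)
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    n = x.size
    win = min(smooth_ms if smooth_ms % 2 else smooth_ms + 1, n if n % 2 else n - 1)
    if n < 5 or win < 5:
        return []
    dt_s = 1e-3  # 1 kHz
    xs = savgol_filter(x, win, 2)
    ys = savgol_filter(y, win, 2)
    vx = savgol_filter(x, win, 2, deriv=1, delta=dt_s)
    vy = savgol_filter(y, win, 2, deriv=1, delta=dt_s)
    speed = uniform_filter1d(np.hypot(vx, vy), 9, mode="nearest")

    above = speed > v_thresh
    edges = np.diff(above.astype(np.int8))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(n - 1)

    events: list[SaccadeEvent] = []
    for i0, i1 in zip(onsets, offsets):
        if (i1 - i0) < min_dur_ms:
            continue
        pre = slice(max(0, i0 - 25), max(1, i0 - 5))
        post = slice(min(n - 1, i1 + 5), min(n, i1 + 25))
        x0, y0 = float(np.median(xs[pre])), float(np.median(ys[pre]))
        x1, y1 = float(np.median(xs[post])), float(np.median(ys[post]))
        amp = float(np.hypot(x1 - x0, y1 - y0))
        if amp < min_amp:
            continue
        events.append(
            SaccadeEvent(
                t_onset=int(t_us[i0]),
                t_offset=int(t_us[i1]),
                amplitude=amp,
                angle=float(np.degrees(np.arctan2(y1 - y0, x1 - x0))),
            )
        )
    return events


# ---------------------------------------------------------------------------
# PSTH / raster


@dataclass
class PSTH:
    """Peristimulus time histogram plus the raster it was built from."""

    bin_edges_ms: np.ndarray  # length n_bins + 1, relative to the event
    counts: np.ndarray  # total spikes per bin across trials
    n_trials: int
    bin_width_ms: float
    raster: list[np.ndarray]  # per-trial relative spike times (ms)

    @property
    def rate_hz(self) -> np.ndarray:
        """Trial-averaged firing rate per bin in spikes/s."""
        return self.counts / (self.n_trials * self.bin_width_ms * 1e-3)

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def align_spikes(spike_times_us, align_times_us, window_ms) -> list[np.ndarray]:
    """Per-event relative spike times (ms) within the analysis window."""
    spikes = np.asarray(spike_times_us, dtype=np.int64)
    rows = []
    lo, hi = window_ms
    for a in np.asarray(align_times_us, dtype=np.int64):
        rel = (spikes - a) / 1000.0
        rows.append(rel[(rel >= lo) & (rel < hi)])
    return rows


def build_psth(
    spike_times_us,
    align_times_us,
    bin_width_ms: float = 10.0,
    window_ms: tuple[float, float] = (-100.0, 300.0),
) -> PSTH:
    """Event-aligned PSTH with fixed-width bins.

    ``counts[b]`` is the number of spikes whose event-relative time falls
    in bin ``b``, summed over alignment events; the raster keeps each
    trial's relative times.  Sum of counts equals the number of aligned
    spikes in the window exactly.
    """
    align = np.asarray(align_times_us, dtype=np.int64)
    if align.size == 0:
        raise AnalysisError("no alignment events")
    lo, hi = window_ms
    n_bins = int(round((hi - lo) / bin_width_ms))
    edges = lo + bin_width_ms * np.arange(n_bins + 1)
    raster = align_spikes(spike_times_us, align, (lo, float(edges[-1])))
    counts = np.zeros(n_bins, dtype=np.int64)
    for row in raster:
        c, _ = np.histogram(row, bins=edges)
        counts += c
    return PSTH(edges, counts, int(align.size), float(bin_width_ms), raster)


# ---------------------------------------------------------------------------
# spike density


@dataclass
class SpikeDensity:
    """Gaussian-kernel smoothed, trial-averaged firing rate (spikes/s)."""

    time_ms: np.ndarray  # sampling grid relative to the event (includes pad)
    rate_hz: np.ndarray
    n_trials: int
    sd_ms: float

    def integral_spikes(self) -> float:
        """Area under the waveform in spikes (mean count per trial)."""
        dt = np.diff(self.time_ms).mean() * 1e-3
        return float(self.rate_hz.sum() * dt)


def spike_density(
    spike_times_us,
    align_times_us,
    sd_ms: float = 10.0,
    window_ms: tuple[float, float] = (-100.0, 300.0),
    dt_ms: float = 1.0,
) -> SpikeDensity:
    """Spike-density function: unit-area Gaussian kernel, trial average.

    Spikes inside `window_ms` are binned on a `dt_ms` grid padded by 8 SD
    on each side (so no kernel mass is truncated) and convolved with a
    normalized Gaussian of width `sd_ms`; the trial-averaged result is
    scaled to spikes/s.  The waveform's integral therefore equals the mean
    per-trial spike count in the window.
    """
    if sd_ms <= 0:
        raise AnalysisError("kernel SD must be > 0")
    align = np.asarray(align_times_us, dtype=np.int64)
    if align.size == 0:
        raise AnalysisError("no alignment events")
    pad = 8.0 * sd_ms
    lo, hi = window_ms[0] - pad, window_ms[1] + pad
    n = int(round((hi - lo) / dt_ms))
    edges = lo + dt_ms * np.arange(n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = align_spikes(spike_times_us, align, window_ms)
    hist = np.zeros(n, dtype=float)
    for row in rows:
        c, _ = np.histogram(row, bins=edges)
        hist += c
    radius = int(np.ceil(8.0 * sd_ms / dt_ms))
    k = np.arange(-radius, radius + 1) * dt_ms
    kernel = np.exp(-0.5 * (k / sd_ms) ** 2)
    kernel /= kernel.sum()
    smoothed = np.convolve(hist, kernel, mode="same")
    rate = smoothed / (align.size * dt_ms * 1e-3)
    return SpikeDensity(centers, rate, int(align.size), float(sd_ms))


# ---------------------------------------------------------------------------
# first-peak latency


def first_peak_latency(
    psth: PSTH,
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
    criterion_sd: float = 3.0,
) -> float | None:
    """Latency (ms) of the first post-event response excursion.

    The criterion rate is the baseline mean plus `criterion_sd` baseline
    SDs, computed over the bins inside `baseline_window_ms`.  The latency
    is the onset of the first post-event bin whose rate exceeds the
    criterion, refined below bin resolution from the rising edge: the
    supra-threshold bin's excess rate relative to the following plateau
    estimates what fraction of the bin the response occupied, placing the
    onset within the bin.  Returns None ("no response") when no bin
    crosses the criterion — distinct from a latency of 0.
    """
    centers = psth.bin_centers_ms
    rate = psth.rate_hz
    base_mask = (centers >= baseline_window_ms[0]) & (centers < baseline_window_ms[1])
    if not base_mask.any():
        raise AnalysisError("baseline window contains no bins")
    base_mean = float(rate[base_mask].mean())
    base_sd = float(rate[base_mask].std(ddof=0))
    criterion = base_mean + criterion_sd * base_sd

    post = np.flatnonzero((centers > 0) & (rate > criterion))
    if post.size == 0:
        return None
    b = int(post[0])
    bin_start = float(psth.bin_edges_ms[b])
    plateau = float(rate[b + 1]) if b + 1 < rate.size else float(rate[b])
    plateau = max(plateau, float(rate[b]))
    if plateau <= base_mean:
        return bin_start + 0.5 * psth.bin_width_ms
    frac = np.clip((rate[b] - base_mean) / (plateau - base_mean), 0.0, 1.0)
    return float(bin_start + (1.0 - frac) * psth.bin_width_ms)


# ---------------------------------------------------------------------------
# preferred saccade vector


@dataclass
class PreferredVector:
    amplitude_deg: float
    angle_deg: float
    resultant_length: float  # circular concentration of the estimate, [0, 1]
    reliable: bool  # False when directional structure is too weak
    heat_map: np.ndarray  # mean rate per (amplitude, angle) bin; NaN if empty
    amp_edges: np.ndarray
    ang_edges_deg: np.ndarray


def _angular_span_deg(angles_deg: np.ndarray) -> float:
    """Circular span: 360 minus the largest empty gap between directions."""
    a = np.sort(np.asarray(angles_deg) % 360.0)
    if a.size < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return 360.0 - float(gaps.max())


def preferred_vector(
    spike_times_us,
    saccades: list[SaccadeEvent],
    burst_window_ms: tuple[float, float] = (-20.0, 20.0),
    n_amp_bins: int = 4,
    n_ang_bins: int = 8,
) -> PreferredVector:
    """Estimate the saccade vector that evokes maximal perisaccadic firing.

    Each saccade contributes its burst-window firing rate; rates are
    binned over (amplitude, direction), and the preferred vector is the
    rate-weighted circular mean direction and rate-weighted mean amplitude
    of the supra-median bins.  A resultant length below 0.1 marks the
    direction estimate unreliable (direction-independent firing).

    Raises
    ------
    AnalysisError
        With fewer than 20 saccades, directional coverage under 90
        degrees, or zero spikes in every burst window ("insufficient
        activity").
    """
    if len(saccades) < 20:
        raise AnalysisError(f"need >= 20 saccades, got {len(saccades)}")
    angles = np.array([s.angle for s in saccades])
    amps = np.array([s.amplitude for s in saccades])
    if _angular_span_deg(angles) < 90.0:
        raise AnalysisError("insufficient directional coverage (< 90 degrees)")
    spikes = np.asarray(spike_times_us, dtype=np.int64)
    lo, hi = burst_window_ms
    width_s = (hi - lo) * 1e-3
    rates = np.array(
        [
            np.count_nonzero(
                (spikes >= s.t_onset + lo * 1000) & (spikes < s.t_onset + hi * 1000)
            )
            / width_s
            for s in saccades
        ]
    )
    if rates.sum() == 0:
        raise AnalysisError("insufficient activity: zero spikes in all burst windows")

    amp_edges = np.linspace(0.0, float(amps.max()) + 1e-9, n_amp_bins + 1)
    ang_edges = np.linspace(-180.0, 180.0, n_ang_bins + 1)
    heat = np.full((n_amp_bins, n_ang_bins), np.nan)
    ai = np.clip(np.digitize(amps, amp_edges) - 1, 0, n_amp_bins - 1)
    gi = np.clip(np.digitize(angles, ang_edges) - 1, 0, n_ang_bins - 1)
    for a in range(n_amp_bins):
        for g in range(n_ang_bins):
            sel = (ai == a) & (gi == g)
            if sel.any():
                heat[a, g] = rates[sel].mean()

    occupied = ~np.isnan(heat)
    median = np.nanmedian(heat)
    supra = occupied & (heat > median)
    if not supra.any():
        supra = occupied
    ang_centers = 0.5 * (ang_edges[:-1] + ang_edges[1:])
    # estimate from the saccades inside the supra-median bins, weighted by
    # their own burst rates: finer than the 45-degree bin centers
    in_supra = supra[ai, gi]
    w = rates[in_supra]
    z = np.sum(w * np.exp(1j * np.radians(angles[in_supra])))
    pref_angle = float(np.degrees(np.angle(z)))
    pref_amp = float(np.sum(w * amps[in_supra]) / w.sum())
    # reliability from ALL occupied bins: a flat heat map has a near-zero
    # resultant there, whereas supra-median selection alone would inflate it
    oa, og = np.nonzero(occupied)
    wa = heat[oa, og]
    za = np.sum(wa * np.exp(1j * np.radians(ang_centers[og])))
    resultant = float(np.abs(za) / wa.sum()) if wa.sum() > 0 else 0.0
    return PreferredVector(
        amplitude_deg=pref_amp,
        angle_deg=pref_angle,
        resultant_length=resultant,
        reliable=resultant >= 0.1,
        heat_map=heat,
        amp_edges=amp_edges,
        ang_edges_deg=ang_edges,
    )
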