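"""Placeholder stimulus assets and example configurations.

The real rig presented natural communication calls and photographs; the
simulation needs only well-formed files, so this module fabricates small
PNG images (solid-color squares with a centered disc) and 1-s WAV tone
bursts (the classic short tone-burst stimulus; the nominal 80 dB SPL
presentation level is metadata only — the simulation has no acoustics).
Everything is generated locally, nothing is downloaded.
"""

from __future__ import annotations

import wave
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

import yaml

TONE_DURATION_S = 1.0
TONE_LEVEL_DB_SPL = 80.0  # nominal presentation level, metadata only


def make_image(path: Path, color: tuple[int, int, int], size_px: int = 64) -> Path:
    """Write a placeholder PNG: black field with a colored disc."""
    img = Image.new("RGB", (size_px, size_px), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    m = size_px // 8
    draw.ellipse([m, m, size_px - m, size_px - m], fill=color)
    img.save(path, format="PNG")
    return path


def make_tone(
    path: Path,
    freq_hz: float = 1000.0,
    duration_s: float = TONE_DURATION_S,
    rate_hz: int = 22050,
    ramp_ms: float = 10.0,
) -> Path:
    """Write a 16-bit mono WAV tone burst with cosine on/off ramps."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = np.sin(2.0 * np.pi * freq_hz * t)
    n_ramp = int(ramp_ms * 1e-3 * rate_hz)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    pcm = (x * 0.8 * 32767).astype("<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(rate_hz)
        w.writeframes(pcm.tobytes())
    return path


def make_assets(out_dir: Path, n_pairs: int = 1) -> list[dict]:
    """Generate `n_pairs` sound/image pairs; returns manifest entries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    palette = [(0, 200, 0), (200, 0, 0), (0, 0, 200), (200, 200, 0)]
    pairs = []
    for i in range(n_pairs):
        img = make_image(out_dir / f"img{i + 1}.png", palette[i % len(palette)])
        snd = make_tone(out_dir / f"call{i + 1}.wav", freq_hz=500.0 * (i + 1))
        pairs.append({"image": str(img), "sound": str(snd)})
    return pairs


def write_example_config(out_dir: Path, seed: int = 42, n_trials: int = 20) -> Path:
    """Fabricate assets and an example session config next to them."""
    out_dir = Path(out_dir)
    pairs = make_assets(out_dir / "assets", n_pairs=1)
    cfg = {
        "subject": "sim01",
        "seed": seed,
        "out_dir": str(out_dir / "session"),
        "geometry": {
            "width_cm": 121.0, "height_cm": 68.0, "res_x": 1920, "res_y": 1080,
            "distance_cm": 121.92, "refresh_hz": 60.0,
        },
        "window_deg": 2.0,
        "image_size_deg": [8.0, 8.0],
        "reward_ms": 50.0,
        "timeout_ms": 2000.0,
        "policy": {
            "p_acquire": 0.9, "p_hold": 0.9, "p_target_choice": 1.0,
            "reaction_ms": [180.0, 30.0], "jitter_deg": 0.1,
        },
        "timing": {
            "t_acquire_ms": 500.0, "t_initial_fix_ms": 300.0, "t_reward_fix_ms": 300.0,
        },
        "scenarios": [
            {"name": "association", "task": "ASSOCIATION", "n_trials": n_trials,
             "pairs": pairs},
        ],
        "neurons": {
            "ic_onset": {"archetype": "AUDITORY_ONSET", "baseline_hz": 10.0,
                          "response_hz": 80.0, "latency_ms": 21.0},
        },
    }
    path = out_dir / "example_config.yaml"
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
    return path
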