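"""Session-config loading and validation (declarative dialog replacement).

The interactive dialog cascade of the original rig is replaced by a YAML
document holding the same fields: subject, display geometry, detection
window size, reward duration, the three timing criteria, the stimulus
pairing list, and the scenario schedule.  Validation errors carry the
offending field's dotted path so a bad config fails loudly and precisely.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from gazerig.controller import StimulusPair, TaskKind, TaskSpec
from gazerig.core import DacCalibration, DisplayGeometry, TimeBase
from gazerig.rigsim import Archetype, NeuronModel, SubjectPolicy
from gazerig.session import SessionConfig


class SchemaError(ValueError):
    """Config violates the schema; message names the field."""

    def __init__(self, field: str, message: str) -> None:
        self.field = field
        super().__init__(f"{field}: {message}")


def _require(doc: dict, field: str, path: str):
    if field not in doc:
        raise SchemaError(f"{path}.{field}" if path else field, "missing required field")
    return doc[field]


def _positive(value, field: str):
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise SchemaError(field, f"not a number: {value!r}") from None
    if v <= 0:
        raise SchemaError(field, f"must be > 0, got {v}")
    return v


def load_config(path: str | Path) -> SessionConfig:
    """Parse and validate a session config file (YAML or JSON)."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict):
        raise SchemaError("<root>", "config must be a mapping")

    timing = _require(doc, "timing", "")
    for key in ("t_acquire_ms", "t_initial_fix_ms", "t_reward_fix_ms"):
        _positive(_require(timing, key, "timing"), f"timing.{key}")

    g = doc.get("geometry", {})
    try:
        geometry = DisplayGeometry(
            width_cm=g.get("width_cm", 121.0),
            height_cm=g.get("height_cm", 68.0),
            res_x=g.get("res_x", 1920),
            res_y=g.get("res_y", 1080),
            distance_cm=g.get("distance_cm", 121.92),
            refresh_hz=g.get("refresh_hz", 60.0),
        )
    except ValueError as e:
        raise SchemaError("geometry", str(e)) from None

    p = doc.get("policy", {})
    try:
        policy = SubjectPolicy(
            p_acquire=p.get("p_acquire", 1.0),
            p_hold=p.get("p_hold", 1.0),
            p_target_choice=p.get("p_target_choice", 1.0),
            reaction_ms=tuple(p.get("reaction_ms", (180.0, 30.0))),
            jitter_deg=p.get("jitter_deg", 0.1),
        )
    except ValueError as e:
        raise SchemaError("policy", str(e)) from None

    scenarios = _require(doc, "scenarios", "")
    if not isinstance(scenarios, list) or not scenarios:
        raise SchemaError("scenarios", "must be a nonempty list")
    schedule = []
    for i, sc in enumerate(scenarios):
        loc = f"scenarios[{i}]"
        name = _require(sc, "name", loc)
        kind_str = _require(sc, "task", loc)
        try:
            kind = TaskKind[kind_str]
        except KeyError:
            raise SchemaError(
                f"{loc}.task",
                f"unknown task {kind_str!r}; one of {[k.name for k in TaskKind]}",
            ) from None
        pairs = tuple(
            StimulusPair(sound=pr["sound"], image=pr["image"])
            for pr in sc.get("pairs", [])
        )
        n_trials = int(_positive(_require(sc, "n_trials", loc), f"{loc}.n_trials"))
        try:
            task = TaskSpec(
                kind=kind,
                pairs=pairs,
                offset_deg=sc.get("offset_deg", 8.0),
                distracter_positions=tuple(
                    tuple(q) for q in sc.get("distracter_positions", [])
                ),
                walk_positions=tuple(
                    tuple(q) for q in sc.get("walk_positions", [(0.0, 0.0)])
                ),
                t_acquire_ms=timing["t_acquire_ms"],
                t_initial_fix_ms=timing["t_initial_fix_ms"],
                t_reward_fix_ms=timing["t_reward_fix_ms"],
            )
        except ValueError as e:
            raise SchemaError(loc, str(e)) from None
        schedule.append((name, task, n_trials))

    neurons = {}
    for name, nd in (doc.get("neurons") or {}).items():
        loc = f"neurons.{name}"
        arch_str = _require(nd, "archetype", loc)
        try:
            arch = Archetype[arch_str]
        except KeyError:
            raise SchemaError(f"{loc}.archetype", f"unknown archetype {arch_str!r}") from None
        try:
            neurons[name] = NeuronModel(
                archetype=arch,
                baseline_hz=nd.get("baseline_hz", 10.0),
                response_hz=nd.get("response_hz", 80.0),
                latency_ms=nd.get("latency_ms", 21.0),
                buildup_ms=nd.get("buildup_ms", 70.0),
                response_dur_ms=nd.get("response_dur_ms", 40.0),
            )
        except ValueError as e:
            raise SchemaError(loc, str(e)) from None

    return SessionConfig(
        subject=doc.get("subject", "subj1"),
        geometry=geometry,
        calibration=DacCalibration(),
        timebase=TimeBase(),
        policy=policy,
        neurons=neurons,
        window_deg=_positive(doc.get("window_deg", 2.0), "window_deg"),
        image_size_deg=tuple(doc.get("image_size_deg", (8.0, 8.0))),
        reward_ms=_positive(doc.get("reward_ms", 50.0), "reward_ms"),
        timeout_ms=_positive(doc.get("timeout_ms", 2000.0), "timeout_ms"),
        seed=int(doc.get("seed", 0)),
        out_dir=Path(doc.get("out_dir", "gazerig_out")),
        schedule=schedule,
    )
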