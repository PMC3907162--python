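"""The stimulus endpoint: object registry, command loop, frame quantization.

The presenter predefines every stimulus object a session may call (a named
dot, image, sound, image+sound pair, or the black screen).  Its command
loop answers each serial token by updating the display state, sending the
reply token back on the serial path, and stamping a 1-ms TTL on bit 8 of
the parallel port at the moment the stimulus actually appears.

Visual onsets are quantized to the vertical refresh: a request lands on the
next frame boundary, so a 60-Hz display carries an inherent worst-case
onset error of 16 ms (one truncated frame period).  Sound is not
frame-quantized — playback starts at the request time plus a configurable
fixed audio latency (0 in simulation) — so :func:`audit_av_sync` reports
the per-event image/sound onset offset, bounded by one frame period.

An explicit alias table maps token words to object names (the classic rig
used the 7-character word ``grendot`` for the object ``greendot``), so
command vocabulary and object naming stay decoupled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from gazerig.core import DisplayGeometry
from gazerig.protocol import Bus, ProtocolError, TTLPulse, _validate_word

STIMULUS_LINE = "parallel.bit8"


class RegistryError(ValueError):
    """Duplicate registration, missing asset, or invariant violation."""


@dataclass(frozen=True)
class StimulusObject:
    """Everything the presenter needs to draw/play one named stimulus."""

    name: str
    kind: str  # DOT | IMAGE | SOUND | IMAGE_SOUND | BLACK
    image: str | None = None
    sound: str | None = None
    pos: tuple[float, float] = (0.0, 0.0)  # degrees
    size: tuple[float, float] = (0.0, 0.0)  # degrees
    background: str = "black"

    def __post_init__(self) -> None:
        _validate_word(self.name)
        if self.kind not in {"DOT", "IMAGE", "SOUND", "IMAGE_SOUND", "BLACK"}:
            raise RegistryError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "IMAGE_SOUND" and not (self.image and self.sound):
            raise RegistryError(f"IMAGE_SOUND object {self.name!r} needs both assets")
        if self.kind == "IMAGE" and not self.image:
            raise RegistryError(f"IMAGE object {self.name!r} needs an image asset")
        if self.kind == "SOUND" and not self.sound:
            raise RegistryError(f"SOUND object {self.name!r} needs a sound asset")
        if self.kind == "DOT" and (self.size[0] <= 0 or self.size[1] <= 0):
            raise RegistryError(f"DOT object {self.name!r} must have size > 0")


@dataclass(frozen=True)
class PresentationEvent:
    """One handled command: request time, frame-quantized onset, TTL."""

    t_request: int
    t_onset: int
    object_name: str
    token_word: str
    reply_word: str
    ttl: TTLPulse
    sound_onset: int | None = None


def frame_quantize(geom: DisplayGeometry, t_request: int, t0: int = 0) -> int:
    """Smallest frame-boundary time >= t_request.

    Boundaries sit at ``t0 + k * (1e6 / refresh_hz)`` microseconds; the
    result is rounded to the integer microsecond grid of the session log.
    """
    period = geom.frame_period_us
    k = math.ceil((t_request - t0) / period - 1e-9)
    return t0 + round(k * period)


def worst_case_onset_error_ms(geom: DisplayGeometry) -> int:
    """Largest possible request-to-onset delay, truncated to whole ms.

    For a 60-Hz display this is the inherent 16-ms presentation error: a
    request arriving just after a refresh waits almost one full frame.
    """
    return int(geom.frame_period_us // 1000)


class Presenter:
    """Registry + command loop; registers itself as a bus endpoint."""

    def __init__(
        self,
        geom: DisplayGeometry,
        bus: Bus,
        endpoint: str = "presenter",
        aliases: dict[str, str] | None = None,
        audio_latency_us: int = 0,
    ) -> None:
        self.geom = geom
        self.bus = bus
        self.endpoint = endpoint
        self.aliases = dict(aliases or {})
        self.audio_latency_us = audio_latency_us
        self._registry: dict[str, StimulusObject] = {}
        self.events: list[PresentationEvent] = []
        self.current_object: str | None = None
        bus.register_endpoint(endpoint, self._handle)

    # -- registry -----------------------------------------------------------

    def register_object(self, obj: StimulusObject) -> None:
        if obj.name in self._registry:
            raise RegistryError(f"object already registered: {obj.name!r}")
        self._registry[obj.name] = obj

    def resolve(self, word: str) -> StimulusObject:
        name = self.aliases.get(word, word)
        try:
            return self._registry[name]
        except KeyError:
            raise ProtocolError(f"no stimulus object for token word {word!r}") from None

    # -- command loop -------------------------------------------------------

    def _handle(self, word: str, t_request: int) -> str:
        obj = self.resolve(word)  # unknown word raises before any side effect
        t_onset = frame_quantize(self.geom, t_request)
        # the reply fires at presentation time, together with the TTL, so the
        # session clock advances to the frame boundary before either is logged
        self.bus.clock.advance(max(0, t_onset - self.bus.clock.now()))
        ttl = self.bus.emit_ttl(STIMULUS_LINE, t_onset, 1.0, endpoint=self.endpoint)
        sound_onset = None
        if obj.kind in {"SOUND", "IMAGE_SOUND"}:
            sound_onset = t_request + self.audio_latency_us
        reply = f"ack:{word}"
        self.events.append(
            PresentationEvent(
                t_request=t_request,
                t_onset=t_onset,
                object_name=obj.name,
                token_word=word,
                reply_word=reply,
                ttl=ttl,
                sound_onset=sound_onset,
            )
        )
        self.current_object = obj.name
        return reply


def audit_av_sync(events: list[PresentationEvent]) -> list[int]:
    """Image-minus-sound onset offset (us) for each audiovisual event.

    The image waits for the frame boundary while the sound starts at the
    request, so each offset lies in [0, frame period + audio latency).
    """
    return [
        ev.t_onset - ev.sound_onset
        for ev in events
        if ev.sound_onset is not None
    ]
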