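"""Message fabric: serial command/reply tokens and the parallel TTL sideband.

Two message currencies keep the three programs of the rig in lockstep:

* **Tokens** — short ASCII words with a single-character terminator
  (``'grendot\\n'``) sent over the serial path.  Every command must receive
  exactly one reply before the next command is issued; the reply echoes the
  command word prefixed ``ack:``.
* **TTL pulses** — 1-ms low-high-low logic transitions on a named line
  (``parallel.bit8`` for stimulus onsets, ``reward.dio0`` for reward
  delivery).  Their rising edges are the event timestamps the analysis
  aligns spikes to.

In simulation the transport is an in-memory deterministic queue driven by a
single session clock; everything that crosses it lands in a :class:`BusLog`
that can be replayed to verify the lockstep contract after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

MAX_WORD_LEN = 32  # defensive cap; command words in practice are ~7 chars


class ProtocolError(RuntimeError):
    """Violation of the token/TTL contract (routing, lockstep, overlap)."""


class TokenError(ValueError):
    """Malformed token word."""


@dataclass(frozen=True)
class Token:
    """A serial command or reply word plus its terminator character."""

    word: str
    terminator: str = "\n"

    def __post_init__(self) -> None:
        _validate_word(self.word, self.terminator)

    def encode(self) -> bytes:
        return (self.word + self.terminator).encode("ascii")


def _validate_word(word: str, terminator: str = "\n") -> None:
    if not word:
        raise TokenError("token word must be nonempty")
    if len(word) > MAX_WORD_LEN:
        raise TokenError(f"token word longer than {MAX_WORD_LEN} chars: {word!r}")
    if terminator in word:
        raise TokenError(f"token word contains terminator: {word!r}")
    if not all(32 <= ord(c) < 127 for c in word):
        raise TokenError(f"token word not printable ASCII: {word!r}")


def encode_token(word: str, terminator: str = "\n") -> bytes:
    """Encode a command word as transmitted bytes (word + terminator)."""
    _validate_word(word, terminator)
    return (word + terminator).encode("ascii")


def decode_token(data: bytes, terminator: str = "\n") -> str:
    """Exact inverse of :func:`encode_token`."""
    text = data.decode("ascii")
    if not text.endswith(terminator):
        raise TokenError(f"missing terminator in {data!r}")
    word = text[: -len(terminator)]
    _validate_word(word, terminator)
    return word


@dataclass(frozen=True)
class TTLPulse:
    """A logic pulse on a named line; `t` is the rising edge in microseconds."""

    t: int
    line: str
    duration_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("TTLPulse.duration_ms must be > 0")

    @property
    def t_end(self) -> int:
        return self.t + round(self.duration_ms * 1000)


@dataclass(frozen=True)
class BusRecord:
    t_us: int
    endpoint: str
    direction: str  # "tx" | "rx"
    kind: str  # "token" | "ttl"
    payload: object  # Token or TTLPulse

    def to_json(self) -> str:
        if self.kind == "token":
            payload = {"word": self.payload.word, "terminator": self.payload.terminator}
        else:
            payload = {
                "t": self.payload.t,
                "line": self.payload.line,
                "duration_ms": self.payload.duration_ms,
            }
        return json.dumps(
            {
                "t_us": self.t_us,
                "endpoint": self.endpoint,
                "dir": self.direction,
                "kind": self.kind,
                "payload": payload,
            },
            sort_keys=True,
        )


@dataclass
class BusLog:
    """Ordered record of every token and pulse that crossed the bus."""

    records: list[BusRecord] = field(default_factory=list)

    def append(self, rec: BusRecord) -> None:
        if self.records and rec.t_us < self.records[-1].t_us:
            raise ProtocolError(
                f"bus log time went backwards: {rec.t_us} < {self.records[-1].t_us}"
            )
        self.records.append(rec)

    def tokens(self) -> list[BusRecord]:
        return [r for r in self.records if r.kind == "token"]

    def pulses(self, line: str | None = None) -> list[TTLPulse]:
        out = [r.payload for r in self.records if r.kind == "ttl"]
        if line is not None:
            out = [p for p in out if p.line == line]
        return out

    def to_jsonl(self) -> str:
        return "\n".join(r.to_json() for r in self.records) + ("\n" if self.records else "")


class Clock:
    """Monotone session clock in integer microseconds."""

    def __init__(self, t0: int = 0) -> None:
        self.t = int(t0)

    def now(self) -> int:
        return self.t

    def advance(self, dt_us: int) -> int:
        if dt_us < 0:
            raise ValueError("clock cannot run backwards")
        self.t += int(dt_us)
        return self.t


class Bus:
    """Deterministic in-memory transport between named endpoints.

    Endpoints register a handler ``handler(word, t_request) -> reply word``.
    :meth:`send_command` enforces the lockstep contract: a second command
    from the same endpoint while one is outstanding is a protocol error, as
    is routing to an endpoint with no handler for the word.  TTL lines track
    the last pulse end so overlapping pulses on one line raise.
    """

    def __init__(self, clock: Clock | None = None) -> None:
        self.clock = clock if clock is not None else Clock()
        self.log = BusLog()
        self._handlers: dict[str, Callable[[str, int], str]] = {}
        self._outstanding: set[str] = set()
        self._line_busy_until: dict[str, int] = {}

    def register_endpoint(self, name: str, handler: Callable[[str, int], str]) -> None:
        if name in self._handlers:
            raise ProtocolError(f"endpoint already registered: {name}")
        self._handlers[name] = handler

    def send_command(self, src: str, dst: str, tok: Token) -> Token:
        """Send `tok` from `src` to `dst` and block (logically) for the reply."""
        if src in self._outstanding:
            raise ProtocolError(f"endpoint {src} already has an outstanding command")
        if dst not in self._handlers:
            raise ProtocolError(f"no endpoint registered as {dst}")
        t = self.clock.now()
        self._outstanding.add(src)
        self.log.append(BusRecord(t, src, "tx", "token", tok))
        try:
            reply_word = self._handlers[dst](tok.word, t)
        finally:
            self._outstanding.discard(src)
        reply = Token(reply_word, tok.terminator)
        self.log.append(BusRecord(self.clock.now(), dst, "tx", "token", reply))
        return reply

    def emit_ttl(self, line: str, t: int, duration_ms: float = 1.0, endpoint: str = "") -> TTLPulse:
        """Log a pulse on `line` with rising edge at `t` microseconds."""
        busy_until = self._line_busy_until.get(line, -1)
        if t < busy_until:
            raise ProtocolError(
                f"pulse on {line} at {t} us overlaps previous pulse ending {busy_until} us"
            )
        pulse = TTLPulse(t=int(t), line=line, duration_ms=duration_ms)
        self._line_busy_until[line] = pulse.t_end
        self.log.append(BusRecord(max(t, self.clock.now()), endpoint or line, "tx", "ttl", pulse))
        return pulse


def verify_lockstep(log: BusLog, stimulus_line: str = "parallel.bit8") -> None:
    """Replay a bus log and assert the lockstep contract.

    Checks, raising :class:`ProtocolError` on the first violation:

    1. tokens alternate command/reply (every command word is answered by its
       ``ack:``-prefixed echo before the next command appears);
    2. every stimulus change has exactly one command token, one reply token
       and one TTL pulse on `stimulus_line`, with the pulse's rising edge at
       or after the command time.
    """
    toks = log.tokens()
    pulses = log.pulses(stimulus_line)
    commands: list[BusRecord] = []
    expecting_reply_for: str | None = None
    for rec in toks:
        word = rec.payload.word
        if expecting_reply_for is None:
            if word.startswith("ack:"):
                raise ProtocolError(f"reply {word!r} with no pending command")
            commands.append(rec)
            expecting_reply_for = word
        else:
            if word != f"ack:{expecting_reply_for}":
                raise ProtocolError(
                    f"expected reply 'ack:{expecting_reply_for}', saw {word!r}"
                )
            expecting_reply_for = None
    if expecting_reply_for is not None:
        raise ProtocolError(f"command {expecting_reply_for!r} never answered")
    if len(pulses) != len(commands):
        raise ProtocolError(
            f"{len(commands)} stimulus commands but {len(pulses)} pulses on {stimulus_line}"
        )
    for cmd, pulse in zip(commands, pulses):
        if pulse.t < cmd.t_us:
            raise ProtocolError(
                f"TTL rising edge {pulse.t} us precedes its command at {cmd.t_us} us"
            )
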