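"""Hardware abstraction: touch hit-testing, audio cues, and the two-node
peripheral cue protocol.

The deployed rig splits in two: the screen node runs the task and sends
single-character cue tokens over a radio link; the peripheral node maps
tokens to outputs — by default ``"1"`` cycles the pellet dispenser once and
``"2"`` turns the tone generator on for 1 s. Here the link is modeled as an
ordered, lossless channel with an optional stray-token injector (radio
pickup of signals from other electronics is a real failure mode), and the
physical transport is a plug-in point behind :class:`Transport`.

Buttons respond on the *initial press*, never on release: pigs press and
then swipe upward, so release points land off-button. For the same reason
a box may expose an invisible touch region extending above its visible
rectangle (``hit_extension_above``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ResponseBox, ScreenGeometry, SessionContext, encode_payload

__all__ = [
    "TouchEvent",
    "PeripheralCommand",
    "PeripheralState",
    "AudioCue",
    "DEFAULT_CUE_TABLE",
    "TONE_DURATION_S",
    "AUDIO_CUES",
    "hit_test",
    "dispatch_cue",
    "tone_active",
    "watchdog_tick",
    "play_cue",
    "Transport",
    "MockTransport",
    "PeripheralController",
]

TONE_DURATION_S = 1.0

#: token -> action; overridable from the session config.
DEFAULT_CUE_TABLE: dict[str, str] = {"1": "pellet", "2": "tone"}

#: speaker cue definitions: purpose -> (frequency Hz, duration s).
#: 2900 Hz on every registered press, 7500 Hz at trial start; the
#: reinforcement cue reuses the press-feedback pitch.
AUDIO_CUES: dict[str, tuple[float, float]] = {
    "response_feedback": (2900.0, 0.2),
    "trial_start": (7500.0, 0.5),
    "reinforcement": (2900.0, 1.0),
}


@dataclass(frozen=True)
class TouchEvent:
    """A raw screen contact; ``kind`` is ``press`` or ``release``."""

    x: float
    y: float
    kind: str
    timestamp: float

    def __post_init__(self):
        if self.kind not in ("press", "release"):
            raise ValueError(f"touch kind must be press or release, got {self.kind!r}")
        if not (0 <= self.x <= 1 and 0 <= self.y <= 1):
            raise ValueError("touch must lie within the unit square")


@dataclass(frozen=True)
class PeripheralCommand:
    """A cue token sent over the transceiver link."""

    cue: str
    issued_at: float


@dataclass
class PeripheralState:
    """Outputs on the receiving node.

    The optional watchdog mirrors a hardening suggestion for stray-signal
    pickup: any output left on longer than ``watchdog_timeout`` seconds
    without a refreshing cue is forced off.
    """

    pellet_cycles: int = 0
    tone_on_until: Optional[float] = None
    watchdog_timeout: Optional[float] = None
    last_refresh_at: Optional[float] = None


@dataclass(frozen=True)
class AudioCue:
    frequency: float
    duration: float
    purpose: str

    def __post_init__(self):
        if self.frequency <= 0 or self.duration <= 0:
            raise ValueError("audio cues need positive frequency and duration")


# ---------------------------------------------------------------------------
# Hit testing
# ---------------------------------------------------------------------------


def hit_test(geometry: ScreenGeometry, touch: TouchEvent) -> Optional[ResponseBox]:
    """Return the active box whose touch region contains a *press*, else None.

    Release events never register (press-on-touch semantics); the touch
    region is the visible rectangle extended upward by the box's
    ``hit_extension_above``.
    """
    if touch.kind != "press":
        return None
    for box in geometry.boxes:
        if box.active and box.contains(touch.x, touch.y):
            return box
    return None


# ---------------------------------------------------------------------------
# Peripheral cue protocol
# ---------------------------------------------------------------------------


def dispatch_cue(
    state: PeripheralState,
    cmd: PeripheralCommand,
    ctx: SessionContext,
    cue_table: Optional[dict[str, str]] = None,
    *,
    noncontingent: bool = False,
) -> PeripheralState:
    """Act on a received cue token and log the resulting device event.

    ``"1"`` (pellet) increments the cycle count and emits a
    ``pellet_command`` event; ``"2"`` (tone) sets the tone on for 1 s from
    now and emits a ``tone`` event — a second tone cue while on extends the
    off time (non-retriggerable extension). Unknown tokens change no output
    and are logged as stray-signal ``manual_note`` events, never fatal.
    """
    table = DEFAULT_CUE_TABLE if cue_table is None else cue_table
    action = table.get(cmd.cue)
    now = ctx.clock.now
    if action == "pellet":
        state.pellet_cycles += 1
        payload = {"cue": cmd.cue}
        if noncontingent:
            payload["noncontingent"] = 1
        ctx.emit("pellet_command", payload=encode_payload(payload))
        state.last_refresh_at = now
    elif action == "tone":
        state.tone_on_until = now + TONE_DURATION_S
        ctx.emit(
            "tone",
            payload=encode_payload(
                {"cue": cmd.cue, "source": "sonalert", "duration_s": TONE_DURATION_S}
            ),
        )
        state.last_refresh_at = now
    else:
        ctx.emit("manual_note", payload=encode_payload({"stray_cue": cmd.cue}))
    return state


def tone_active(state: PeripheralState, now: float) -> bool:
    """Tone is on iff ``now`` is before ``tone_on_until``."""
    return state.tone_on_until is not None and now < state.tone_on_until


def watchdog_tick(state: PeripheralState, now: float, ctx: Optional[SessionContext] = None) -> PeripheralState:
    """Force outputs off if no refreshing cue arrived within the timeout."""
    if state.watchdog_timeout is None:
        return state
    ref = state.last_refresh_at
    if ref is None or now - ref <= state.watchdog_timeout:
        return state
    if tone_active(state, now):
        state.tone_on_until = None
        if ctx is not None:
            ctx.emit("manual_note", payload=encode_payload({"watchdog": "tone_forced_off"}))
    return state


# ---------------------------------------------------------------------------
# Speaker cues
# ---------------------------------------------------------------------------


def play_cue(purpose: str, ctx: SessionContext) -> AudioCue:
    """Emit the speaker tone for ``purpose`` and log it as a tone event."""
    try:
        freq, dur = AUDIO_CUES[purpose]
    except KeyError:
        raise ValueError(f"no audio cue configured for purpose {purpose!r}") from None
    cue = AudioCue(frequency=freq, duration=dur, purpose=purpose)
    ctx.emit(
        "tone",
        payload=encode_payload(
            {"source": "speaker", "purpose": purpose, "freq_hz": freq, "duration_s": dur}
        ),
    )
    return cue


# ---------------------------------------------------------------------------
# Transport abstraction
# ---------------------------------------------------------------------------


class Transport:
    """Plug-in point for the physical cue link (radio, GPIO, ...)."""

    def send(self, token: str, now: float) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class PeripheralController:
    """The receiving node: maps incoming tokens to outputs via the cue table."""

    def __init__(
        self,
        ctx: SessionContext,
        state: Optional[PeripheralState] = None,
        cue_table: Optional[dict[str, str]] = None,
    ):
        self.ctx = ctx
        self.state = state if state is not None else PeripheralState()
        self.cue_table = dict(DEFAULT_CUE_TABLE if cue_table is None else cue_table)
        self.received: list[PeripheralCommand] = []

    def receive(self, token: str, now: float, *, noncontingent: bool = False) -> PeripheralState:
        cmd = PeripheralCommand(cue=token, issued_at=now)
        self.received.append(cmd)
        watchdog_tick(self.state, now, self.ctx)
        return dispatch_cue(self.state, cmd, self.ctx, self.cue_table, noncontingent=noncontingent)


@dataclass
class MockTransport(Transport):
    """Ordered, lossless in-process link with optional stray-token injection.

    ``stray_rate`` is the per-send probability that an interference token
    (drawn from ``stray_tokens``) is delivered immediately before the real
    one — a test hook for protocol robustness.
    """

    controller: PeripheralController
    stray_rate: float = 0.0
    stray_tokens: tuple[str, ...] = ("9", "7", "x")
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    noncontingent_next: bool = False

    def send(self, token: str, now: float) -> None:
        if self.stray_rate > 0 and self.rng.random() < self.stray_rate:
            stray = str(self.rng.choice(list(self.stray_tokens)))
            self.controller.receive(stray, now)
        nc = self.noncontingent_next
        self.noncontingent_next = False
        self.controller.receive(token, now, noncontingent=nc)

    def send_pellet(self, now: float, *, noncontingent: bool = False) -> None:
        self.noncontingent_next = noncontingent
        self.send("1", now)

    def send_tone(self, now: float) -> None:
        self.send("2", now)


def make_peripherals(
    ctx: SessionContext,
    *,
    watchdog_timeout: Optional[float] = None,
    cue_table: Optional[dict[str, str]] = None,
    stray_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> MockTransport:
    """Convenience: a mock link wired to a fresh peripheral controller."""
    state = PeripheralState(watchdog_timeout=watchdog_timeout)
    controller = PeripheralController(ctx, state, cue_table)
    return MockTransport(
        controller=controller,
        stray_rate=stray_rate,
        rng=rng if rng is not None else np.random.default_rng(0),
    )
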