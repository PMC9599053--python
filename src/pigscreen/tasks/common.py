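"""Trial specifications and primitives shared by the task state machines."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from ..core import ResponseBox, ScreenGeometry, SessionContext, encode_payload
from ..hal import hit_test, play_cue

__all__ = [
    "OptionSpec",
    "TrialSpec",
    "fr_register",
    "balanced_side_sequence",
    "PressOutcome",
    "press_until_fulfilled",
]


@dataclass(frozen=True)
class OptionSpec:
    """One selectable outcome in a trial (a button the subject may choose).

    ``magnitude`` is the reinforcer count delivered on selection and
    ``delay`` the seconds between selection and delivery. ``is_correct``
    marks the reinforced option in discrimination trials; inactive options
    are rendered but cannot be chosen (their box is gray and dead).
    """

    id: str
    side: Optional[str] = None
    color: Optional[str] = None
    magnitude: float = 1.0
    delay: float = 0.0
    active: bool = True
    fr: int = 1
    is_correct: Optional[bool] = None

    def __post_init__(self):
        if self.side not in (None, "left", "right", "center"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.magnitude < 0 or self.delay < 0 or self.fr < 1:
            raise ValueError("magnitude, delay >= 0 and fr >= 1 required")


@dataclass(frozen=True)
class TrialSpec:
    """The planned configuration of one trial."""

    trial_index: int
    trial_type: str
    options: tuple[OptionSpec, ...] = ()
    block_index: int = 0
    delay: float = 0.0
    sample_color: Optional[str] = None

    def active_options(self) -> tuple[OptionSpec, ...]:
        return tuple(o for o in self.options if o.active)

    def with_index(self, trial_index: int) -> "TrialSpec":
        return replace(self, trial_index=trial_index)


def fr_register(box: ResponseBox, press: bool = True) -> tuple[ResponseBox, bool]:
    """Count one registered press toward the box's fixed-ratio requirement.

    Returns the box and whether the ratio was fulfilled; on fulfilment the
    counter resets, so under FR-n a run of p presses fulfils floor(p / n)
    times.
    """
    if not box.active:
        raise ValueError(f"box {box.id!r} is inactive and cannot register presses")
    if not press:
        return box, False
    box.fr_count += 1
    if box.fr_count >= box.fr_requirement:
        box.fr_count = 0
        return box, True
    return box, False


def balanced_side_sequence(
    n: int,
    rng: np.random.Generator,
    *,
    block: int = 6,
    max_run: int = 3,
) -> list[str]:
    """Pseudorandom left/right sequence: balanced within blocks, run-capped.

    Each block of ``block`` trials holds equal left and right assignments
    in shuffled order, and no more than ``max_run`` consecutive trials share
    a side (checked across block boundaries). Blocks are redrawn until the
    run constraint holds, which terminates quickly for max_run >= 2.
    """
    if block % 2:
        raise ValueError("side-balance block size must be even")
    sides: list[str] = []
    while len(sides) < n:
        for _ in range(10_000):
            cand = ["left"] * (block // 2) + ["right"] * (block // 2)
            rng.shuffle(cand)
            if _max_run(sides[-max_run:] + cand) <= max_run:
                sides.extend(cand)
                break
        else:  # pragma: no cover - unreachable for max_run >= 2
            raise RuntimeError("could not satisfy side-run constraint")
    return sides[:n]


@dataclass
class PressOutcome:
    """Result of a press-interaction loop on one layout."""

    box: Optional[ResponseBox] = None  # the box whose FR was fulfilled
    first_press_t: Optional[float] = None  # first *registered* press time
    fulfilled_t: Optional[float] = None
    presses_registered: int = 0


def press_until_fulfilled(
    agent,
    geometry: ScreenGeometry,
    ctx: SessionContext,
    deadline: float,
    *,
    aim: Optional[ResponseBox] = None,
    extra_for: Optional[Callable[[ResponseBox], dict]] = None,
    feedback: bool = True,
) -> PressOutcome:
    """Let the agent press at the layout until some box's FR is fulfilled.

    Each attempt advances the simulated clock by an agent latency draw,
    logs the raw press/release touches, hit-tests the press, and — if a
    box registers — logs a ``response_registered`` event and plays the
    2900 Hz press-feedback cue. Whichever active box fulfils its fixed
    ratio first wins (a scattered press that lands on the other option
    counts toward that option, as it would on the real screen). Returns
    an unfulfilled outcome once the next attempt would pass ``deadline``;
    the clock is then advanced to the deadline.
    """
    out = PressOutcome()
    while True:
        latency = agent.draw_latency()
        t_next = ctx.clock.now + latency
        if t_next > deadline:
            ctx.clock.advance(max(0.0, deadline - ctx.clock.now))
            return out
        ctx.clock.advance(latency)
        press, release = agent.emit_touch(aim, ctx.clock.now)
        ctx.emit("touch", x=press.x, y=press.y, payload=encode_payload({"kind": "press"}))
        hit = hit_test(geometry, press)
        ctx.emit("touch", x=release.x, y=release.y, payload=encode_payload({"kind": "release"}))
        if hit is None:
            continue
        out.presses_registered += 1
        if out.first_press_t is None:
            out.first_press_t = ctx.clock.now
        _, fulfilled = fr_register(hit)
        payload = {"box": hit.id, "fulfilled": int(fulfilled)}
        if fulfilled and extra_for is not None:
            payload.update(extra_for(hit))
        ctx.emit(
            "response_registered",
            x=press.x,
            y=press.y,
            payload=encode_payload(payload),
        )
        if feedback:
            play_cue("response_feedback", ctx)
        if fulfilled:
            out.box = hit
            out.fulfilled_t = ctx.clock.now
            return out


def _max_run(seq: list[str]) -> int:
    best = run = 0
    prev = None
    for s in seq:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best
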