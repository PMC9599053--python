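"""Response shaping: stages 0-3, with an optional stage 4.

The shaping program trains naive pigs to press illuminated boxes on the
screen, in automatic stages:

* **Stage 0** — Pavlovian autoshaping: the whole screen illuminates yellow
  and a pellet arrives 10 s later regardless of behavior; concurrently an
  FR-1 schedule reinforces any screen press immediately. 20 reinforced
  presses advance to stage 1.
* **Stage 1** — presses are reinforced only while the screen is
  illuminated (FR-1); 15 presses advance.
* **Stage 2** — the box shrinks to a yellow band occupying 1/3 of the
  screen height, placed at one of three heights at random; 15 presses
  advance.
* **Stage 3** — a yellow square of side 40% of screen width at one of five
  positions (four corner-offset, one center); after 40 presses the subject
  is ready for testing. The ratio may be raised to FR-3/FR-5 here if later
  tasks need it.
* **Stage 4** (optional) — the square shrinks by a fixed decrement per
  consecutive reinforced trial, to shape precision toward smaller targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..core import ResponseBox, ScreenGeometry, SessionContext, TrialResult, encode_payload
from ..hal import MockTransport, play_cue
from .common import press_until_fulfilled

__all__ = [
    "ShapingConfig",
    "ShapingState",
    "DEFAULT_THRESHOLDS",
    "shaping_geometry",
    "shaping_advance",
    "autoshape_step",
    "shaping_press_step",
]

#: Reinforced presses required to leave stages 0..3 (stage 4 reuses the
#: stage-3 count when enabled).
DEFAULT_THRESHOLDS = (20, 15, 15, 40)

STAGE2_HEIGHTS = (0.0, 1 / 3, 2 / 3)
STAGE3_SIZE = 0.40
_CORNER_OFFSET = 0.05


@dataclass(frozen=True)
class ShapingConfig:
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    fr: int = 1
    start_stage: int = 0
    autoshape_delay_s: float = 10.0
    response_window_s: float = 60.0
    iti_s: float = 15.0
    hit_extension_above: float = 0.0
    stage4_enabled: bool = False
    stage4_decrement: float = 0.02
    stage4_min_size: float = 0.22  # pigs track squares down to ~22% of screen height
    stage4_threshold: int = 40

    def __post_init__(self):
        if len(self.thresholds) != 4 or any(t < 1 for t in self.thresholds):
            raise ValueError("thresholds must be four positive press counts")
        if self.start_stage not in (0, 1, 2, 3, 4):
            raise ValueError("start_stage must be in 0..4")
        if self.fr < 1:
            raise ValueError("fr must be >= 1")

    def threshold(self, stage: int) -> int:
        return self.stage4_threshold if stage == 4 else self.thresholds[stage]


@dataclass
class ShapingState:
    """Where the subject is in the shaping progression.

    ``stage`` never decreases within a session; ``presses_in_stage`` is
    always below the current stage's threshold between advances.
    """

    stage: int = 0
    presses_in_stage: int = 0
    complete: bool = False
    box_size: float = STAGE3_SIZE  # current square side, used by stage 4
    consecutive_correct: int = 0


def _square_positions(size: float) -> list[tuple[float, float]]:
    off = _CORNER_OFFSET
    far = 1.0 - off - size
    mid = (1.0 - size) / 2
    return [(off, off), (far, off), (off, far), (far, far), (mid, mid)]


def shaping_geometry(
    stage: int,
    rng: np.random.Generator,
    *,
    box_size: Optional[float] = None,
    hit_extension_above: float = 0.0,
    fr: int = 1,
) -> tuple[ScreenGeometry, int]:
    """The illuminated layout for a shaping trial, plus its position index.

    Stages 0/1 illuminate the full screen; stage 2 draws one of three
    band heights uniformly; stages 3/4 draw one of five square positions
    uniformly (independent draws; immediate repeats are allowed).
    """
    if stage in (0, 1):
        box = ResponseBox("screen", 0.0, 0.0, 1.0, 1.0, "yellow", fr_requirement=fr)
        return ScreenGeometry([box]), 0
    if stage == 2:
        pos = int(rng.integers(len(STAGE2_HEIGHTS)))
        box = ResponseBox(
            "band",
            0.0,
            STAGE2_HEIGHTS[pos],
            1.0,
            1 / 3,
            "yellow",
            hit_extension_above=hit_extension_above,
            fr_requirement=fr,
        )
        return ScreenGeometry([box]), pos
    if stage in (3, 4):
        size = STAGE3_SIZE if stage == 3 else (box_size if box_size is not None else STAGE3_SIZE)
        positions = _square_positions(size)
        pos = int(rng.integers(len(positions)))
        x, y = positions[pos]
        box = ResponseBox(
            "square",
            x,
            y,
            size,
            size,
            "yellow",
            hit_extension_above=hit_extension_above,
            fr_requirement=fr,
        )
        return ScreenGeometry([box]), pos
    raise ValueError(f"invalid shaping stage {stage}")


def shaping_advance(
    state: ShapingState,
    config: ShapingConfig,
    ctx: Optional[SessionContext] = None,
) -> tuple[ShapingState, bool]:
    """Credit one reinforced press; advance the stage at its threshold.

    Returns the state and whether a stage boundary was crossed. Crossing
    the stage-3 threshold marks the subject ready for testing (or enters
    stage 4 when enabled); a ``stage_advance`` event is logged either way.
    """
    if state.complete:
        raise ValueError("shaping already complete")
    state.presses_in_stage += 1
    if state.presses_in_stage < config.threshold(state.stage):
        return state, False
    old = state.stage
    state.presses_in_stage = 0
    if state.stage < 3:
        state.stage += 1
    elif state.stage == 3 and config.stage4_enabled:
        state.stage = 4
        state.box_size = STAGE3_SIZE
        state.consecutive_correct = 0
    else:
        state.complete = True
    if ctx is not None:
        payload = {"from_stage": old}
        if state.complete:
            payload["complete"] = 1
        else:
            payload["to_stage"] = state.stage
        ctx.emit("stage_advance", payload=encode_payload(payload))
    return state, True


def autoshape_step(
    state: ShapingState,
    config: ShapingConfig,
    ctx: SessionContext,
    agent,
    link: MockTransport,
    trial_index: int,
) -> TrialResult:
    """One stage-0 illumination: Pavlovian delivery with a concurrent FR-1.

    If no press occurs within ``autoshape_delay_s`` of illumination, one
    noncontingent pellet is delivered exactly at the delay. A press
    anywhere on the screen before then is reinforced immediately and
    cancels the pending Pavlovian delivery — at most one delivery per
    illumination, and only contingent deliveries count toward the stage
    threshold.
    """
    if state.stage != 0:
        raise ValueError("autoshape_step requires stage 0")
    ctx.trial_index = trial_index
    start = ctx.clock.now
    ctx.emit("trial_start", payload=encode_payload({"trial_type": "autoshape", "stage": 0}))
    play_cue("trial_start", ctx)
    geometry, _ = shaping_geometry(0, np.random.default_rng(0))
    deadline = start + config.autoshape_delay_s

    outcome = None
    if not agent.will_omit():
        outcome = press_until_fulfilled(agent, geometry, ctx, deadline, aim=geometry.boxes[0])
    if outcome is not None and outcome.box is not None:
        ctx.emit("reinforcement", payload=encode_payload({"n": 1, "contingency": "fr1"}))
        link.send_pellet(ctx.clock.now)
        shaping_advance(state, config, ctx)
        return TrialResult(
            trial_index=trial_index,
            trial_type="autoshape",
            choice="none",
            initiation_latency=outcome.first_press_t - start,
            reinforcers_delivered=1,
        )
    # no contact: deliver the Pavlovian pellet exactly at the delay
    if hasattr(ctx.clock, "advance_to"):
        ctx.clock.advance_to(deadline)
    else:
        ctx.clock.advance(max(0.0, deadline - ctx.clock.now))
    link.send_pellet(ctx.clock.now, noncontingent=True)
    return TrialResult(trial_index=trial_index, trial_type="autoshape", choice="none")


def shaping_press_step(
    state: ShapingState,
    config: ShapingConfig,
    ctx: SessionContext,
    agent,
    link: MockTransport,
    rng: np.random.Generator,
    trial_index: int,
) -> TrialResult:
    """One operant shaping trial for stages 1-4.

    The stage's layout illuminates with the trial-start cue; fulfilling
    the box's fixed ratio within the response window earns one pellet and
    credits the stage counter. No fulfilment within the window is an
    omission. In stage 4, each reinforced trial shrinks the square by the
    configured decrement (down to the minimum size) and an omission resets
    it to the stage-3 size.
    """
    if state.stage == 0:
        raise ValueError("use autoshape_step for stage 0")
    ctx.trial_index = trial_index
    start = ctx.clock.now
    geometry, pos = shaping_geometry(
        state.stage,
        rng,
        box_size=state.box_size,
        hit_extension_above=config.hit_extension_above,
        fr=config.fr,
    )
    box = geometry.boxes[0]
    ctx.emit(
        "trial_start",
        payload=encode_payload(
            {
                "trial_type": "shaping_press",
                "stage": state.stage,
                "position": pos,
                "box_size": round(box.w, 4),
            }
        ),
    )
    play_cue("trial_start", ctx)
    deadline = start + config.response_window_s

    outcome = None
    if not agent.will_omit():
        outcome = press_until_fulfilled(agent, geometry, ctx, deadline, aim=box)
    if outcome is None or outcome.box is None:
        if hasattr(ctx.clock, "advance_to"):
            ctx.clock.advance_to(deadline)
        ctx.emit("omission", payload=encode_payload({"stage": state.stage}))
        if state.stage == 4:
            state.consecutive_correct = 0
            state.box_size = STAGE3_SIZE
        return TrialResult(trial_index=trial_index, trial_type="shaping_press", omitted=True)

    ctx.emit("reinforcement", payload=encode_payload({"n": 1, "contingency": f"fr{config.fr}"}))
    link.send_pellet(ctx.clock.now)
    if state.stage == 4:
        state.consecutive_correct += 1
        state.box_size = max(config.stage4_min_size, state.box_size - config.stage4_decrement)
    shaping_advance(state, config, ctx)
    return TrialResult(
        trial_index=trial_index,
        trial_type="shaping_press",
        initiation_latency=outcome.first_press_t - start,
        choice_latency=outcome.fulfilled_t - start,
        reinforcers_delivered=1,
    )
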