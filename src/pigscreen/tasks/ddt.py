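"""Delay discounting task (DDT): choice impulsivity via Large-vs-Small choice.

Two buttons are offered: *Large* delivers 4 pellets, *Small* 1 pellet.
Each session is built from blocks of 12 trials (6 forced-choice exposing
each option, then 6 free-choice), and the delay to the Large reinforcer
steps up across blocks — by default 0, 5, 10 and 20 s, incrementing every
12 trials. A magnitude discrimination (Large preference training) is the
same session with the single delay 0. Button reversal (swapping which
side carries Large) is a pure config transform used between phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ..core import ResponseBox, ScreenGeometry, SessionContext, TrialResult, encode_payload
from ..hal import MockTransport, play_cue
from .common import OptionSpec, TrialSpec, press_until_fulfilled

__all__ = [
    "DDTConfig",
    "DDTState",
    "build_ddt_session",
    "reverse_buttons",
    "magnitude_discrimination",
    "run_ddt_trial",
]

_BOX_W, _BOX_H, _BOX_Y = 0.28, 0.30, 0.35
_LEFT_X, _RIGHT_X = 0.08, 0.64


@dataclass(frozen=True)
class DDTConfig:
    """Session structure for the delay discounting task.

    ``delays`` must be strictly increasing; every block holds
    ``forced_per_block`` forced + ``free_per_block`` free trials. The
    intertrial interval is kept under 20 s so competing exploration does
    not take over.
    """

    large_magnitude: int = 4
    small_magnitude: int = 1
    delays: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    trials_per_block: int = 12
    forced_per_block: int = 6
    free_per_block: int = 6
    large_side: str = "left"
    iti_s: float = 15.0
    response_window_s: float = 60.0
    hit_extension_above: float = 0.0
    pellet_cycle_s: float = 0.5

    def __post_init__(self):
        if self.forced_per_block + self.free_per_block != self.trials_per_block:
            raise ValueError("forced_per_block + free_per_block must equal trials_per_block")
        if self.forced_per_block % 2:
            raise ValueError("forced_per_block must be even (half Large-only, half Small-only)")
        if any(b <= a for a, b in zip(self.delays, self.delays[1:])):
            raise ValueError("delays must be strictly increasing")
        if not self.delays or self.delays[0] < 0:
            raise ValueError("at least one non-negative delay is required")
        if self.large_side not in ("left", "right"):
            raise ValueError("large_side must be 'left' or 'right'")
        if self.large_magnitude <= self.small_magnitude:
            raise ValueError("Large must deliver more pellets than Small")
        if self.iti_s <= 0:
            raise ValueError("iti_s must be positive")

    @property
    def small_side(self) -> str:
        return "right" if self.large_side == "left" else "left"


def reverse_buttons(config: DDTConfig) -> DDTConfig:
    """Swap which side carries the Large button (an involution)."""
    return replace(config, large_side=config.small_side)


def magnitude_discrimination(config: DDTConfig) -> DDTConfig:
    """The same session structure with no delays (Large-preference training)."""
    return replace(config, delays=(0.0,))


@dataclass
class DDTState:
    """Progress through a DDT session plan."""

    phase: str = "discounting"  # or "magnitude_discrimination"
    block_index: int = 0
    trial_in_block: int = 0
    current_delay: float = 0.0

    def advance(self, spec: TrialSpec, config: DDTConfig) -> None:
        self.block_index = spec.block_index
        self.current_delay = config.delays[spec.block_index]
        self.trial_in_block = spec.trial_index - spec.block_index * config.trials_per_block


def _options(config: DDTConfig, delay: float, *, forced: Optional[str] = None) -> tuple[OptionSpec, OptionSpec]:
    large = OptionSpec(
        id="large",
        side=config.large_side,
        color="yellow",
        magnitude=config.large_magnitude,
        delay=delay,
        active=forced in (None, "large"),
    )
    small = OptionSpec(
        id="small",
        side=config.small_side,
        color="yellow",
        magnitude=config.small_magnitude,
        delay=0.0,
        active=forced in (None, "small"),
    )
    return large, small


def build_ddt_session(config: DDTConfig, rng: np.random.Generator) -> list[TrialSpec]:
    """Plan a full session: one block per delay, ascending.

    Each block opens with the forced trials (half Large-only, half
    Small-only, order shuffled) followed by the free-choice trials; the
    block's delay applies to the Large option only.
    """
    specs: list[TrialSpec] = []
    idx = 0
    for b, delay in enumerate(config.delays):
        forced_kinds = ["large"] * (config.forced_per_block // 2) + ["small"] * (
            config.forced_per_block // 2
        )
        rng.shuffle(forced_kinds)
        for kind in forced_kinds:
            specs.append(
                TrialSpec(
                    trial_index=idx,
                    trial_type="forced_choice",
                    options=_options(config, delay, forced=kind),
                    block_index=b,
                    delay=delay,
                )
            )
            idx += 1
        for _ in range(config.free_per_block):
            specs.append(
                TrialSpec(
                    trial_index=idx,
                    trial_type="free_choice",
                    options=_options(config, delay),
                    block_index=b,
                    delay=delay,
                )
            )
            idx += 1
    return specs


def _geometry(spec: TrialSpec, config: DDTConfig) -> ScreenGeometry:
    boxes = []
    for o in spec.options:
        x = _LEFT_X if o.side == "left" else _RIGHT_X
        boxes.append(
            ResponseBox(
                o.id,
                x,
                _BOX_Y,
                _BOX_W,
                _BOX_H,
                o.color if o.active else "inactive_gray",
                active=o.active,
                hit_extension_above=config.hit_extension_above,
            )
        )
    return ScreenGeometry(boxes)


def run_ddt_trial(
    spec: TrialSpec,
    config: DDTConfig,
    ctx: SessionContext,
    agent,
    link: MockTransport,
) -> TrialResult:
    """Run one DDT trial against an agent.

    The trial-start cue (7500 Hz) marks button availability; both boxes
    render, with the unavailable one inactive (gray, dead) on forced
    trials. A registered Large choice schedules ``large_magnitude``
    pellet cycles after the block's delay; Small delivers immediately.
    No registered choice within the response window is an omission.
    """
    ctx.trial_index = spec.trial_index
    start = ctx.clock.now
    ctx.emit(
        "trial_start",
        payload=encode_payload(
            {
                "trial_type": spec.trial_type,
                "block": spec.block_index,
                "delay_s": spec.delay,
                "large_side": config.large_side,
            }
        ),
    )
    play_cue("trial_start", ctx)
    geometry = _geometry(spec, config)
    deadline = start + config.response_window_s
    by_id = {o.id: o for o in spec.options}

    outcome = None
    if not agent.will_omit():
        target_opt = agent.choose(spec.active_options())
        outcome = press_until_fulfilled(
            agent,
            geometry,
            ctx,
            deadline,
            aim=geometry.box(target_opt.id),
            extra_for=lambda box: {
                "choice": box.id,
                "side": by_id[box.id].side,
                "color": by_id[box.id].color,
            },
        )
    if outcome is None or outcome.box is None:
        if hasattr(ctx.clock, "advance_to"):
            ctx.clock.advance_to(deadline)
        ctx.emit("omission", payload=encode_payload({"trial_type": spec.trial_type}))
        return TrialResult(
            trial_index=spec.trial_index,
            trial_type=spec.trial_type,
            omitted=True,
            block_index=spec.block_index,
            delay=spec.delay,
        )

    chosen = by_id[outcome.box.id]
    if chosen.delay > 0:
        ctx.clock.advance(chosen.delay)
    ctx.emit(
        "reinforcement",
        payload=encode_payload({"n": int(chosen.magnitude), "choice": chosen.id}),
    )
    for i in range(int(chosen.magnitude)):
        link.send_pellet(ctx.clock.now)
        if i < chosen.magnitude - 1:
            ctx.clock.advance(config.pellet_cycle_s)
    return TrialResult(
        trial_index=spec.trial_index,
        trial_type=spec.trial_type,
        choice=chosen.id,
        choice_side=chosen.side,
        choice_color=chosen.color,
        initiation_latency=outcome.first_press_t - start,
        choice_latency=outcome.fulfilled_t - start,
        reinforcers_delivered=int(chosen.magnitude),
        block_index=spec.block_index,
        delay=spec.delay,
    )
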