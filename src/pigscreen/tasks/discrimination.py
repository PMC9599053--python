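"""Color discrimination task: simple, correction, and conditional phases.

A trial starts with a center (sample/observing) box; fulfilling its fixed
ratio brings up two choice boxes, left and right, with sides assigned
pseudorandomly (balanced within blocks of six, runs capped). In the
*simple* phase yellow is the reinforced color and blue the comparison.
The *correction* phase adds correction trials: an incorrect choice
immediately re-presents the identical layout with the incorrect box
rendered inactive (visible but gray and dead), so the subject can only
complete it correctly. The *conditional* (match-to-sample) phase shows a
green or blue sample in the center and reinforces only choices of that
color; an FR-3 requirement on sample and choice buttons may be added to
increase salience. Correction trials are excluded from the accuracy
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ..core import ResponseBox, ScreenGeometry, SessionContext, TrialResult, encode_payload
from ..hal import MockTransport, play_cue
from .common import OptionSpec, TrialSpec, press_until_fulfilled

__all__ = [
    "DiscriminationConfig",
    "DiscriminationState",
    "make_discrimination_trial",
    "correction_trial",
    "run_discrimination_trial",
]

PHASES = ("simple", "correction", "conditional")

_CENTER = dict(x=0.36, y=0.36, w=0.28, h=0.28)
_CHOICE_W, _CHOICE_H, _CHOICE_Y = 0.28, 0.30, 0.35
_LEFT_X, _RIGHT_X = 0.08, 0.64


@dataclass(frozen=True)
class DiscriminationConfig:
    phase: str = "simple"
    target_color: str = "yellow"
    comparison_color: str = "blue"
    conditional_colors: tuple[str, str] = ("green", "blue")
    fr_sample: int = 1
    fr_choice: int = 1
    reinforcer_magnitude: int = 1
    iti_s: float = 15.0
    response_window_s: float = 60.0
    hit_extension_above: float = 0.0
    side_block: int = 6
    max_same_side_run: int = 3

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.fr_sample < 1 or self.fr_choice < 1:
            raise ValueError("fixed ratios must be >= 1")
        if len(set(self.conditional_colors)) != 2:
            raise ValueError("conditional phase needs two distinct colors")


@dataclass
class DiscriminationState:
    """Progress through a discrimination session.

    ``pending_correction`` holds the re-presentation spec immediately after
    an incorrect choice (correction and conditional phases only).
    """

    phase: str = "simple"
    pending_correction: Optional[TrialSpec] = None
    trials_run: int = 0
    scored_trials: int = 0


def make_discrimination_trial(
    config: DiscriminationConfig,
    trial_index: int,
    correct_side: str,
    rng: Optional[np.random.Generator] = None,
) -> TrialSpec:
    """Plan one non-correction trial with the correct option on ``correct_side``.

    In the conditional phase the sample color is drawn per trial (uniform
    over the two conditional colors; ``rng`` required) and the matching
    choice box is the reinforced one.
    """
    other = "right" if correct_side == "left" else "left"
    if config.phase == "conditional":
        if rng is None:
            raise ValueError("conditional trials need an rng to draw the sample color")
        sample = str(rng.choice(list(config.conditional_colors)))
        distractor = next(c for c in config.conditional_colors if c != sample)
        trial_type = "sample"
        correct_color, wrong_color = sample, distractor
    else:
        sample = None
        trial_type = "choice"
        correct_color, wrong_color = config.target_color, config.comparison_color
    options = (
        OptionSpec(
            id="correct",
            side=correct_side,
            color=correct_color,
            magnitude=config.reinforcer_magnitude,
            fr=config.fr_choice,
            is_correct=True,
        ),
        OptionSpec(
            id="incorrect",
            side=other,
            color=wrong_color,
            magnitude=config.reinforcer_magnitude,
            fr=config.fr_choice,
            is_correct=False,
        ),
    )
    return TrialSpec(
        trial_index=trial_index,
        trial_type=trial_type,
        options=options,
        sample_color=sample,
    )


def correction_trial(parent: TrialSpec) -> TrialSpec:
    """The re-presentation of an incorrectly answered trial.

    The layout is identical — same sides, same colors, same sample — but
    the incorrect option is inactive, so exactly one box can be chosen.
    """
    options = tuple(
        o if o.is_correct else replace(o, active=False) for o in parent.options
    )
    return replace(parent, trial_type="correction", options=options)


def _choice_geometry(spec: TrialSpec, config: DiscriminationConfig) -> ScreenGeometry:
    boxes = []
    for o in spec.options:
        x = _LEFT_X if o.side == "left" else _RIGHT_X
        boxes.append(
            ResponseBox(
                o.id,
                x,
                _CHOICE_Y,
                _CHOICE_W,
                _CHOICE_H,
                o.color if o.active else "inactive_gray",
                active=o.active,
                hit_extension_above=config.hit_extension_above,
                fr_requirement=o.fr,
            )
        )
    return ScreenGeometry(boxes)


def run_discrimination_trial(
    state: DiscriminationState,
    config: DiscriminationConfig,
    ctx: SessionContext,
    agent,
    link: MockTransport,
    rng: np.random.Generator,
    trial_index: int,
    correct_side: Optional[str] = None,
) -> tuple[TrialResult, DiscriminationState]:
    """Run one trial (correction trials take priority over planned ones).

    Sequence: trial-start cue, center box until its fixed ratio is
    fulfilled (initiation), then the two choice boxes until one fulfils
    its ratio. A correct choice earns the reinforcer; an incorrect choice
    earns nothing and — beyond the simple phase — queues the correction
    re-presentation. Omissions at either stage leave any pending
    correction in place.
    """
    if state.pending_correction is not None:
        spec = state.pending_correction.with_index(trial_index)
    else:
        if correct_side is None:
            raise ValueError("a planned trial needs a correct_side")
        spec = make_discrimination_trial(config, trial_index, correct_side, rng)

    ctx.trial_index = trial_index
    start = ctx.clock.now
    correct_opt = next(o for o in spec.options if o.is_correct)
    meta = {
        "trial_type": spec.trial_type,
        "phase": config.phase,
        "correct_side": correct_opt.side,
        "correct_color": correct_opt.color,
    }
    if spec.sample_color:
        meta["sample_color"] = spec.sample_color
    ctx.emit("trial_start", payload=encode_payload(meta))
    if spec.trial_type == "correction":
        ctx.emit("correction_start", payload=encode_payload({"parent_side": correct_opt.side}))
    play_cue("trial_start", ctx)
    deadline = start + config.response_window_s
    state.trials_run += 1

    def _omit(stage: str) -> TrialResult:
        if hasattr(ctx.clock, "advance_to"):
            ctx.clock.advance_to(deadline)
        ctx.emit("omission", payload=encode_payload({"at": stage}))
        return TrialResult(trial_index=trial_index, trial_type=spec.trial_type, omitted=True)

    if agent.will_omit():
        return _omit("sample"), state

    # center (sample/observing) box
    center_color = spec.sample_color if spec.sample_color else config.target_color
    center = ResponseBox(
        "center",
        _CENTER["x"],
        _CENTER["y"],
        _CENTER["w"],
        _CENTER["h"],
        center_color,
        hit_extension_above=config.hit_extension_above,
        fr_requirement=config.fr_sample,
    )
    sample_geom = ScreenGeometry([center])
    sample_out = press_until_fulfilled(
        agent,
        sample_geom,
        ctx,
        deadline,
        aim=center,
        extra_for=lambda box: {"role": "sample"},
    )
    if sample_out.box is None:
        return _omit("sample"), state

    # choice boxes
    geometry = _choice_geometry(spec, config)
    by_id = {o.id: o for o in spec.options}
    target_opt = agent.choose(spec.active_options())
    choice_out = press_until_fulfilled(
        agent,
        geometry,
        ctx,
        deadline,
        aim=geometry.box(target_opt.id),
        extra_for=lambda box: {
            "role": "choice",
            "choice": box.id,
            "side": by_id[box.id].side,
            "color": by_id[box.id].color,
        },
    )
    if choice_out.box is None:
        return _omit("choice"), state

    chosen = by_id[choice_out.box.id]
    reinforced = bool(chosen.is_correct)
    if reinforced:
        ctx.emit(
            "reinforcement",
            payload=encode_payload({"n": int(chosen.magnitude), "choice": "correct"}),
        )
        for _ in range(int(chosen.magnitude)):
            link.send_pellet(ctx.clock.now)
        if spec.trial_type == "correction":
            state.pending_correction = None
    elif config.phase != "simple":
        state.pending_correction = correction_trial(spec)
    if spec.trial_type != "correction":
        state.scored_trials += 1

    return (
        TrialResult(
            trial_index=trial_index,
            trial_type=spec.trial_type,
            choice="correct" if reinforced else "incorrect",
            choice_side=chosen.side,
            choice_color=chosen.color,
            initiation_latency=sample_out.first_press_t - start,
            choice_latency=choice_out.fulfilled_t - start,
            reinforcers_delivered=int(chosen.magnitude) if reinforced else 0,
        ),
        state,
    )
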