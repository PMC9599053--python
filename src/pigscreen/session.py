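"""Session orchestration: run a whole task against an agent, log everything.

Every runner follows the same recipe: a simulated clock starting at 0, a
mock peripheral link, a session header event recording the seed, then the
task's trial loop with the configured intertrial interval. All randomness
— layout draws, trial shuffles, pseudorandom sides, agent behavior —
flows from the single session seed, so the same seed and config produce a
byte-identical session file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .agents import Agent, AgentPolicy, make_agent
from .core import EventLog, SessionContext, SimulatedClock, encode_payload, write_session_csv
from .hal import MockTransport, make_peripherals
from .tasks.common import balanced_side_sequence
from .tasks.ddt import DDTConfig, DDTState, build_ddt_session, run_ddt_trial
from .tasks.discrimination import DiscriminationConfig, DiscriminationState, run_discrimination_trial
from .tasks.shaping import ShapingConfig, ShapingState, autoshape_step, shaping_press_step

__all__ = [
    "run_shaping_session",
    "run_ddt_session",
    "run_discrimination_session",
    "write_session_files",
]

AgentLike = Union[Agent, AgentPolicy, str, None]


def _resolve_agent(agent: AgentLike, rng: np.random.Generator) -> Agent:
    if agent is None:
        return make_agent("perfect", rng=rng)
    if isinstance(agent, Agent):
        return agent
    if isinstance(agent, AgentPolicy):
        return Agent(agent, rng=rng)
    if isinstance(agent, str):
        return make_agent(agent, rng=rng)
    raise TypeError(f"cannot interpret {agent!r} as an agent")


def _setup(
    task: str,
    subject_id: str,
    session_id: int,
    seed: int,
    agent: AgentLike,
    *,
    watchdog_timeout: Optional[float] = None,
) -> tuple[SessionContext, MockTransport, Agent, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    task_seed, agent_seed = ss.spawn(2)
    task_rng = np.random.default_rng(task_seed)
    ctx = SessionContext(
        subject_id=subject_id, session_id=session_id, task=task, clock=SimulatedClock()
    )
    agent_obj = _resolve_agent(agent, np.random.default_rng(agent_seed))
    link = make_peripherals(ctx, watchdog_timeout=watchdog_timeout)
    ctx.emit(
        "manual_note",
        payload=encode_payload(
            {
                "note": "session_header",
                "seed": seed,
                "task": task,
                "agent": agent_obj.policy.kind,
            }
        ),
        trial_index=None,
    )
    return ctx, link, agent_obj, task_rng


def run_shaping_session(
    agent: AgentLike = None,
    *,
    config: Optional[ShapingConfig] = None,
    subject_id: str = "sim",
    session_id: int = 1,
    seed: int = 0,
    max_trials: int = 1000,
) -> tuple[EventLog, ShapingState]:
    """Run the shaping program until completion or ``max_trials``.

    A subject that never misses completes in exactly the sum of the stage
    thresholds (90 reinforced presses under the defaults: 20+15+15+40).
    """
    config = config if config is not None else ShapingConfig()
    ctx, link, agent_obj, rng = _setup("shaping", subject_id, session_id, seed, agent)
    state = ShapingState(stage=config.start_stage)
    trial = 0
    while not state.complete and trial < max_trials:
        ctx.phase = f"stage_{state.stage}"
        if state.stage == 0:
            autoshape_step(state, config, ctx, agent_obj, link, trial)
        else:
            shaping_press_step(state, config, ctx, agent_obj, link, rng, trial)
        ctx.clock.advance(config.iti_s)
        trial += 1
    return ctx.log, state


def run_ddt_session(
    agent: AgentLike = None,
    *,
    config: Optional[DDTConfig] = None,
    subject_id: str = "sim",
    session_id: int = 1,
    seed: int = 0,
) -> EventLog:
    """Run one full delay discounting session from a built trial plan."""
    config = config if config is not None else DDTConfig()
    ctx, link, agent_obj, rng = _setup("ddt", subject_id, session_id, seed, agent)
    phase = "magnitude_discrimination" if tuple(config.delays) == (0.0,) else "discounting"
    state = DDTState(phase=phase)
    for spec in build_ddt_session(config, rng):
        state.advance(spec, config)
        ctx.phase = phase
        run_ddt_trial(spec, config, ctx, agent_obj, link)
        ctx.clock.advance(config.iti_s)
    return ctx.log


def run_discrimination_session(
    agent: AgentLike = None,
    *,
    config: Optional[DiscriminationConfig] = None,
    n_trials: int = 36,
    subject_id: str = "sim",
    session_id: int = 1,
    seed: int = 0,
) -> tuple[EventLog, DiscriminationState]:
    """Run ``n_trials`` planned discrimination trials (plus any corrections).

    Correction trials are inserted immediately after each incorrect choice
    and do not consume planned trials or their side assignments; the
    session therefore runs ``n_trials`` scored trials plus however many
    corrections the subject's errors generate (capped at 4x the plan).
    """
    config = config if config is not None else DiscriminationConfig()
    ctx, link, agent_obj, rng = _setup("discrimination", subject_id, session_id, seed, agent)
    state = DiscriminationState(phase=config.phase)
    sides = iter(
        balanced_side_sequence(
            n_trials, rng, block=config.side_block, max_run=config.max_same_side_run
        )
    )
    ctx.phase = config.phase
    trial_index = 0
    planned_done = 0
    next_side: Optional[str] = None
    while planned_done < n_trials and trial_index < 4 * n_trials:
        if state.pending_correction is None and next_side is None:
            next_side = next(sides)
        side_arg = None if state.pending_correction is not None else next_side
        was_correction = state.pending_correction is not None
        result, state = run_discrimination_trial(
            state, config, ctx, agent_obj, link, rng, trial_index, correct_side=side_arg
        )
        if not was_correction and not result.omitted:
            planned_done += 1
            next_side = None
        ctx.clock.advance(config.iti_s)
        trial_index += 1
    return ctx.log, state


def write_session_files(
    log: EventLog,
    out_dir: str | Path,
    *,
    on_exists: str = "refuse",
) -> list[Path]:
    """Write one CSV per subject/session present in the log.

    ``on_exists`` controls rerun behavior: ``refuse`` (error), ``suffix``
    (append ``_1``, ``_2``, ...), or ``overwrite``. A run never silently
    clobbers an earlier session file.
    """
    if on_exists not in ("refuse", "suffix", "overwrite"):
        raise ValueError("on_exists must be 'refuse', 'suffix' or 'overwrite'")
    out_dir = Path(out_dir)
    paths: list[Path] = []
    for subject_id, session_id in log.subjects():
        base = out_dir / f"{subject_id}_s{session_id}.csv"
        path = base
        if path.exists() and on_exists == "refuse":
            raise FileExistsError(f"{path} exists; pass on_exists='suffix' or 'overwrite'")
        if on_exists == "suffix":
            n = 1
            while path.exists():
                path = out_dir / f"{subject_id}_s{session_id}_{n}.csv"
                n += 1
        write_session_csv(log.for_subject(subject_id, session_id), path)
        paths.append(path)
    return paths
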