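"""Session-level outcome metrics: latency, omissions, accuracy, discounting
AUC, and side/color preference indices.

All metrics are computed from reconstructed :class:`~pigscreen.core.TrialResult`
sequences, which in turn come from the CSV event log alone — a session file
on disk is sufficient to recompute every number here.

The discounting AUC follows the task's own definition: the proportion of
completed free-choice trials on which the Large option was chosen, pooled
across delay blocks, bounded in [0, 1] (0 = exclusively Small/immediate,
1 = exclusively Large/delayed/self-controlled). The conventional
delay-normalized trapezoidal AUC is available as an explicit alternate
mode, since the two differ whenever choice varies across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import EventLog, TrialResult, read_session_csv, trials_from_log

__all__ = [
    "SessionMetrics",
    "discounting_auc",
    "side_bias",
    "color_bias",
    "percent_correct",
    "initiation_latency",
    "session_metrics",
    "summarize_sessions",
    "plot_sessions",
]


@dataclass(frozen=True)
class SessionMetrics:
    """One session's outcome panel.

    Metrics that do not apply to the session's task (e.g. AUC outside the
    DDT, color bias in a yellow/blue discrimination with no green choices)
    are ``None``.
    """

    trials_completed: int
    omissions: int
    mean_initiation_latency: Optional[float]
    reinforcers_delivered: int
    percent_correct: Optional[float] = None
    auc: Optional[float] = None
    side_bias: Optional[float] = None
    color_bias: Optional[float] = None

    def __post_init__(self):
        if self.auc is not None and not 0 <= self.auc <= 1:
            raise ValueError("auc must lie in [0, 1]")
        for name in ("side_bias", "color_bias"):
            v = getattr(self, name)
            if v is not None and not -1 <= v <= 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.percent_correct is not None and not 0 <= self.percent_correct <= 100:
            raise ValueError("percent_correct must lie in [0, 100]")


def _completed_free_choices(trials: Iterable[TrialResult]) -> list[TrialResult]:
    return [
        t
        for t in trials
        if t.trial_type == "free_choice" and not t.omitted and t.choice in ("large", "small")
    ]


def discounting_auc(trials: Sequence[TrialResult], mode: str = "pooled") -> Optional[float]:
    """Discounting AUC over completed free-choice trials; None if there are none.

    ``pooled`` (default): proportion of Large choices across all completed
    free choices. ``trapezoid``: per-block Large proportions against block
    delay, trapezoidal area normalized by the maximum delay (requires a
    positive delay span). Omitted trials never enter a denominator.
    """
    free = _completed_free_choices(trials)
    if not free:
        return None
    if mode == "pooled":
        return sum(t.choice == "large" for t in free) / len(free)
    if mode == "trapezoid":
        by_delay: dict[float, list[TrialResult]] = {}
        for t in free:
            if t.delay is None:
                raise ValueError("trapezoid mode needs per-trial delays")
            by_delay.setdefault(t.delay, []).append(t)
        delays = sorted(by_delay)
        if delays[-1] <= delays[0]:
            raise ValueError("trapezoid mode needs at least two distinct delays")
        props = [
            sum(t.choice == "large" for t in by_delay[d]) / len(by_delay[d]) for d in delays
        ]
        return float(np.trapezoid(props, delays) / (delays[-1] - delays[0]))
    raise ValueError(f"unknown AUC mode {mode!r}")


def _preference_index(trials: Sequence[TrialResult], attr: str, pos: str, neg: str) -> Optional[float]:
    eligible = [
        t
        for t in trials
        if not t.omitted
        and t.trial_type not in ("forced_choice", "correction")
        and getattr(t, attr) in (pos, neg)
    ]
    if not eligible:
        return None
    p = sum(getattr(t, attr) == pos for t in eligible)
    n = len(eligible) - p
    return (p - n) / (p + n)


def side_bias(trials: Sequence[TrialResult]) -> Optional[float]:
    """(L - R) / (L + R) over completed free choices, in [-1, 1]; +1 = all left.

    Forced and correction trials are excluded — their side is imposed, not
    preferred.
    """
    return _preference_index(trials, "choice_side", "left", "right")


def color_bias(trials: Sequence[TrialResult]) -> Optional[float]:
    """(G - B) / (G + B) over completed free choices of green or blue; +1 = all green."""
    return _preference_index(trials, "choice_color", "green", "blue")


def percent_correct(trials: Sequence[TrialResult]) -> Optional[float]:
    """100 x correct / scored discrimination trials.

    Scored trials are completed, non-correction trials with a
    correct/incorrect outcome; correction trials are excluded from the
    denominator by convention (the subject cannot get them wrong).
    """
    scored = [
        t
        for t in trials
        if not t.omitted and t.trial_type != "correction" and t.choice in ("correct", "incorrect")
    ]
    if not scored:
        return None
    return 100.0 * sum(t.choice == "correct" for t in scored) / len(scored)


def initiation_latency(trials: Sequence[TrialResult]) -> Optional[float]:
    """Mean seconds from the trial-start tone to the first registered
    response, over initiated (non-omitted) trials; None if none initiated."""
    lats = [
        t.initiation_latency
        for t in trials
        if not t.omitted and t.initiation_latency is not None
    ]
    if not lats:
        return None
    return float(np.mean(lats))


def session_metrics(
    source: EventLog | Sequence[TrialResult],
    *,
    auc_mode: str = "pooled",
) -> SessionMetrics:
    """Compute the full metrics panel from a log or trial sequence."""
    trials = trials_from_log(source) if isinstance(source, EventLog) else list(source)
    completed = [t for t in trials if not t.omitted]
    auc = discounting_auc(trials, auc_mode) if _completed_free_choices(trials) else None
    return SessionMetrics(
        trials_completed=len(completed),
        omissions=sum(t.omitted for t in trials),
        mean_initiation_latency=initiation_latency(trials),
        reinforcers_delivered=sum(t.reinforcers_delivered for t in trials),
        percent_correct=percent_correct(trials),
        auc=auc,
        side_bias=side_bias(trials),
        color_bias=color_bias(trials),
    )


def summarize_sessions(paths: Iterable[str | Path], *, auc_mode: str = "pooled") -> pd.DataFrame:
    """Per-session metrics table from one or more session CSV files."""
    rows = []
    for path in paths:
        log = read_session_csv(path)
        for subject_id, session_id in log.subjects():
            sub = log.for_subject(subject_id, session_id)
            m = session_metrics(sub, auc_mode=auc_mode)
            task = next(iter(sub)).task if len(sub) else ""
            rows.append(
                {
                    "file": str(path),
                    "subject_id": subject_id,
                    "session_id": session_id,
                    "task": task,
                    "trials_completed": m.trials_completed,
                    "omissions": m.omissions,
                    "mean_initiation_latency_s": m.mean_initiation_latency,
                    "reinforcers_delivered": m.reinforcers_delivered,
                    "percent_correct": m.percent_correct,
                    "auc": m.auc,
                    "side_bias": m.side_bias,
                    "color_bias": m.color_bias,
                }
            )
    return pd.DataFrame(rows)


def plot_sessions(table: pd.DataFrame):
    """Panel figure over sessions: latency, omissions, AUC or accuracy,
    and preference indices — one line per subject."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    panels = [
        ("mean_initiation_latency_s", "Initiation latency (s)"),
        ("omissions", "Omissions"),
        ("auc", "Discounting AUC"),
        ("percent_correct", "Percent correct"),
        ("side_bias", "Side preference (+1 = left)"),
        ("color_bias", "Color preference (+1 = green)"),
    ]
    panels = [(col, label) for col, label in panels if table[col].notna().any()]
    n = max(len(panels), 1)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), sharex=True, squeeze=False)
    for ax, (col, label) in zip(axes.ravel(), panels):
        for subject, grp in table.groupby("subject_id"):
            ax.plot(grp["session_id"], grp[col], marker="o", label=str(subject))
        ax.set_ylabel(label)
        if col in ("side_bias", "color_bias"):
            ax.axhline(0.0, color="gray", lw=0.8, ls=":")
            ax.set_ylim(-1.05, 1.05)
    axes.ravel()[0].legend(title="subject", fontsize="small")
    axes.ravel()[-1].set_xlabel("Session")
    fig.tight_layout()
    return fig
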