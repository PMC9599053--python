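"""Domain types, clocks, event logging and CSV session files.

Everything downstream of the task state machines funnels through one
structure: an append-only :class:`EventLog` of timestamped
:class:`EventRecord` rows, written as one comma-separated file per subject.
The log is the single source of truth — trial outcomes and all session
metrics are reconstructed from it rather than from in-memory state, so a
session file on disk is fully self-describing.

Coordinates are stored as fractions of screen width/height in ``[0, 1]``
with the origin at the top-left, making layouts resolution-independent.
Timestamps are seconds since session start, recorded at millisecond
precision.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "TASKS",
    "EVENT_TYPES",
    "CSV_COLUMNS",
    "Clock",
    "SimulatedClock",
    "WallClock",
    "EventRecord",
    "EventLog",
    "SessionContext",
    "TrialResult",
    "ResponseBox",
    "ScreenGeometry",
    "LogOrderError",
    "SessionFileError",
    "encode_payload",
    "parse_payload",
    "log_event",
    "write_session_csv",
    "read_session_csv",
    "trials_from_log",
    "summarize_session",
]

TASKS = ("shaping", "ddt", "discrimination")

EVENT_TYPES = (
    "trial_start",
    "touch",
    "response_registered",
    "reinforcement",
    "pellet_command",
    "tone",
    "omission",
    "correction_start",
    "stage_advance",
    "manual_note",
)

#: Fixed column order of the session CSV schema. The recording format is
#: comma-separated with one file per subject; this particular column set is
#: this package's own schema.
CSV_COLUMNS = (
    "subject_id",
    "session_id",
    "task",
    "phase",
    "trial_index",
    "event_type",
    "timestamp_s",
    "x",
    "y",
    "payload",
)

TRIAL_TYPES = (
    "autoshape",
    "shaping_press",
    "forced_choice",
    "free_choice",
    "correction",
    "sample",
    "choice",
)

CHOICES = ("large", "small", "left", "right", "correct", "incorrect", "none")


class LogOrderError(ValueError):
    """Raised when an event would violate timestamp ordering in a log."""


class SessionFileError(ValueError):
    """Raised on a malformed session CSV; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# Clocks
# ---------------------------------------------------------------------------


class Clock:
    """Monotonic session clock; ``now`` is seconds since session start."""

    mode: str

    @property
    def now(self) -> float:
        raise NotImplementedError

    def advance(self, seconds: float) -> float:
        raise NotImplementedError


class SimulatedClock(Clock):
    """Discrete-event clock: time moves only when explicitly advanced.

    Lets a full behavioral session (minutes to hours of subject time) run
    in milliseconds of wall time, which is what makes the task machines
    testable without animals or hardware.
    """

    mode = "simulated"

    def __init__(self, start: float = 0.0):
        if start < 0:
            raise ValueError("clock cannot start before session time 0")
        self._now = float(start)

    @property
    def now(self) -> float:
        return self._now

    def advance(self, seconds: float) -> float:
        if seconds < 0:
            raise ValueError("cannot advance a monotonic clock backwards")
        self._now += float(seconds)
        return self._now

    def advance_to(self, t: float) -> float:
        if t < self._now:
            raise ValueError("cannot advance a monotonic clock backwards")
        self._now = float(t)
        return self._now


class WallClock(Clock):
    """Real-time clock for live sessions; ``advance`` sleeps."""

    mode = "wall"

    def __init__(self):
        self._t0 = time.monotonic()

    @property
    def now(self) -> float:
        return time.monotonic() - self._t0

    def advance(self, seconds: float) -> float:
        if seconds < 0:
            raise ValueError("cannot advance a monotonic clock backwards")
        time.sleep(seconds)
        return self.now


# ---------------------------------------------------------------------------
# Payload helpers
# ---------------------------------------------------------------------------


def encode_payload(fields: Mapping[str, object]) -> str:
    """Encode key-value detail as ``k=v;k=v`` text for the payload column."""
    parts = []
    for k, v in fields.items():
        k, v = str(k), str(v)
        if "=" in k or ";" in k or "=" in v or ";" in v:
            raise ValueError(f"payload keys/values may not contain '=' or ';': {k}={v}")
        parts.append(f"{k}={v}")
    return ";".join(parts)


def parse_payload(text: str) -> dict[str, str]:
    """Inverse of :func:`encode_payload`; free text without '=' yields {}."""
    out: dict[str, str] = {}
    if not text:
        return out
    for part in text.split(";"):
        if "=" in part:
            k, _, v = part.partition("=")
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Event records and the log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRecord:
    """One timestamped behavioral or device event — the unit of CSV logging.

    ``timestamp`` is seconds since session start (millisecond precision);
    ``x``/``y`` are screen fractions in [0, 1] and are required for
    ``response_registered`` events; ``payload`` is ``k=v;k=v`` detail text.
    """

    subject_id: str
    session_id: int
    task: str
    phase: str
    event_type: str
    timestamp: float
    trial_index: Optional[int] = None
    x: Optional[float] = None
    y: Optional[float] = None
    payload: str = ""

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.session_id < 1:
            raise ValueError("session_id must be >= 1")
        if self.trial_index is not None and self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")
        # quantize so that the CSV round trip is the identity
        object.__setattr__(self, "timestamp", round(float(self.timestamp), 3))
        for name in ("x", "y"):
            v = getattr(self, name)
            if v is not None:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must lie in the unit square, got {v}")
                object.__setattr__(self, name, round(float(v), 6))
        if self.event_type == "response_registered" and (self.x is None or self.y is None):
            raise ValueError("response_registered events require x and y")

    @property
    def payload_dict(self) -> dict[str, str]:
        return parse_payload(self.payload)


class EventLog:
    """Append-only, time-ordered sequence of events for one or more subjects.

    Ordering is enforced per (subject_id, session_id): appending an event
    earlier than the last logged timestamp for that session raises
    :class:`LogOrderError`.
    """

    def __init__(self, events: Iterable[EventRecord] = ()):
        self._events: list[EventRecord] = []
        self._last_t: dict[tuple[str, int], float] = {}
        for ev in events:
            self.append(ev)

    def append(self, record: EventRecord) -> "EventLog":
        key = (record.subject_id, record.session_id)
        last = self._last_t.get(key)
        if last is not None and record.timestamp < last:
            raise LogOrderError(
                f"event at t={record.timestamp:.3f}s precedes last logged "
                f"t={last:.3f}s for subject {record.subject_id!r} "
                f"session {record.session_id}"
            )
        self._events.append(record)
        self._last_t[key] = record.timestamp
        return self

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self._events == other._events

    def subjects(self) -> list[tuple[str, int]]:
        """Distinct (subject_id, session_id) pairs in insertion order."""
        seen: dict[tuple[str, int], None] = {}
        for ev in self._events:
            seen.setdefault((ev.subject_id, ev.session_id), None)
        return list(seen)

    def for_subject(self, subject_id: str, session_id: Optional[int] = None) -> "EventLog":
        sub = EventLog()
        for ev in self._events:
            if ev.subject_id == subject_id and (session_id is None or ev.session_id == session_id):
                sub.append(ev)
        return sub


def log_event(log: EventLog, record: EventRecord) -> EventLog:
    """Append ``record`` to ``log`` (every response is a new line)."""
    return log.append(record)


@dataclass
class SessionContext:
    """Identity + clock bundle that task code uses to emit events.

    ``phase`` and ``trial_index`` are mutated by the session runner as the
    task progresses so that every emitted event is correctly attributed.
    """

    subject_id: str
    session_id: int
    task: str
    clock: Clock
    log: EventLog = field(default_factory=EventLog)
    phase: str = ""
    trial_index: Optional[int] = None

    def emit(
        self,
        event_type: str,
        *,
        x: Optional[float] = None,
        y: Optional[float] = None,
        payload: str = "",
        trial_index: Optional[int] = "unset",  # type: ignore[assignment]
    ) -> EventRecord:
        ti = self.trial_index if trial_index == "unset" else trial_index
        rec = EventRecord(
            subject_id=self.subject_id,
            session_id=self.session_id,
            task=self.task,
            phase=self.phase,
            event_type=event_type,
            timestamp=self.clock.now,
            trial_index=ti,
            x=x,
            y=y,
            payload=payload,
        )
        self.log.append(rec)
        return rec


# ---------------------------------------------------------------------------
# Screen geometry
# ---------------------------------------------------------------------------

BOX_COLORS = ("yellow", "blue", "green", "inactive_gray")


@dataclass
class ResponseBox:
    """A rectangular on-screen button with press-on-touch semantics.

    ``hit_extension_above`` enlarges the touch-sensitive region upward
    (toward smaller y) beyond the visible rectangle, compensating for the
    press-then-swipe-upward response topography of pigs. ``fr_requirement``
    is the fixed-ratio press count needed to fulfil the box (FR-1 default).
    """

    id: str
    x: float
    y: float
    w: float
    h: float
    color: str = "yellow"
    active: bool = True
    hit_extension_above: float = 0.0
    fr_requirement: int = 1
    fr_count: int = 0

    def __post_init__(self):
        if self.color not in BOX_COLORS:
            raise ValueError(f"unknown box color {self.color!r}")
        if self.fr_requirement < 1:
            raise ValueError("fr_requirement must be >= 1")
        if not (0 <= self.fr_count < self.fr_requirement):
            raise ValueError("fr_count must satisfy 0 <= fr_count < fr_requirement")
        if self.hit_extension_above < 0:
            raise ValueError("hit_extension_above must be >= 0")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box must have positive width and height")
        if not (0 <= self.x and 0 <= self.y and self.x + self.w <= 1 + 1e-9 and self.y + self.h <= 1 + 1e-9):
            raise ValueError(f"box {self.id!r} must lie within the unit square")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2, self.y + self.h / 2)

    def hit_region(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the touch-sensitive rectangle, extension included."""
        return (self.x, max(0.0, self.y - self.hit_extension_above), self.x + self.w, self.y + self.h)

    def contains(self, px: float, py: float) -> bool:
        x0, y0, x1, y1 = self.hit_region()
        return x0 <= px <= x1 and y0 <= py <= y1


@dataclass
class ScreenGeometry:
    """A screen layout on the unit square; overlap of active boxes is
    rejected at construction time so hit-testing is never ambiguous."""

    boxes: list[ResponseBox] = field(default_factory=list)

    def __post_init__(self):
        active = [b for b in self.boxes if b.active]
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                if _rects_overlap(a.hit_region(), b.hit_region()):
                    raise ValueError(
                        f"active boxes {a.id!r} and {b.id!r} overlap; "
                        "layouts must keep touch regions disjoint"
                    )

    def box(self, box_id: str) -> ResponseBox:
        for b in self.boxes:
            if b.id == box_id:
                return b
        raise KeyError(box_id)


def _rects_overlap(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> bool:
    # touching edges (zero-area intersection) is allowed
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


# ---------------------------------------------------------------------------
# Trial results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialResult:
    """Realized outcome of one trial, reconstructed from the event log."""

    trial_index: int
    trial_type: str
    choice: str = "none"
    choice_side: Optional[str] = None
    choice_color: Optional[str] = None
    initiation_latency: Optional[float] = None
    choice_latency: Optional[float] = None
    reinforcers_delivered: int = 0
    omitted: bool = False
    block_index: Optional[int] = None
    delay: Optional[float] = None

    def __post_init__(self):
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.choice not in CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if self.omitted and (self.choice != "none" or self.reinforcers_delivered != 0):
            raise ValueError("an omitted trial has no choice and no reinforcers")
        if self.reinforcers_delivered < 0:
            raise ValueError("reinforcers_delivered must be >= 0")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _fmt(v: Optional[float | int | str]) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_session_csv(log: EventLog, path: str | Path) -> Path:
    """Write one log to one comma-separated file (header + one line/event).

    The caller is responsible for splitting multi-subject logs (see
    :func:`pigscreen.session.write_session_files`, which writes a separate
    file for each subject).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for ev in log:
            writer.writerow(
                [
                    ev.subject_id,
                    ev.session_id,
                    ev.task,
                    ev.phase,
                    _fmt(ev.trial_index),
                    ev.event_type,
                    f"{ev.timestamp:.3f}",
                    _fmt(ev.x),
                    _fmt(ev.y),
                    ev.payload,
                ]
            )
    return path


def read_session_csv(path: str | Path) -> EventLog:
    """Read a session CSV back into an :class:`EventLog`.

    ``read(write(log))`` is the identity. Malformed lines raise
    :class:`SessionFileError` naming the 1-based line number.
    """
    path = Path(path)
    log = EventLog()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SessionFileError("empty file (missing header)", 1) from None
        if tuple(header) != CSV_COLUMNS:
            raise SessionFileError(f"unexpected header {header!r}", 1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_COLUMNS):
                raise SessionFileError(
                    f"expected {len(CSV_COLUMNS)} fields, got {len(row)}", lineno
                )
            try:
                rec = EventRecord(
                    subject_id=row[0],
                    session_id=int(row[1]),
                    task=row[2],
                    phase=row[3],
                    trial_index=int(row[4]) if row[4] else None,
                    event_type=row[5],
                    timestamp=float(row[6]),
                    x=float(row[7]) if row[7] else None,
                    y=float(row[8]) if row[8] else None,
                    payload=row[9],
                )
            except (ValueError, IndexError) as exc:
                raise SessionFileError(str(exc), lineno) from exc
            try:
                log.append(rec)
            except LogOrderError as exc:
                raise SessionFileError(str(exc), lineno) from exc
    return log


# ---------------------------------------------------------------------------
# Trial reconstruction and session summary
# ---------------------------------------------------------------------------


def trials_from_log(log: EventLog) -> list[TrialResult]:
    """Rebuild per-trial outcomes from the raw event stream.

    Contingent reinforcers are pellet commands without a ``noncontingent``
    payload flag; the choice is carried on the fulfilling
    ``response_registered`` event (payload key ``choice``).
    """
    by_trial: dict[int, list[EventRecord]] = {}
    for ev in log:
        if ev.trial_index is not None:
            by_trial.setdefault(ev.trial_index, []).append(ev)

    results: list[TrialResult] = []
    for ti in sorted(by_trial):
        evs = by_trial[ti]
        start = next((e for e in evs if e.event_type == "trial_start"), None)
        if start is None:
            continue
        meta = start.payload_dict
        trial_type = meta.get("trial_type", "shaping_press")
        block = int(meta["block"]) if "block" in meta else None
        delay = float(meta["delay_s"]) if "delay_s" in meta else None

        responses = [e for e in evs if e.event_type == "response_registered"]
        omitted = any(e.event_type == "omission" for e in evs)
        pellets = sum(
            1
            for e in evs
            if e.event_type == "pellet_command" and e.payload_dict.get("noncontingent") != "1"
        )

        choice, side, color = "none", None, None
        choice_t = None
        for e in responses:
            pd = e.payload_dict
            if "choice" in pd:
                choice = pd["choice"]
                side = pd.get("side")
                color = pd.get("color")
                choice_t = e.timestamp
        if choice == "none" and responses and not omitted and trial_type == "shaping_press":
            # a fulfilled shaping press carries no choice token
            pass

        init_lat = responses[0].timestamp - start.timestamp if responses else None
        choice_lat = choice_t - start.timestamp if choice_t is not None else None

        results.append(
            TrialResult(
                trial_index=ti,
                trial_type=trial_type,
                choice=choice if not omitted else "none",
                choice_side=side,
                choice_color=color,
                initiation_latency=init_lat,
                choice_latency=choice_lat,
                reinforcers_delivered=pellets,
                omitted=omitted,
                block_index=block,
                delay=delay,
            )
        )
    return results


def summarize_session(log: EventLog) -> dict[str, object]:
    """End-of-session summary table: exact tallies over reconstructed trials.

    ``trials_completed`` counts non-omitted trials; the latency mean
    excludes omitted trials; ``percent_correct`` is present only when the
    log contains scored (non-correction) discrimination trials.
    """
    trials = trials_from_log(log)
    completed = [t for t in trials if not t.omitted]
    omissions = sum(t.omitted for t in trials)
    lats = [t.initiation_latency for t in completed if t.initiation_latency is not None]
    scored = [t for t in completed if t.choice in ("correct", "incorrect") and t.trial_type != "correction"]
    summary: dict[str, object] = {
        "trials_total": len(trials),
        "trials_completed": len(completed),
        "omissions": omissions,
        "mean_initiation_latency_s": (sum(lats) / len(lats)) if lats else None,
        "reinforcers_delivered": sum(t.reinforcers_delivered for t in trials),
        "percent_correct": (
            100.0 * sum(t.choice == "correct" for t in scored) / len(scored) if scored else None
        ),
    }
    return summary


def copy_config(cfg, **overrides):
    """dataclasses.replace re-export used by task configs."""
    return replace(cfg, **overrides)
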