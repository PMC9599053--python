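"""Run configuration: nested YAML config files with per-task defaults.

A run config mirrors the task and agent dataclass defaults; every default
is overridable from the file or from CLI flags. Unknown keys are rejected
with the offending field named, so typos fail loudly before a session
starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .agents import AgentPolicy
from .tasks.ddt import DDTConfig
from .tasks.discrimination import DiscriminationConfig
from .tasks.shaping import ShapingConfig

__all__ = ["RunConfig", "load_config", "defaults_yaml", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the field."""


@dataclass
class RunConfig:
    """Everything needed to execute one session."""

    subject_id: str = "pig1"
    session_id: int = 1
    task: str = "shaping"
    seed: int = 0
    out_dir: str = "sessions"
    on_exists: str = "refuse"
    n_trials: int = 36  # discrimination planned trials
    agent: AgentPolicy = field(default_factory=AgentPolicy)
    shaping: ShapingConfig = field(default_factory=ShapingConfig)
    ddt: DDTConfig = field(default_factory=DDTConfig)
    discrimination: DiscriminationConfig = field(default_factory=DiscriminationConfig)

    def task_config(self):
        return {"shaping": self.shaping, "ddt": self.ddt, "discrimination": self.discrimination}[
            self.task
        ]


_SECTIONS = {
    "agent": AgentPolicy,
    "shaping": ShapingConfig,
    "ddt": DDTConfig,
    "discrimination": DiscriminationConfig,
}


def _build_section(cls, data: dict[str, Any], section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[{section}]: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a nested key-value YAML config into a validated RunConfig."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a mapping at the top level")
    cfg = RunConfig()
    top_fields = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    updates: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"[{key}] must be a mapping of parameter overrides")
            updates[key] = _build_section(_SECTIONS[key], value, key)
        else:
            updates[key] = value
    cfg = replace(cfg, **updates)
    if cfg.task not in ("shaping", "ddt", "discrimination"):
        raise ConfigError(f"task must be shaping, ddt or discrimination, got {cfg.task!r}")
    if cfg.session_id < 1:
        raise ConfigError("session_id must be >= 1")
    return cfg


def defaults_yaml() -> str:
    """All defaults as a ready-to-edit YAML document."""
    cfg = RunConfig()
    doc = asdict(cfg)
    for section in _SECTIONS:
        doc[section] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in doc[section].items()
        }
    return yaml.safe_dump(doc, sort_keys=False)
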