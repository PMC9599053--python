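"""Simulated subjects that drive the tasks headlessly.

An :class:`Agent` stands in for a pig at the screen: it decides which
option to go for, emits noisy press/release touches aimed at a box, takes
a stochastic latency to respond, and occasionally withholds responding
entirely. The choice rule is hyperbolic delay discounting (Mazur form)
``V = A / (1 + kD)`` with optional softmax noise and additive side/color
bias terms — one interpretable parameter ``k`` is enough to generate
delay-averse choice data spanning the full range of the discounting AUC.

Touch topology matters: pigs press and then swipe upward at a slight
diagonal, so presses land above the aim point (``swipe_offset``) with
scatter (``touch_sd``). This is what the invisible upward hit-region
extension on buttons exists to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ResponseBox
from .hal import TouchEvent
from .tasks.common import OptionSpec

__all__ = ["AgentPolicy", "Agent", "hyperbolic_value", "make_agent", "AGENT_KINDS"]

AGENT_KINDS = ("perfect", "nonresponder", "random_toucher", "hyperbolic", "biased")


def hyperbolic_value(A: float, D: float, k: float) -> float:
    """Discounted value ``A / (1 + k D)`` of amount A delayed by D seconds.

    Strictly decreasing in D for k > 0; equals A at D = 0 or k = 0.
    """
    if A < 0 or D < 0 or k < 0:
        raise ValueError("A, D and k must be non-negative")
    return A / (1.0 + k * D)


@dataclass(frozen=True)
class AgentPolicy:
    """Parameterization of a simulated subject.

    ``k`` is the hyperbolic discounting rate (1/s); ``temperature`` the
    softmax temperature (0 = greedy argmax); ``side_bias``/``color_bias``
    in [-1, 1] enter as additive value offsets (+1 = fully left / fully
    green); ``touch_sd`` and ``swipe_offset`` are screen fractions;
    ``latency_sd`` of 0 makes response latencies deterministic at the mean.
    """

    kind: str = "hyperbolic"
    k: float = 0.0
    temperature: float = 0.0
    side_bias: float = 0.0
    color_bias: float = 0.0
    touch_sd: float = 0.0
    swipe_offset: float = 0.0
    response_latency_mean: float = 2.0
    latency_sd: float = 1.0
    omission_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not 0 <= self.omission_prob <= 1:
            raise ValueError("omission_prob must be in [0, 1]")
        if not -1 <= self.side_bias <= 1 or not -1 <= self.color_bias <= 1:
            raise ValueError("bias terms must be in [-1, 1]")
        for name in ("k", "temperature", "touch_sd", "latency_sd", "response_latency_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class Agent:
    """A simulated subject: policy + seeded random stream."""

    def __init__(self, policy: AgentPolicy, rng: Optional[np.random.Generator] = None):
        self.policy = policy
        self.rng = rng if rng is not None else np.random.default_rng(policy.seed)

    # -- responding -------------------------------------------------------

    @property
    def responds(self) -> bool:
        return self.policy.kind != "nonresponder"

    def will_omit(self) -> bool:
        """Drawn once per trial: does the subject withhold all responding?"""
        if not self.responds:
            return True
        if self.policy.omission_prob == 0:
            return False
        return bool(self.rng.random() < self.policy.omission_prob)

    def draw_latency(self) -> float:
        """Seconds until the next response attempt (gamma-distributed)."""
        m, sd = self.policy.response_latency_mean, self.policy.latency_sd
        if m == 0:
            return 0.0
        if sd == 0:
            return m
        shape = (m / sd) ** 2
        return float(self.rng.gamma(shape, m / shape))

    # -- choice -----------------------------------------------------------

    def option_value(self, option: OptionSpec, scale: float) -> float:
        """Discounted value plus additive bias terms.

        Biases are scaled by the largest option magnitude so a full bias
        (|1|) can dominate choice in any task, including discriminations
        where all options deliver the same reinforcer.
        """
        v = hyperbolic_value(option.magnitude, option.delay, self.policy.k)
        if option.side == "left":
            v += 0.5 * self.policy.side_bias * scale
        elif option.side == "right":
            v -= 0.5 * self.policy.side_bias * scale
        if option.color == "green":
            v += 0.5 * self.policy.color_bias * scale
        elif option.color == "blue":
            v -= 0.5 * self.policy.color_bias * scale
        return v

    def choose(self, options: Sequence[OptionSpec]) -> OptionSpec:
        """Pick one active option.

        Forced trials (a single active option) always select that option.
        The perfect agent takes the reinforced option when one is marked;
        otherwise choice is greedy argmax over values (seeded tie-break)
        or a softmax draw for temperature > 0. Random touchers pick
        uniformly.
        """
        active = [o for o in options if o.active]
        if not active:
            raise ValueError("a trial must offer at least one active option")
        if len(active) == 1:
            return active[0]
        if self.policy.kind == "perfect":
            for o in active:
                if o.is_correct:
                    return o
        if self.policy.kind == "random_toucher":
            return active[int(self.rng.integers(len(active)))]
        scale = max(o.magnitude for o in active) or 1.0
        values = np.array([self.option_value(o, scale) for o in active])
        if self.policy.temperature == 0:
            best = np.flatnonzero(values == values.max())
            idx = int(best[0]) if len(best) == 1 else int(self.rng.choice(best))
            return active[idx]
        z = values / self.policy.temperature
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
        return active[int(self.rng.choice(len(active), p=p))]

    # -- touching ---------------------------------------------------------

    def emit_touch(self, target: Optional[ResponseBox], now: float) -> tuple[TouchEvent, TouchEvent]:
        """One press/release pair aimed at ``target``.

        The press lands at the box center plus Gaussian scatter and an
        upward swipe offset; the release lands further up along the swipe.
        Contact duration is not modeled (press and release share a
        timestamp). Random touchers ignore the target and press anywhere.
        """
        if self.policy.kind == "random_toucher" or target is None:
            px, py = self.rng.uniform(0, 1, size=2)
        else:
            cx, cy = target.center
            sd = self.policy.touch_sd
            px = cx + (self.rng.normal(0, sd) if sd else 0.0)
            py = cy - self.policy.swipe_offset + (self.rng.normal(0, sd) if sd else 0.0)
        px, py = float(np.clip(px, 0, 1)), float(np.clip(py, 0, 1))
        rx = float(np.clip(px + 0.01, 0, 1))
        ry = float(np.clip(py - 0.5 * self.policy.swipe_offset - 0.01, 0, 1))
        press = TouchEvent(x=px, y=py, kind="press", timestamp=now)
        release = TouchEvent(x=rx, y=ry, kind="release", timestamp=now)
        return press, release


_KIND_DEFAULTS: dict[str, dict] = {
    "perfect": dict(k=0.0, omission_prob=0.0, touch_sd=0.0, swipe_offset=0.0),
    "nonresponder": dict(omission_prob=1.0),
    "random_toucher": dict(),
    "hyperbolic": dict(),
    "biased": dict(),
}


def make_agent(
    kind: str = "perfect",
    rng: Optional[np.random.Generator] = None,
    **overrides,
) -> Agent:
    """Build an agent of a named kind with policy overrides applied."""
    if kind not in AGENT_KINDS:
        raise ValueError(f"unknown agent kind {kind!r}; choose from {AGENT_KINDS}")
    params = dict(_KIND_DEFAULTS[kind])
    params.update(overrides)
    policy = AgentPolicy(kind=kind, **params)
    return Agent(policy, rng=rng)
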