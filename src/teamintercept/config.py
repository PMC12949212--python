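"""Shared configuration objects and seeded random-number streams.

The simulator, the agents, the synthetic humans, and the experiment
generator all draw randomness from named substreams derived from a single
master seed.  Substreams are keyed by a stable integer per purpose so that,
for example, swapping the AI policy does not perturb the target-spawn
sequence of a round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

HUMAN = "human"
AI = "ai"
CENTER = "center"
PLAYERS = (HUMAN, AI)

AGENT_KINDS = ("ignorant", "omit", "divide", "delay", "bottom_feeder")

# Stable ids for the named RNG substreams.  New names append; existing
# numbers never change, or logged rounds stop being reproducible.
_STREAM_IDS = {
    "spawn_position": 1,
    "heading": 2,
    "speed": 3,
    "value": 4,
    "human": 5,
    "agent": 6,
    "experiment": 7,
    "likert": 8,
    "choice": 9,
}


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Independent generator for a named purpose under one master seed.

    ``extra`` integers (participant index, block, round, replicate, ...)
    further split the stream so that nested loops stay independent.
    """
    if name not in _STREAM_IDS:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(_STREAM_IDS)}")
    key = (_STREAM_IDS[name],) + tuple(int(e) for e in extra)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def child_seed(seed: int, *extra: int) -> int:
    """A derived master seed (< 2**31) for an independent sub-experiment."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(e) for e in extra))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class GameConfig:
    """Parameters of one round of the interception game.

    Canonical units: the arena radius is the unit of length and seconds the
    unit of time.  The avatar crosses the arena diameter in ~8 s at the
    default speed, so a 180 s round yields several dozen interceptions per
    team -- the desk-scale analogue of the browser game.
    """

    arena_radius: float = 1.0
    avatar_speed: float = 0.25          # radii per second
    target_density: int = 5             # concurrently maintained target paths (5 or 15)
    round_duration: float = 180.0       # seconds
    tick_dt: float = 0.05               # seconds per simulation tick
    capture_radius: float = 0.03        # interception proximity, radii
    spawn_cone_half_angle: float = math.pi / 4  # heading cone around the inward normal
    value_levels: int = 16              # integer point values 0 .. value_levels-1
    target_speed_range: tuple[float, float] = (0.50, 0.99)  # fraction of avatar speed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_density < 1:
            raise ValueError("target_density must be a positive integer")
        if self.tick_dt <= 0:
            raise ValueError("tick_dt must be positive")
        if not (0 < self.capture_radius < self.arena_radius):
            raise ValueError("capture_radius must satisfy 0 < capture_radius < arena_radius")
        if not (0 < self.spawn_cone_half_angle <= math.pi / 2):
            raise ValueError("spawn_cone_half_angle must lie in (0, pi/2]")
        lo, hi = self.target_speed_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("target_speed_range must satisfy 0 <= lo <= hi < 1")
        if self.round_duration <= 0:
            raise ValueError("round_duration must be positive")
        if self.value_levels < 1:
            raise ValueError("value_levels must be >= 1")

    def with_(self, **kwargs) -> "GameConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AgentConfig:
    """Parameters shared by the five collaborative AI policies.

    kind
        One of ``ignorant``, ``omit``, ``divide``, ``delay``,
        ``bottom_feeder``.
    replan_period
        Seconds between periodic re-searches; the agent also replans
        immediately when its pursued target disappears or leaves its
        consideration set.
    max_sequence_length
        Interception sequences of up to this many targets are enumerated
        (three, matching the real-time budget of the original client).
    ema_window, ema_alpha
        The Delay agent's reaction-time estimate is an exponentially
        weighted mean over the last ``ema_window`` human response times
        with per-step decay ``1 - ema_alpha``.
    initial_delay
        Delay applied before any human response time has been observed.
    rate_objective
        Optional alternative planning objective: value per second rather
        than total value.
    """

    kind: str = "ignorant"
    replan_period: float = 0.5
    max_sequence_length: int = 3
    ema_window: int = 5
    ema_alpha: float = 1.0 / 3.0
    initial_delay: float = 0.5
    rate_objective: bool = False

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; known: {AGENT_KINDS}")
        if self.max_sequence_length < 1:
            raise ValueError("max_sequence_length must be >= 1")
        if self.ema_window < 1:
            raise ValueError("ema_window must be >= 1")
        if not (0 < self.ema_alpha <= 1):
            raise ValueError("ema_alpha must lie in (0, 1]")
        if self.replan_period <= 0:
            raise ValueError("replan_period must be positive")


@dataclass(frozen=True)
class HumanPolicyParams:
    """Parametric simulated human player.

    After completing each action the player waits a lognormal reaction
    time, then picks among interceptable targets by a softmax over
    perceived value rate (perceived value = value + Gaussian noise,
    divided by time-to-intercept).  ``temperature`` -> 0 recovers the
    greedy argmax; large temperatures approach uniform choice.
    ``reclick_rate`` is a per-second hazard of spontaneously retargeting
    mid-pursuit.
    """

    rt_log_mean: float = math.log(0.8)  # median reaction time 0.8 s
    rt_log_sd: float = 0.4
    temperature: float = 1.0
    value_noise_sd: float = 1.0         # points
    reclick_rate: float = 0.10          # per second

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.rt_log_sd < 0:
            raise ValueError("rt_log_sd must be >= 0")
        if self.value_noise_sd < 0:
            raise ValueError("value_noise_sd must be >= 0")
        if self.reclick_rate < 0:
            raise ValueError("reclick_rate must be >= 0")
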