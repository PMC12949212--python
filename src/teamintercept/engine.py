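"""Tick-based simulator of the circular-arena target-interception game.

Two avatars (a human player and an AI teammate) move at a common constant
speed inside a unit disc.  Point-valued targets spawn on the boundary,
traverse the arena along straight chords at 50-99% of avatar speed, and
either get intercepted or exit.  A click on a target sends the avatar to
the closed-form interception point; anything passing within the capture
radius is intercepted incidentally.  The number of maintained target
*paths* -- including "ghost" paths of already-intercepted targets, which
are tracked until they would have reached the perimeter -- is held exactly
at the configured target density, so the spawning process is independent
of player skill.

Everything a round produces is serialized into an ordered event log
(spawns, clicks, interceptions, exits, path-intersection onsets, round
end); the metrics layer works from that log alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import AI, CENTER, HUMAN, PLAYERS, GameConfig, substream

ACTIVE = "active"
INTERCEPTED = "intercepted"
EXITED = "exited"

EV_SPAWN = "spawn"
EV_CLICK = "click"
EV_INTERCEPTION = "interception"
EV_EXIT = "exit"
EV_PATH_INTERSECTION = "path_intersection_onset"
EV_ROUND_END = "round_end"


class EngineError(Exception):
    """Base class for simulator contract violations."""


class UnknownTargetError(EngineError):
    pass


class CapacityError(EngineError):
    pass


class TimeOverrunError(EngineError):
    pass


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def interception_solution(
    avatar_position: tuple[float, float],
    avatar_speed: float,
    target_position: tuple[float, float],
    target_velocity: tuple[float, float],
) -> tuple[float, tuple[float, float]]:
    """Earliest time and point at which a constant-speed pursuer meets a
    constant-velocity target.

    Solves |p_t + t v - p_a| = s t, i.e. the quadratic
    ``(|v|^2 - s^2) t^2 + 2 (d.v) t + |d|^2 = 0`` with
    ``d = p_t - p_a``.  Because the pursuer is strictly faster than the
    target the quadratic has exactly one non-negative root.
    """
    vx, vy = target_velocity
    tspeed2 = vx * vx + vy * vy
    if avatar_speed <= 0 or tspeed2 >= avatar_speed * avatar_speed:
        raise ValueError("avatar must be strictly faster than the target")
    dx = target_position[0] - avatar_position[0]
    dy = target_position[1] - avatar_position[1]
    d2 = dx * dx + dy * dy
    if d2 == 0.0:
        return 0.0, (avatar_position[0], avatar_position[1])
    a = tspeed2 - avatar_speed * avatar_speed  # < 0
    b = 2.0 * (dx * vx + dy * vy)
    # roots t = (-b +- sqrt(b^2 - 4ac)) / (2a); product c/a < 0 so exactly
    # one root is positive -- with a < 0 it is the '-' branch.
    disc = b * b - 4.0 * a * d2
    t = (-b - math.sqrt(disc)) / (2.0 * a)
    return t, (target_position[0] + t * vx, target_position[1] + t * vy)


def interception_times_batch(
    avatar_position: tuple[float, float],
    avatar_speed: float,
    target_positions: np.ndarray,
    target_velocities: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`interception_solution` over N targets.

    Returns (times, points) with shapes (N,), (N, 2).  Inputs must satisfy
    the same feasibility precondition per row.
    """
    d = target_positions - np.asarray(avatar_position)
    v = target_velocities
    a = np.einsum("ij,ij->i", v, v) - avatar_speed**2  # < 0 elementwise
    b = 2.0 * np.einsum("ij,ij->i", d, v)
    c = np.einsum("ij,ij->i", d, d)
    disc = b * b - 4.0 * a * c
    t = (-b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
    t = np.where(c == 0.0, 0.0, t)
    points = target_positions + t[:, None] * v
    return t, points


def clamp_destination(
    avatar_position: tuple[float, float],
    interception_point: tuple[float, float],
    arena_radius: float,
) -> tuple[float, float]:
    """Clip an out-of-arena interception point to the boundary.

    If the point lies outside the closed disc, returns the intersection of
    the segment avatar -> point with the boundary circle; the avatar is
    then guided to the edge of the playable area and halts there.
    """
    px, py = interception_point
    if px * px + py * py <= arena_radius * arena_radius:
        return (px, py)
    ax, ay = avatar_position
    wx, wy = px - ax, py - ay
    # |a + u w|^2 = R^2, u in [0, 1]; the outward crossing is the larger root.
    qa = wx * wx + wy * wy
    qb = 2.0 * (ax * wx + ay * wy)
    qc = ax * ax + ay * ay - arena_radius * arena_radius
    disc = qb * qb - 4.0 * qa * qc
    u = (-qb + math.sqrt(max(disc, 0.0))) / (2.0 * qa)
    return (ax + u * wx, ay + u * wy)


def segments_intersect(
    p1: tuple[float, float],
    p2: tuple[float, float],
    q1: tuple[float, float],
    q2: tuple[float, float],
) -> bool:
    """Orientation test for closed-segment intersection.

    Degenerate (zero-length) segments never intersect anything: a halted
    avatar has no ongoing trajectory to cross.
    """
    if (p1 == p2) or (q1 == q2):
        return False

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return int(v > 0) - int(v < 0)

    o1 = orient(p1, p2, q1)
    o2 = orient(p1, p2, q2)
    o3 = orient(q1, q2, p1)
    o4 = orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True

    def on_segment(a, b, c):
        return (
            min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
            and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
        )

    if o1 == 0 and on_segment(p1, p2, q1):
        return True
    if o2 == 0 and on_segment(p1, p2, q2):
        return True
    if o3 == 0 and on_segment(q1, q2, p1):
        return True
    if o4 == 0 and on_segment(q1, q2, p2):
        return True
    return False


# ---------------------------------------------------------------------------
# Target values
# ---------------------------------------------------------------------------

def sample_target_value(rng: np.random.Generator, value_levels: int = 16) -> int:
    """Integer point value: a Beta(1, 2) draw binned into equal-width bins.

    With 16 levels the bin masses are (31 - 2k)/256 for k = 0..15, so
    low-value targets appear more often than high-value ones.
    """
    u = rng.beta(1.0, 2.0)
    return min(int(u * value_levels), value_levels - 1)


def value_pmf(value_levels: int = 16) -> np.ndarray:
    """Closed-form bin masses of the discretized Beta(1, 2) values.

    P(k) = F((k+1)/L) - F(k/L) with F(x) = 2x - x^2.
    """
    edges = np.arange(value_levels + 1) / value_levels
    cdf = 2.0 * edges - edges**2
    return np.diff(cdf)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class Target:
    id: int
    spawn_position: tuple[float, float]
    velocity: tuple[float, float]
    value: int
    spawn_time: float
    path_expiry_time: float
    status: str = ACTIVE
    interceptor: Optional[str] = None

    def position_at(self, t: float) -> tuple[float, float]:
        dt = t - self.spawn_time
        return (
            self.spawn_position[0] + dt * self.velocity[0],
            self.spawn_position[1] + dt * self.velocity[1],
        )


@dataclass
class AvatarState:
    player: str
    position: tuple[float, float]
    destination: tuple[float, float]
    marked_target: Optional[int] = None
    moving: bool = False


@dataclass
class GameEvent:
    t: float
    type: str
    data: dict = field(default_factory=dict)


EventLog = list  # list[GameEvent]; serialized line-per-event by the io module


@dataclass
class GameState:
    time: float
    targets: dict  # id -> Target (includes expired/ghost for bookkeeping)
    avatars: dict  # player -> AvatarState
    scores: dict  # player -> int
    rngs: dict  # stream name -> np.random.Generator
    next_target_id: int = 0
    tick_index: int = 0
    total_value_spawned: int = 0
    paths_intersecting: bool = False

    def active_targets(self) -> list:
        return [tg for tg in self.targets.values() if tg.status == ACTIVE]

    def unexpired_paths(self) -> list:
        return [tg for tg in self.targets.values() if tg.path_expiry_time > self.time]


# ---------------------------------------------------------------------------
# Spawning
# ---------------------------------------------------------------------------

def spawn_target(state: GameState, config: GameConfig) -> Target:
    """Spawn one target on the boundary, heading inward within the cone.

    Position uniform on the circle; heading uniform within the cone around
    the inward normal; speed uniform in the configured fraction of avatar
    speed; value from the binned Beta(1, 2).  The straight-line exit time
    (chord length / speed) is fixed at spawn and gates the respawn of the
    replacement path.
    """
    if len(state.unexpired_paths()) >= config.target_density:
        raise CapacityError("target path count already at the configured density")
    R = config.arena_radius
    phi = state.rngs["spawn_position"].uniform(0.0, 2.0 * math.pi)
    sx, sy = R * math.cos(phi), R * math.sin(phi)
    heading = phi + math.pi + state.rngs["heading"].uniform(
        -config.spawn_cone_half_angle, config.spawn_cone_half_angle
    )
    lo, hi = config.target_speed_range
    speed = config.avatar_speed * state.rngs["speed"].uniform(lo, hi)
    vx, vy = speed * math.cos(heading), speed * math.sin(heading)
    # chord exit: |s + t v| = R with |s| = R  =>  t = -2 (s.v) / |v|^2
    t_exit = -2.0 * (sx * vx + sy * vy) / (vx * vx + vy * vy)
    value = sample_target_value(state.rngs["value"], config.value_levels)
    target = Target(
        id=state.next_target_id,
        spawn_position=(sx, sy),
        velocity=(vx, vy),
        value=value,
        spawn_time=state.time,
        path_expiry_time=state.time + t_exit,
    )
    state.next_target_id += 1
    state.targets[target.id] = target
    state.total_value_spawned += value
    return target


def _spawn_event(target: Target) -> GameEvent:
    return GameEvent(
        t=target.spawn_time,
        type=EV_SPAWN,
        data={
            "target_id": target.id,
            "position": list(target.spawn_position),
            "velocity": list(target.velocity),
            "value": target.value,
            "path_expiry_time": target.path_expiry_time,
        },
    )


def new_game(config: GameConfig) -> tuple[GameState, list[GameEvent]]:
    """Initial state at t = 0 with the full density of freshly spawned targets.

    Avatars start symmetrically offset from the center (human on the left)
    with their destinations at their own positions.
    """
    rngs = {
        name: substream(config.seed, name)
        for name in ("spawn_position", "heading", "speed", "value")
    }
    x0 = 0.2 * config.arena_radius
    state = GameState(
        time=0.0,
        targets={},
        avatars={
            HUMAN: AvatarState(HUMAN, (-x0, 0.0), (-x0, 0.0)),
            AI: AvatarState(AI, (x0, 0.0), (x0, 0.0)),
        },
        scores={HUMAN: 0, AI: 0},
        rngs=rngs,
    )
    events = []
    for _ in range(config.target_density):
        events.append(_spawn_event(spawn_target(state, config)))
    return state, events


# ---------------------------------------------------------------------------
# Commands and stepping
# ---------------------------------------------------------------------------

def apply_click(
    state: GameState, config: GameConfig, player: str, clicked
) -> list[GameEvent]:
    """Handle a click on a target (or the center token) by ``player``.

    Sets the cross-hair, recomputes the destination as the clamped
    interception point, and records a click event.  Re-clicking mid-path
    is always permitted; current trajectories are simply interrupted.
    """
    avatar = state.avatars[player]
    if clicked == CENTER:
        avatar.marked_target = None
        avatar.destination = (0.0, 0.0)
        avatar.moving = True
        return [GameEvent(state.time, EV_CLICK, {"player": player, "target": CENTER})]
    target = state.targets.get(clicked)
    if target is None or target.status != ACTIVE:
        raise UnknownTargetError(f"target {clicked!r} is not an active target")
    _, point = interception_solution(
        avatar.position,
        config.avatar_speed,
        target.position_at(state.time),
        target.velocity,
    )
    avatar.marked_target = target.id
    avatar.destination = clamp_destination(avatar.position, point, config.arena_radius)
    avatar.moving = True
    return [GameEvent(state.time, EV_CLICK, {"player": player, "target": target.id})]


def _advance_avatar(avatar: AvatarState, speed: float, dt: float) -> None:
    if not avatar.moving:
        return
    px, py = avatar.position
    dx = avatar.destination[0] - px
    dy = avatar.destination[1] - py
    dist = math.hypot(dx, dy)
    step = speed * dt
    if dist <= step or dist == 0.0:
        avatar.position = avatar.destination
        avatar.moving = False
    else:
        f = step / dist
        avatar.position = (px + f * dx, py + f * dy)


def step(
    state: GameState, config: GameConfig, commands: Optional[dict] = None
) -> list[GameEvent]:
    """Advance the simulation by one tick, returning the events emitted.

    Order within a tick: apply clicks at the current time; move avatars
    toward their destinations (halting on arrival); advance time; resolve
    interceptions by capture-radius proximity (each target at most once,
    nearest avatar wins ties, then the human); expire paths that reached
    the boundary (emitting exits for still-active targets) and spawn their
    replacements; detect path-intersection onsets between the two players'
    position->destination segments.
    """
    if state.time + config.tick_dt > config.round_duration + 1e-9:
        raise TimeOverrunError("stepping past round_duration")
    events: list[GameEvent] = []
    if commands:
        for player, clicked in commands.items():
            if clicked is not None:
                events.extend(apply_click(state, config, player, clicked))

    for avatar in state.avatars.values():
        _advance_avatar(avatar, config.avatar_speed, config.tick_dt)

    state.tick_index += 1
    state.time = state.tick_index * config.tick_dt

    t = state.time
    cap = config.capture_radius
    # interceptions: proximity capture, incidental targets included
    for target in state.targets.values():
        if target.status != ACTIVE:
            continue
        tx, ty = target.position_at(t)
        best = None  # (distance, priority, player)
        for player in PLAYERS:
            av = state.avatars[player]
            d = math.hypot(tx - av.position[0], ty - av.position[1])
            if d <= cap:
                prio = 0 if player == HUMAN else 1
                if best is None or (d, prio) < (best[0], best[1]):
                    best = (d, prio, player)
        if best is None:
            continue
        player = best[2]
        other = AI if player == HUMAN else HUMAN
        incidental = state.avatars[player].marked_target != target.id
        other_marked_same = state.avatars[other].marked_target == target.id
        target.status = INTERCEPTED
        target.interceptor = player
        state.scores[player] += target.value
        events.append(
            GameEvent(
                t,
                EV_INTERCEPTION,
                {
                    "player": player,
                    "target_id": target.id,
                    "value": target.value,
                    "incidental": incidental,
                    "other_player_marked_same": other_marked_same,
                },
            )
        )
        for av in state.avatars.values():
            if av.marked_target == target.id:
                av.marked_target = None

    # path expiries -> exits for still-active targets, then replacements
    expired = [tg for tg in state.targets.values() if tg.path_expiry_time <= t and tg.status != EXITED]
    respawns = 0
    for target in expired:
        if target.status == ACTIVE:
            target.status = EXITED
            events.append(GameEvent(t, EV_EXIT, {"target_id": target.id}))
            for av in state.avatars.values():
                if av.marked_target == target.id:
                    av.marked_target = None
        else:
            # ghost path of an intercepted target reached the perimeter;
            # mark it exited so it is not re-counted, but emit no event
            target.status = EXITED
        respawns += 1
    for _ in range(respawns):
        events.append(_spawn_event(spawn_target(state, config)))

    # path-intersection onset detection (debounced)
    h = state.avatars[HUMAN]
    a = state.avatars[AI]
    now = segments_intersect(h.position, h.destination, a.position, a.destination)
    if now and not state.paths_intersecting:
        events.append(GameEvent(t, EV_PATH_INTERSECTION, {}))
    state.paths_intersecting = now
    return events


def run_round(human_policy, ai_policy, config: GameConfig) -> list[GameEvent]:
    """Simulate one full round and return its complete event log.

    Policies implement ``act(state, events) -> optional command`` where a
    command is a target id or the center token; ``events`` are the events
    emitted since the policy last acted.  The loop is fully determined by
    the config seed and the policies.
    """
    state, events = new_game(config)
    log: list[GameEvent] = list(events)
    recent = list(events)
    n_ticks = int(round(config.round_duration / config.tick_dt))
    for _ in range(n_ticks):
        try:
            cmd_h = human_policy.act(state, recent)
            cmd_a = ai_policy.act(state, recent)
        except Exception as exc:  # pragma: no cover - diagnostic context
            raise EngineError(
                f"policy failure at t={state.time:.2f}s (seed {config.seed})"
            ) from exc
        recent = step(state, config, {HUMAN: cmd_h, AI: cmd_a})
        log.extend(recent)
    log.append(
        GameEvent(
            state.time,
            EV_ROUND_END,
            {
                "scores": dict(state.scores),
                "total_value_spawned": state.total_value_spawned,
            },
        )
    )
    return log


class NullPolicy:
    """A player that never clicks; useful as a baseline and in tests."""

    def act(self, state, events):
        return None
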