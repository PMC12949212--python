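"""Interception-sequence planner and the five collaborative AI policies.

All five agents share one search algorithm: enumerate every ordered
sequence of up to three distinct targets, propagating the AI avatar and
the target positions through the sequence, and pick the sequence with the
highest total point value (ties: shorter completion time, then
lexicographic target ids).  The variants differ only in what the search
is allowed to see:

ignorant
    Considers every active target; blind to the human's cross-hair.
omit
    Drops the human's currently marked target and any target sitting on
    the human's interception path; targets the human abandons re-enter.
divide
    The omit set further restricted to targets whose interception point
    lies in the half of the arena away from the human (the dividing line
    runs through the center, orthogonal to the center-to-human direction).
delay
    The omit agent, but after each of its own interceptions it waits for
    an exponentially weighted moving average of the human's last five
    response times before selecting a new target.
bottom_feeder
    The omit agent planning under inverted values (15 - v), so it
    consistently pursues the lowest-value targets; real values still score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import AI, CENTER, HUMAN, AgentConfig, GameConfig
from .engine import (
    ACTIVE,
    EV_CLICK,
    EV_INTERCEPTION,
    GameState,
    interception_solution,
)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Leg:
    target_id: int
    time: float  # absolute interception time, seconds from round start
    point: tuple[float, float]
    value: int   # planning value (possibly inverted for bottom_feeder)


@dataclass(frozen=True)
class Plan:
    legs: tuple[Leg, ...]
    total_value: int
    total_time: float  # seconds from planning instant to final interception

    @property
    def target_ids(self) -> tuple[int, ...]:
        return tuple(leg.target_id for leg in self.legs)


def effective_values(kind: str, targets: dict) -> dict:
    """Planning values per target id; bottom_feeder inverts v -> 15 - v.

    Only the planner sees inverted values -- scoring always uses the real
    ones.
    """
    if kind == "bottom_feeder":
        return {tid: 15 - v for tid, v in targets.items()}
    return dict(targets)


def enumerate_plans(
    state: GameState,
    config: GameConfig,
    consideration: Iterable[int],
    max_len: int,
    value_map: Optional[dict] = None,
) -> list[Plan]:
    """All ordered interception sequences of 1..max_len distinct targets.

    Each leg is solved from the previous leg's interception point and
    time with target positions propagated; a leg is infeasible (pruning
    the sequence there) if the target's path expires before interception
    or the interception point falls outside the arena.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    avatar = state.avatars[AI]
    t0 = state.time
    targets = [
        state.targets[tid]
        for tid in sorted(consideration)
        if state.targets[tid].status == ACTIVE
    ]
    R = config.arena_radius
    speed = config.avatar_speed
    plans: list[Plan] = []

    def recurse(pos, t_abs, used, legs, vsum):
        for tg in targets:
            if tg.id in used:
                continue
            tau, pt = interception_solution(
                pos, speed, tg.position_at(t_abs), tg.velocity
            )
            t_hit = t_abs + tau
            if t_hit > tg.path_expiry_time:
                continue
            if math.hypot(pt[0], pt[1]) > R + _EPS:
                continue
            val = value_map[tg.id] if value_map is not None else tg.value
            new_legs = legs + (Leg(tg.id, t_hit, pt, val),)
            plans.append(Plan(new_legs, vsum + val, t_hit - t0))
            if len(new_legs) < max_len:
                recurse(pt, t_hit, used | {tg.id}, new_legs, vsum + val)

    recurse(avatar.position, t0, frozenset(), (), 0)
    return plans


def best_plan(plans: Sequence[Plan]) -> Optional[Plan]:
    """Highest total value; ties broken by shorter total time, then by
    lexicographic target-id sequence.  Empty input -> None."""
    if not plans:
        return None
    return min(plans, key=lambda p: (-p.total_value, p.total_time, p.target_ids))


def search_best_plan(
    state: GameState,
    config: GameConfig,
    consideration: Iterable[int],
    max_len: int,
    value_map: Optional[dict] = None,
) -> Optional[Plan]:
    """Vectorized equivalent of ``best_plan(enumerate_plans(...))``.

    Expands the sequence tree level by level with batched quadratic
    solves, which keeps replanning cheap at high target density where up
    to 15 + 15*14 + 15*14*13 sequences exist.
    """
    avatar = state.avatars[AI]
    t0 = state.time
    cands = [
        state.targets[tid]
        for tid in sorted(consideration)
        if state.targets[tid].status == ACTIVE
    ]
    nc = len(cands)
    if nc == 0:
        return None
    sp = np.array([tg.spawn_position for tg in cands])
    vel = np.array([tg.velocity for tg in cands])
    st = np.array([tg.spawn_time for tg in cands])
    expiry = np.array([tg.path_expiry_time for tg in cands])
    if value_map is not None:
        vals = np.array([value_map[tg.id] for tg in cands])
    else:
        vals = np.array([tg.value for tg in cands])
    ids = [tg.id for tg in cands]
    speed2 = config.avatar_speed**2
    R2 = (config.arena_radius + _EPS) ** 2
    a_coef = np.einsum("ij,ij->i", vel, vel) - speed2  # < 0 per target

    def expand(P, T, used):
        # P: (m, 2) endpoints; T: (m,) absolute times; used: (m, nc) bool
        tpos = sp[None, :, :] + (T[:, None] - st[None, :])[:, :, None] * vel[None, :, :]
        d = tpos - P[:, None, :]
        b = 2.0 * np.einsum("mjk,jk->mj", d, vel)
        c = np.einsum("mjk,mjk->mj", d, d)
        disc = b * b - 4.0 * a_coef[None, :] * c
        tau = (-b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a_coef[None, :])
        tau = np.where(c == 0.0, 0.0, tau)
        t_hit = T[:, None] + tau
        meet = tpos + tau[:, :, None] * vel[None, :, :]
        inside = np.einsum("mjk,mjk->mj", meet, meet) <= R2
        feas = (~used) & (t_hit <= expiry[None, :]) & inside
        return t_hit, meet, feas

    # Level arrays; chains tracked through (parent, last) indices per level.
    levels = []  # per level: dict with P, T, V, used, parent, last
    P = np.array([avatar.position])
    T = np.array([t0])
    used = np.zeros((1, nc), dtype=bool)
    parent = np.array([-1])
    last = np.array([-1])
    V = np.zeros(1)
    for depth in range(max_len):
        t_hit, meet, feas = expand(P, T, used)
        mi, tj = np.nonzero(feas)
        if mi.size == 0:
            break
        levels.append(
            {
                "parent": mi,
                "last": tj,
                "T": t_hit[mi, tj],
                "V": V[mi] + vals[tj],
            }
        )
        P = meet[mi, tj]
        T = t_hit[mi, tj]
        V = levels[-1]["V"]
        used = used[mi]
        used[np.arange(mi.size), tj] = True
        parent, last = mi, tj
    if not levels:
        return None

    # pick max value, then min completion time, then lexicographic ids
    best = None  # (value, time, level_idx, row)
    vmax = max(lv["V"].max() for lv in levels)
    for li, lv in enumerate(levels):
        rows = np.nonzero(lv["V"] == vmax)[0]
        for r in rows:
            cand = (lv["T"][r], li, r)
            if best is None or cand[0] < best[0] - _EPS:
                best = cand
            elif abs(cand[0] - best[0]) <= _EPS:
                if _chain_ids(levels, li, r, ids) < _chain_ids(levels, best[1], best[2], ids):
                    best = cand
    li, row = best[1], best[2]
    seq = _chain_rows(levels, li, row)
    legs = []
    pos = avatar.position
    t_abs = t0
    for lvl, r in seq:
        tj = levels[lvl]["last"][r]
        tg = cands[tj]
        tau, pt = interception_solution(
            pos, config.avatar_speed, tg.position_at(t_abs), tg.velocity
        )
        t_abs += tau
        legs.append(Leg(tg.id, t_abs, pt, int(vals[tj])))
        pos = pt
    return Plan(tuple(legs), int(round(vmax)), t_abs - t0)


def _chain_rows(levels, li, row):
    seq = []
    while li >= 0:
        seq.append((li, row))
        row = int(levels[li]["parent"][row])
        li -= 1
    return list(reversed(seq))


def _chain_ids(levels, li, row, ids):
    return tuple(ids[levels[lvl]["last"][r]] for lvl, r in _chain_rows(levels, li, row))


# ---------------------------------------------------------------------------
# Consideration sets
# ---------------------------------------------------------------------------

def _point_segment_distance(p, a, b) -> float:
    ax, ay = a
    bx, by = b
    px, py = p
    wx, wy = bx - ax, by - ay
    L2 = wx * wx + wy * wy
    if L2 == 0.0:
        return math.hypot(px - ax, py - ay)
    u = ((px - ax) * wx + (py - ay) * wy) / L2
    u = min(1.0, max(0.0, u))
    return math.hypot(px - (ax + u * wx), py - (ay + u * wy))


def consideration_set(
    kind: str,
    state: GameState,
    config: GameConfig,
    prev_divide_dir: Optional[tuple[float, float]] = None,
) -> tuple[set, Optional[tuple[float, float]]]:
    """Target ids the agent's planner may use, plus the divide direction.

    ignorant: every active target.  omit family (omit/delay/bottom_feeder):
    all active targets minus the human's currently marked target and any
    active target lying within the capture radius of the human's current
    interception path; previously marked but abandoned targets re-enter.
    divide: the omit set further restricted to targets whose AI
    interception point lies strictly in the open half-plane away from the
    human (the boundary passes through the center, orthogonal to the
    center->human vector).  A human exactly at the center leaves the line
    undefined: the previous line is reused, or, failing that, the omit set
    is returned unchanged.

    Returns ``(ids, divide_dir)`` where ``divide_dir`` is the unit
    center->human vector actually used (None for non-divide kinds).
    """
    active = {tg.id for tg in state.targets.values() if tg.status == ACTIVE}
    if kind == "ignorant":
        return active, None
    human = state.avatars[HUMAN]
    t = state.time
    excluded = set()
    if human.marked_target is not None:
        excluded.add(human.marked_target)
        for tid in active:
            if tid == human.marked_target:
                continue
            tg = state.targets[tid]
            d = _point_segment_distance(
                tg.position_at(t), human.position, human.destination
            )
            if d <= config.capture_radius:
                excluded.add(tid)
    ids = active - excluded
    if kind != "divide":
        return ids, None
    hx, hy = human.position
    norm = math.hypot(hx, hy)
    if norm < 1e-9:
        if prev_divide_dir is None:
            return ids, None
        ux, uy = prev_divide_dir
    else:
        ux, uy = hx / norm, hy / norm
    ai = state.avatars[AI]
    kept = set()
    for tid in ids:
        tg = state.targets[tid]
        _, pt = interception_solution(
            ai.position, config.avatar_speed, tg.position_at(t), tg.velocity
        )
        if pt[0] * ux + pt[1] * uy < 0.0:
            kept.add(tid)
    return kept, (ux, uy)


# ---------------------------------------------------------------------------
# Response-time EMA (Delay agent)
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    """Mutable per-round memory of a collaborative agent."""

    current_plan: Optional[Plan] = None
    pursued: Optional[int] = None
    delay_until: Optional[float] = None
    rt_buffer: list = field(default_factory=list)  # newest last, len <= window
    rt_ema: Optional[float] = None
    last_plan_time: float = -math.inf
    divide_dir: Optional[tuple[float, float]] = None
    last_human_completion: Optional[float] = None


def update_rt_ema(
    agent_state: AgentState, new_rt: float, ema_alpha: float, ema_window: int
) -> AgentState:
    """Push a human response time and recompute the windowed EMA.

    The buffer keeps at most ``ema_window`` values; the estimate is the
    weighted mean with weights (1 - alpha)^age (age 0 = newest), honoring
    both the "exponential moving average" and the "previous five" clauses.
    """
    if new_rt < 0:
        raise ValueError("response times must be non-negative")
    agent_state.rt_buffer.append(float(new_rt))
    del agent_state.rt_buffer[:-ema_window]
    buf = agent_state.rt_buffer
    weights = [(1.0 - ema_alpha) ** (len(buf) - 1 - i) for i in range(len(buf))]
    agent_state.rt_ema = sum(w * r for w, r in zip(weights, buf)) / sum(weights)
    return agent_state


# ---------------------------------------------------------------------------
# The per-tick policy
# ---------------------------------------------------------------------------

def agent_act(
    agent_config: AgentConfig,
    agent_state: AgentState,
    game_state: GameState,
    events: Sequence,
    game_config: GameConfig,
):
    """One tick of a collaborative agent; returns (command, agent_state).

    Replans when the pursued target is gone, when it leaves the
    consideration set, or when the replan period has elapsed; the delay
    agent additionally defers re-selection after its own interceptions by
    the current response-time estimate.  The emitted command is a click on
    the first leg of the best plan (only when it differs from the target
    already pursued -- the interception point of a constant-velocity
    target does not move, so re-clicking the same target is redundant).
    """
    kind = agent_config.kind
    for ev in events:
        if ev.type == EV_CLICK and ev.data.get("player") == HUMAN:
            if ev.data.get("target") != "center" and agent_state.last_human_completion is not None:
                rt = ev.t - agent_state.last_human_completion
                update_rt_ema(agent_state, rt, agent_config.ema_alpha, agent_config.ema_window)
                agent_state.last_human_completion = None
        elif ev.type == EV_INTERCEPTION:
            if ev.data.get("player") == HUMAN and not ev.data.get("incidental"):
                agent_state.last_human_completion = ev.t
            if (
                kind == "delay"
                and ev.data.get("player") == AI
                and not ev.data.get("incidental")
            ):
                wait = agent_state.rt_ema if agent_state.rt_ema is not None else agent_config.initial_delay
                agent_state.delay_until = ev.t + wait
                agent_state.pursued = None
                agent_state.current_plan = None

    t = game_state.time
    if kind == "delay" and agent_state.delay_until is not None:
        if t < agent_state.delay_until:
            return None, agent_state
        agent_state.delay_until = None

    ids, ddir = consideration_set(kind, game_state, game_config, agent_state.divide_dir)
    if ddir is not None:
        agent_state.divide_dir = ddir

    pursued = agent_state.pursued
    pursued_alive = (
        pursued is not None
        and pursued in game_state.targets
        and game_state.targets[pursued].status == ACTIVE
    )
    need = (
        not pursued_alive
        or pursued not in ids
        or (t - agent_state.last_plan_time) >= agent_config.replan_period
    )
    if not need:
        return None, agent_state

    values = {tid: game_state.targets[tid].value for tid in ids}
    vmap = effective_values(kind, values)
    if agent_config.rate_objective:
        plans = enumerate_plans(
            game_state, game_config, ids, agent_config.max_sequence_length, vmap
        )
        plan = None
        if plans:
            plan = min(
                plans,
                key=lambda p: (
                    -(p.total_value / p.total_time if p.total_time > 0 else math.inf),
                    p.total_time,
                    p.target_ids,
                ),
            )
    else:
        plan = search_best_plan(
            game_state, game_config, ids, agent_config.max_sequence_length, vmap
        )
    agent_state.last_plan_time = t
    agent_state.current_plan = plan
    if plan is None:
        # No feasible sequence.  If we were still heading for a target that
        # left our consideration set (e.g. the human just marked it), back
        # off to the center so our cross-hair and path release it.
        cmd = CENTER if (pursued_alive and pursued not in ids) else None
        agent_state.pursued = None
        return cmd, agent_state
    first = plan.legs[0].target_id
    if first == pursued and pursued_alive:
        return None, agent_state
    agent_state.pursued = first
    return first, agent_state


class AgentPolicy:
    """Policy-contract wrapper: ``act(state, events) -> optional command``."""

    def __init__(self, agent_config: AgentConfig, game_config: GameConfig):
        self.config = agent_config
        self.game_config = game_config
        self.state = AgentState()

    def act(self, state: GameState, events: Sequence):
        cmd, self.state = agent_act(
            self.config, self.state, state, events, self.game_config
        )
        return cmd


def make_agent(kind: str, game_config: GameConfig, **kwargs) -> AgentPolicy:
    return AgentPolicy(AgentConfig(kind=kind, **kwargs), game_config)
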