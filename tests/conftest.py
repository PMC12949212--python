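"""Shared fixtures: hand-built boards, scripted policies, oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from teamintercept.config import AI, HUMAN, GameConfig
from teamintercept.engine import ACTIVE, AvatarState, GameState, Target


@pytest.fixture
def config():
    return GameConfig(seed=0)


def make_board(
    targets,
    human_pos=(-0.5, 0.0),
    ai_pos=(0.5, 0.0),
    t=0.0,
    human_marked=None,
    human_dest=None,
):
    """GameState with hand-placed targets.

    ``targets`` is a list of dicts with keys pos, vel, value and optional
    expiry (default: the true chord-exit time of the straight-line path,
    or +inf for stationary targets).
    """
    tgs = {}
    for i, spec in enumerate(targets):
        pos = tuple(spec["pos"])
        vel = tuple(spec.get("vel", (0.0, 0.0)))
        if "expiry" in spec:
            expiry = spec["expiry"]
        elif vel == (0.0, 0.0):
            expiry = math.inf
        else:
            # time until |pos + s v| = 1 along the forward ray
            a = vel[0] ** 2 + vel[1] ** 2
            b = 2 * (pos[0] * vel[0] + pos[1] * vel[1])
            c = pos[0] ** 2 + pos[1] ** 2 - 1.0
            disc = b * b - 4 * a * c
            expiry = t + (-b + math.sqrt(max(disc, 0.0))) / (2 * a)
        tgs[i] = Target(
            id=i,
            spawn_position=pos,
            velocity=vel,
            value=int(spec.get("value", 5)),
            spawn_time=t,
            path_expiry_time=expiry,
            status=spec.get("status", ACTIVE),
        )
    hd = tuple(human_dest) if human_dest is not None else tuple(human_pos)
    return GameState(
        time=t,
        targets=tgs,
        avatars={
            HUMAN: AvatarState(HUMAN, tuple(human_pos), hd, marked_target=human_marked,
                               moving=hd != tuple(human_pos)),
            AI: AvatarState(AI, tuple(ai_pos), tuple(ai_pos)),
        },
        scores={HUMAN: 0, AI: 0},
        rngs={},
    )


class ScriptedPolicy:
    """Clicks from a fixed schedule of (time, command) pairs."""

    def __init__(self, schedule):
        self.schedule = sorted(schedule)
        self.i = 0

    def act(self, state, events):
        if self.i < len(self.schedule) and state.time >= self.schedule[self.i][0]:
            cmd = self.schedule[self.i][1]
            self.i += 1
            return cmd
        return None


def pursuit_time_oracle(avatar_pos, avatar_speed, target_pos, target_vel, dt=1e-4):
    """First time on a dt grid at which the target is reachable:
    min t with |target(t) - avatar| <= speed * t.  Independent of the
    closed-form quadratic."""
    d0 = math.hypot(target_pos[0] - avatar_pos[0], target_pos[1] - avatar_pos[1])
    vmax = math.hypot(*target_vel)
    t_hi = d0 / (avatar_speed - vmax) + 10 * dt
    ts = np.arange(0.0, t_hi + dt, dt)
    px = target_pos[0] + ts * target_vel[0] - avatar_pos[0]
    py = target_pos[1] + ts * target_vel[1] - avatar_pos[1]
    reach = np.hypot(px, py) <= avatar_speed * ts
    idx = np.argmax(reach)
    assert reach[idx], "oracle horizon too short"
    return ts[idx]
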