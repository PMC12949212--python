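"""Planner and collaborative-policy tests: consideration sets, sequence
search vs brute force, value inversion, the RT EMA, and replan behavior."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from teamintercept.agents import (
    AgentConfig,
    AgentPolicy,
    AgentState,
    agent_act,
    best_plan,
    consideration_set,
    effective_values,
    enumerate_plans,
    search_best_plan,
    update_rt_ema,
)
from teamintercept.config import AI, CENTER, HUMAN, GameConfig
from teamintercept.engine import GameEvent, EV_CLICK, EV_INTERCEPTION

from conftest import make_board


def random_board(rng, n_targets, radius=1.0, avatar_speed=0.25):
    targets = []
    for _ in range(n_targets):
        r = math.sqrt(rng.uniform(0, 1)) * 0.9
        ang = rng.uniform(0, 2 * math.pi)
        pos = (r * math.cos(ang), r * math.sin(ang))
        spd = rng.uniform(0.5, 0.99) * avatar_speed
        h = rng.uniform(0, 2 * math.pi)
        vel = (spd * math.cos(h), spd * math.sin(h))
        # forward chord-exit time from current position
        a = vel[0] ** 2 + vel[1] ** 2
        b = 2 * (pos[0] * vel[0] + pos[1] * vel[1])
        c = pos[0] ** 2 + pos[1] ** 2 - radius**2
        t_exit = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        targets.append(
            {"pos": pos, "vel": vel, "value": int(rng.integers(0, 16)), "expiry": t_exit}
        )
    return make_board(targets, ai_pos=tuple(rng.uniform(-0.5, 0.5, 2)))


def resimulate_sequence(state, config, seq):
    """Independent per-sequence oracle: propagate the AI through ``seq``
    using bracketed root finding on |target(t) - pos| = speed * t."""
    pos = state.avatars[AI].position
    t_abs = state.time
    total = 0
    for tid in seq:
        tg = state.targets[tid]

        def gap(tau):
            tp = tg.position_at(t_abs + tau)
            return math.hypot(tp[0] - pos[0], tp[1] - pos[1]) - config.avatar_speed * tau

        if gap(0.0) <= 0:
            tau = 0.0
        else:
            hi = 1.0
            while gap(hi) > 0:
                hi *= 2
                if hi > 1e6:
                    return None
            tau = brentq(gap, 0.0, hi, xtol=1e-12)
        t_abs += tau
        pt = tg.position_at(t_abs)
        if t_abs > tg.path_expiry_time or math.hypot(*pt) > config.arena_radius + 1e-9:
            return None
        pos = pt
        total += tg.value
    return total, t_abs - state.time


class TestEnumeratePlans:
    def test_empty_consideration(self, config):
        state = random_board(np.random.default_rng(0), 3)
        assert enumerate_plans(state, config, set(), 3) == []

    def test_single_feasible_target(self, config):
        state = make_board([{"pos": (0.0, 0.0), "value": 4}])
        plans = enumerate_plans(state, config, {0}, 3)
        assert len(plans) == 1
        assert plans[0].target_ids == (0,) and plans[0].total_value == 4

    def test_counts_and_totals_match_resimulation(self, config):
        rng = np.random.default_rng(42)
        for _ in range(15):
            state = random_board(rng, 5)
            plans = enumerate_plans(state, config, set(state.targets), 3)
            assert len(plans) <= 5 + 5 * 4 + 5 * 4 * 3
            for p in plans:
                oracle = resimulate_sequence(state, config, p.target_ids)
                assert oracle is not None
                val, dur = oracle
                assert p.total_value == val
                assert p.total_time == pytest.approx(dur, abs=1e-7)

    def test_leg_times_strictly_increase(self, config):
        state = random_board(np.random.default_rng(3), 4)
        for p in enumerate_plans(state, config, set(state.targets), 3):
            times = [leg.time for leg in p.legs]
            assert all(b > a for a, b in zip(times, times[1:]))


class TestBestPlan:
    def test_tie_breaks(self):
        from teamintercept.agents import Leg, Plan

        def plan(ids, value, time):
            legs = tuple(Leg(i, 1.0, (0, 0), 0) for i in ids)
            return Plan(legs, value, time)

        plans = [plan((1,), 7, 3.0), plan((2,), 12, 6.0), plan((3,), 12, 4.0)]
        assert best_plan(plans).target_ids == (3,)
        assert best_plan([plans[0]]) is plans[0]
        assert best_plan([]) is None
        # equal value and time -> lexicographic ids
        tied = [plan((5,), 9, 2.0), plan((2,), 9, 2.0)]
        assert best_plan(tied).target_ids == (2,)

    def test_vectorized_search_matches_enumeration(self, config):
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(1, 7))
            state = random_board(rng, n)
            ids = set(state.targets)
            ref = best_plan(enumerate_plans(state, config, ids, 3))
            fast = search_best_plan(state, config, ids, 3)
            if ref is None:
                assert fast is None
                continue
            assert fast.target_ids == ref.target_ids
            assert fast.total_value == ref.total_value
            assert fast.total_time == pytest.approx(ref.total_time, abs=1e-7)


class TestEffectiveValues:
    def test_inversion_endpoints_and_identity(self):
        vals = {1: 15, 2: 0, 3: 7}
        inv = effective_values("bottom_feeder", vals)
        assert inv == {1: 0, 2: 15, 3: 8}
        assert effective_values("omit", vals) == vals

    def test_bottom_feeder_single_leg_targets_minimum(self, config):
        rng = np.random.default_rng(6)
        for _ in range(20):
            state = random_board(rng, 3)
            ids = set(state.targets)
            vmap = effective_values(
                "bottom_feeder", {i: state.targets[i].value for i in ids}
            )
            plans = [p for p in enumerate_plans(state, config, ids, 1, vmap)]
            if not plans:
                continue
            chosen = best_plan(plans)
            feasible_vals = [state.targets[p.target_ids[0]].value for p in plans]
            assert state.targets[chosen.target_ids[0]].value == min(feasible_vals)


class TestConsiderationSets:
    def test_ignorant_includes_marked(self, config):
        state = make_board(
            [{"pos": (0.0, 0.3)}, {"pos": (0.0, -0.3)}], human_marked=0
        )
        ids, _ = consideration_set("ignorant", state, config)
        assert ids == {0, 1}

    def test_omit_excludes_marked_and_on_path(self, config):
        # human at (-0.5,0) heading to (0.5,0); target 1 sits on that path
        state = make_board(
            [
                {"pos": (0.5, 0.0)},
                {"pos": (0.0, 0.001)},
                {"pos": (0.0, 0.5)},
            ],
            human_pos=(-0.5, 0.0),
            human_dest=(0.5, 0.0),
            human_marked=0,
        )
        ids, _ = consideration_set("omit", state, config)
        assert ids == {2}

    def test_abandoned_target_reincluded(self, config):
        state = make_board([{"pos": (0.0, 0.3)}, {"pos": (0.0, -0.3)}], human_marked=0)
        ids, _ = consideration_set("omit", state, config)
        assert 0 not in ids
        state.avatars[HUMAN].marked_target = 1
        state.avatars[HUMAN].destination = state.avatars[HUMAN].position
        ids, _ = consideration_set("omit", state, config)
        assert 0 in ids and 1 not in ids

    def test_divide_half_plane(self, config):
        # human at (0.5, 0): the AI may only take targets whose interception
        # point has x < 0
        state = make_board(
            [{"pos": (-0.5, 0.2)}, {"pos": (0.4, -0.2)}],
            human_pos=(0.5, 0.0),
            ai_pos=(0.0, 0.0),
        )
        ids, ddir = consideration_set("divide", state, config)
        assert ids == {0}
        assert ddir == pytest.approx((1.0, 0.0))

    def test_divide_center_degenerate_falls_back(self, config):
        state = make_board(
            [{"pos": (-0.5, 0.2)}, {"pos": (0.4, -0.2)}], human_pos=(0.0, 0.0)
        )
        ids, ddir = consideration_set("divide", state, config, prev_divide_dir=None)
        assert ids == {0, 1}  # omit set unchanged
        ids, _ = consideration_set(
            "divide", state, config, prev_divide_dir=(1.0, 0.0)
        )
        assert ids == {0}


class TestRtEma:
    def test_constant_buffer_returns_constant(self):
        st = AgentState()
        for _ in range(7):
            update_rt_ema(st, 0.9, 1 / 3, 5)
        assert st.rt_ema == pytest.approx(0.9)
        assert len(st.rt_buffer) == 5

    def test_single_observation(self):
        st = AgentState()
        update_rt_ema(st, 1.4, 1 / 3, 5)
        assert st.rt_ema == pytest.approx(1.4)

    def test_eviction_and_weighted_mean(self):
        st = AgentState()
        for rt in [1, 2, 3, 4, 5, 6]:
            update_rt_ema(st, rt, 1 / 3, 5)
        assert st.rt_buffer == [2, 3, 4, 5, 6]
        w = [(2 / 3) ** (4 - i) for i in range(5)]
        expected = sum(wi * ri for wi, ri in zip(w, [2, 3, 4, 5, 6])) / sum(w)
        assert st.rt_ema == pytest.approx(expected)

    def test_negative_rt_rejected(self):
        with pytest.raises(ValueError):
            update_rt_ema(AgentState(), -0.1, 1 / 3, 5)


class TestAgentAct:
    def test_omit_replans_away_when_human_clicks_pursued(self, config):
        state = make_board(
            [{"pos": (0.2, 0.1)}, {"pos": (-0.1, -0.4)}], ai_pos=(0.5, 0.0)
        )
        ast = AgentState()
        cmd, ast = agent_act(AgentConfig(kind="omit"), ast, state, [], config)
        assert cmd is not None
        pursued = cmd
        # human marks the pursued target
        state.avatars[HUMAN].marked_target = pursued
        state.avatars[HUMAN].destination = state.targets[pursued].position_at(0.0)
        state.time = 0.05
        cmd2, ast = agent_act(AgentConfig(kind="omit"), ast, state, [], config)
        assert cmd2 is not None and cmd2 != pursued

    def test_omit_backs_off_to_center_when_nothing_left(self, config):
        state = make_board([{"pos": (0.2, 0.1)}], ai_pos=(0.5, 0.0))
        ast = AgentState()
        cmd, ast = agent_act(AgentConfig(kind="omit"), ast, state, [], config)
        assert cmd == 0
        state.avatars[HUMAN].marked_target = 0
        state.avatars[HUMAN].destination = state.targets[0].position_at(0.0)
        state.time = 0.05
        cmd2, ast = agent_act(AgentConfig(kind="omit"), ast, state, [], config)
        assert cmd2 == CENTER and ast.pursued is None

    def test_delay_waits_after_own_interception(self, config):
        state = make_board([{"pos": (0.2, 0.1)}, {"pos": (-0.3, 0.2)}])
        ast = AgentState()
        update_rt_ema(ast, 0.8, 1 / 3, 5)
        events = [
            GameEvent(
                10.0,
                EV_INTERCEPTION,
                {"player": AI, "target_id": 0, "incidental": False},
            )
        ]
        state.time = 10.0
        state.targets[0].status = "intercepted"
        cmd, ast = agent_act(AgentConfig(kind="delay"), ast, state, events, config)
        assert cmd is None and ast.delay_until == pytest.approx(10.8)
        state.time = 10.75
        cmd, ast = agent_act(AgentConfig(kind="delay"), ast, state, [], config)
        assert cmd is None
        state.time = 10.8
        cmd, ast = agent_act(AgentConfig(kind="delay"), ast, state, [], config)
        assert cmd is not None

    def test_delay_harvests_human_rts_from_events(self, config):
        state = make_board([{"pos": (0.2, 0.1)}])
        ast = AgentState()
        events = [
            GameEvent(5.0, EV_INTERCEPTION, {"player": HUMAN, "target_id": 0, "incidental": False}),
            GameEvent(6.2, EV_CLICK, {"player": HUMAN, "target": 0}),
        ]
        agent_act(AgentConfig(kind="delay"), ast, state, events, config)
        assert ast.rt_ema == pytest.approx(1.2)

    def test_ignorant_follows_planner_on_static_board(self, config):
        # stationary targets: the click sequence should replay the best plan
        state = make_board(
            [
                {"pos": (0.3, 0.0), "value": 9},
                {"pos": (0.0, 0.4), "value": 9},
                {"pos": (-0.4, -0.2), "value": 9},
            ],
            ai_pos=(0.5, 0.0),
        )
        plan = search_best_plan(state, config, set(state.targets), 3)
        ast = AgentState()
        clicked = []
        t = 0.0
        for expected in plan.target_ids:
            cmd, ast = agent_act(AgentConfig(kind="ignorant"), ast, state, [], config)
            assert cmd == expected
            clicked.append(cmd)
            # simulate the interception of the clicked target
            state.targets[cmd].status = "intercepted"
            leg = [l for l in plan.legs if l.target_id == cmd][0]
            state.avatars[AI].position = leg.point
            t = leg.time
            state.time = t
        assert clicked == list(plan.target_ids)
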