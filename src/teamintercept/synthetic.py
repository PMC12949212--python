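"""Synthetic human players and a full synthetic-experiment generator.

The human stand-in is a parametric policy -- lognormal reaction times, a
softmax choice over noisy value rates, and a small spontaneous-retarget
hazard -- that makes no claim of cognitive fidelity; it exists so every
downstream stage (agents, metrics, preference model) can be exercised and
validated end to end without behavioral data.

The experiment generator reproduces the study design: per participant,
two blocks (one per target density, counterbalanced) of two rounds each
(one per assigned agent, order counterbalanced), eight 7-point Likert
ratings per agent per block, and one pairwise choice per block drawn from
a Bradley-Terry logistic over the realized feature differences under a
known ground-truth coefficient vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    AGENT_KINDS,
    AI,
    HUMAN,
    GameConfig,
    HumanPolicyParams,
    child_seed,
    substream,
)
from .engine import (
    ACTIVE,
    EV_EXIT,
    EV_INTERCEPTION,
    GameState,
    interception_solution,
    run_round,
)
from .agents import make_agent
from .metrics import (
    OBJECTIVE_FEATURES,
    SUBJECTIVE_FEATURES,
    round_metrics,
    objective_features,
)


# ---------------------------------------------------------------------------
# Synthetic human policy
# ---------------------------------------------------------------------------

def softmax_choice(scores: np.ndarray, temperature: float, rng: np.random.Generator) -> int:
    """Index sampled by softmax; temperature 0 is the argmax limit."""
    scores = np.asarray(scores, dtype=float)
    if temperature <= 0.0:
        return int(np.argmax(scores))
    z = (scores - scores.max()) / temperature
    w = np.exp(z)
    w /= w.sum()
    return int(rng.choice(len(scores), p=w))


class SyntheticHuman:
    """Policy-contract implementation of the parametric human player.

    After each completed action (own interception, loss of the pursued
    target, or arrival at the destination) the player waits a lognormal
    reaction time and then clicks the softmax winner among interceptable
    targets scored by (value + noise) / time-to-intercept.
    """

    def __init__(
        self,
        params: HumanPolicyParams,
        game_config: GameConfig,
        rng: np.random.Generator,
    ):
        self.params = params
        self.game_config = game_config
        self.rng = rng
        self.pursued: Optional[int] = None
        self.waiting = True
        self.next_decision_time = self._draw_rt()  # round start counts as a completion

    def _draw_rt(self) -> float:
        return float(
            self.rng.lognormal(self.params.rt_log_mean, self.params.rt_log_sd)
        )

    def _completion(self, t: float) -> None:
        self.pursued = None
        self.waiting = True
        self.next_decision_time = t + self._draw_rt()

    def _choose(self, state: GameState) -> Optional[int]:
        cfg = self.game_config
        avatar = state.avatars[HUMAN]
        t = state.time
        cands, scores = [], []
        for tg in state.targets.values():
            if tg.status != ACTIVE:
                continue
            tau, pt = interception_solution(
                avatar.position, cfg.avatar_speed, tg.position_at(t), tg.velocity
            )
            if t + tau > tg.path_expiry_time:
                continue
            if math.hypot(pt[0], pt[1]) > cfg.arena_radius + 1e-12:
                continue
            perceived = tg.value + self.rng.normal(0.0, self.params.value_noise_sd)
            cands.append(tg.id)
            scores.append(perceived / max(tau, cfg.tick_dt))
        if not cands:
            return None
        return cands[softmax_choice(np.array(scores), self.params.temperature, self.rng)]

    def act(self, state: GameState, events: Sequence):
        t = state.time
        if not self.waiting:
            done = False
            for ev in events:
                if (
                    ev.type == EV_INTERCEPTION
                    and ev.data.get("target_id") == self.pursued
                ):
                    done = True
                elif ev.type == EV_EXIT and ev.data.get("target_id") == self.pursued:
                    done = True
            if not done and not state.avatars[HUMAN].moving:
                done = True  # reached destination (e.g. clamped boundary point)
            if done:
                self._completion(t)
            elif self.params.reclick_rate > 0 and (
                self.rng.random() < self.params.reclick_rate * self.game_config.tick_dt
            ):
                choice = self._choose(state)
                if choice is not None and choice != self.pursued:
                    self.pursued = choice
                    return choice
        if self.waiting and t >= self.next_decision_time:
            choice = self._choose(state)
            if choice is None:
                self.next_decision_time = t + 0.25  # nothing catchable; retry soon
                return None
            self.waiting = False
            self.pursued = choice
            return choice
        return None


# ---------------------------------------------------------------------------
# Study design and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionDesign:
    participant_id: int
    agent_pair: tuple[str, str]  # distinct kinds
    density_order: tuple[int, int]  # permutation of (5, 15)
    agent_order_per_block: tuple[tuple[str, str], tuple[str, str]]
    survey_choice_order: str  # "survey_first" | "choice_first"

    def __post_init__(self) -> None:
        if self.agent_pair[0] == self.agent_pair[1]:
            raise ValueError("the two agents of a session must be distinct")


def make_designs(n_participants: int) -> list[SessionDesign]:
    """Counterbalanced session designs cycling through all cells.

    Cells: 10 unordered agent pairs x 2 density orders x 2 first-block
    agent orders x 2 survey/choice orders; the second block presents the
    agents in reversed order.
    """
    pairs = list(itertools.combinations(AGENT_KINDS, 2))
    cells = list(
        itertools.product(pairs, [(5, 15), (15, 5)], [0, 1], ["survey_first", "choice_first"])
    )
    designs = []
    for pid in range(n_participants):
        pair, dens, flip, sco = cells[pid % len(cells)]
        first = (pair[1], pair[0]) if flip else pair
        designs.append(
            SessionDesign(
                participant_id=pid,
                agent_pair=pair,
                density_order=dens,
                agent_order_per_block=(first, (first[1], first[0])),
                survey_choice_order=sco,
            )
        )
    return designs


@dataclass(frozen=True)
class GroundTruthPreference:
    """Generating coefficients for synthetic choices and ratings.

    ``betas`` maps feature names (objective metrics and/or Likert items)
    to utility weights on raw feature differences; ``beta0`` is the
    first-presented-agent order bias.  ``likert_loadings`` gives each
    item's latent mean per agent kind; observed ratings add Gaussian
    noise and clamp to the 7-point scale.
    """

    beta0: float
    betas: dict
    likert_loadings: dict
    likert_noise_sd: float = 1.2


def default_truth() -> GroundTruthPreference:
    """Reference ground truth: inequality- and steal-averse choices with
    teaming-flavored ratings penalizing the ignorant agent."""
    base = {k: 5.0 for k in AGENT_KINDS}
    loadings = {q: dict(base) for q in SUBJECTIVE_FEATURES}
    for q, val in [
        ("q1", 3.0),  # teammate feel
        ("q4", 2.8),  # understood my intentions
        ("q5", 3.5),
        ("q6", 3.2),  # ease of collaboration
        ("q7", 3.4),  # enjoyment
        ("q8", 3.0),  # similar playing style
    ]:
        loadings[q]["ignorant"] = val
    loadings["q2"]["ignorant"] = 5.5  # competent
    loadings["q2"]["bottom_feeder"] = 4.0
    loadings["q3"] = {k: 4.5 for k in AGENT_KINDS}  # intentions equally opaque
    betas = {f: 0.0 for f in OBJECTIVE_FEATURES + SUBJECTIVE_FEATURES}
    betas.update(
        {"score_inequality": -6.0, "steals": -0.25, "q1": 0.35, "q4": 0.2, "q8": 0.35}
    )
    return GroundTruthPreference(beta0=0.3, betas=betas, likert_loadings=loadings)


# ---------------------------------------------------------------------------
# Choice generation and the full experiment
# ---------------------------------------------------------------------------

def generate_choices(
    feature_diffs: pd.DataFrame,
    truth: GroundTruthPreference,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli choice labels (1 = first-presented) from the logistic
    Bradley-Terry model over raw feature differences."""
    missing = set(truth.betas) - set(feature_diffs.columns)
    if missing:
        raise KeyError(f"feature mismatch: diffs lack columns {sorted(missing)}")
    eta = truth.beta0 + sum(
        beta * feature_diffs[name].to_numpy(dtype=float)
        for name, beta in truth.betas.items()
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(feature_diffs)) < p).astype(int)


def _likert_ratings(
    truth: GroundTruthPreference, kind: str, rng: np.random.Generator
) -> dict:
    out = {}
    for q in SUBJECTIVE_FEATURES:
        mu = truth.likert_loadings[q][kind]
        val = int(round(mu + rng.normal(0.0, truth.likert_noise_sd)))
        out[q] = min(7, max(1, val))
    return out


def simulate_experiment(
    n_participants: int,
    designs: Optional[Sequence[SessionDesign]],
    human_params: HumanPolicyParams,
    truth: GroundTruthPreference,
    config: GameConfig,
    seed: int,
    collect_logs: bool = False,
):
    """Simulate the full study; returns (logs, ratings table, choices table).

    ``logs`` maps (participant, block, agent kind) -> event log when
    ``collect_logs`` is set (they are memory-heavy for large cohorts).
    One pairwise choice is sampled per block from the logistic model over
    the realized feature differences (objective metrics and Likert items)
    of the two agents in presentation order.
    """
    if designs is None:
        designs = make_designs(n_participants)
    designs = list(designs)[:n_participants]
    logs = {} if collect_logs else None
    rating_rows, choice_rows = [], []
    features = OBJECTIVE_FEATURES + SUBJECTIVE_FEATURES
    for d in designs:
        pid = d.participant_id
        for block, density in enumerate(d.density_order):
            order = d.agent_order_per_block[block]
            per_agent = {}
            for k, kind in enumerate(order):
                rseed = child_seed(seed, pid, block, k)
                cfg = config.with_(target_density=density, seed=rseed)
                human = SyntheticHuman(
                    human_params, cfg, substream(seed, "human", pid, block, k)
                )
                agent = make_agent(kind, cfg)
                log = run_round(human, agent, cfg)
                if collect_logs:
                    logs[(pid, block, kind)] = log
                m = round_metrics(log)
                feats = objective_features(m)
                feats.update(
                    _likert_ratings(truth, kind, substream(seed, "likert", pid, block, k))
                )
                per_agent[kind] = feats
                rating_rows.append(
                    {
                        "participant_id": pid,
                        "block": block,
                        "density": density,
                        "agent": kind,
                        **{q: feats[q] for q in SUBJECTIVE_FEATURES},
                    }
                )
            first, second = order
            diffs = pd.DataFrame(
                [{f: per_agent[first][f] - per_agent[second][f] for f in features}]
            )
            label = generate_choices(diffs, truth, substream(seed, "choice", pid, block))[0]
            row = {
                "participant_id": pid,
                "block": block,
                "density": density,
                "agent_first": first,
                "agent_second": second,
                "survey_choice_order": d.survey_choice_order,
                "choice": "first" if label == 1 else "second",
            }
            for f in features:
                row[f"first_{f}"] = per_agent[first][f]
                row[f"second_{f}"] = per_agent[second][f]
            choice_rows.append(row)
    ratings = pd.DataFrame(rating_rows)
    choices = pd.DataFrame(choice_rows)
    return logs, ratings, choices
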