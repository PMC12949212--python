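"""Objective behavioral metrics computed from round event logs.

Every metric here is recomputable from a serialized log alone, so online
and replayed analyses agree exactly.  "Relative" scores divide points by
the total point value of all targets spawned during the round -- the
points that were available during game play -- which makes rounds with
different spawn draws comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import AI, HUMAN
from .engine import (
    EV_CLICK,
    EV_EXIT,
    EV_INTERCEPTION,
    EV_PATH_INTERSECTION,
    EV_ROUND_END,
    EV_SPAWN,
    GameEvent,
)

OBJECTIVE_FEATURES = [
    "human_score",
    "ai_score",
    "score_inequality",
    "steals",
    "path_intersections",
]
SUBJECTIVE_FEATURES = [f"q{i}" for i in range(1, 9)]


class MalformedLogError(Exception):
    pass


@dataclass(frozen=True)
class RoundMetrics:
    """Per-round behavioral summary.

    Scores are reported both in points and as fractions of the total
    value spawned; ``score_inequality`` (points) is the absolute
    human-AI score difference, the inequity-aversion feature.
    """

    human_points: int
    ai_points: int
    total_value_spawned: int
    human_relative_score: float
    ai_relative_score: float
    team_relative_score: float
    score_inequality: int
    steals: int
    path_intersections: int


def _round_end(log: Sequence[GameEvent]) -> GameEvent:
    for ev in reversed(log):
        if ev.type == EV_ROUND_END:
            return ev
    raise MalformedLogError("event log has no round_end event")


def relative_scores(log: Sequence[GameEvent]) -> tuple[int, int, int]:
    """(human points, AI points, total value spawned) from the log.

    Points are accumulated from interception events; the denominator from
    spawn events, cross-checked against the round_end record.
    """
    end = _round_end(log)
    pts = {HUMAN: 0, AI: 0}
    spawned = 0
    for ev in log:
        if ev.type == EV_INTERCEPTION:
            pts[ev.data["player"]] += ev.data["value"]
        elif ev.type == EV_SPAWN:
            spawned += ev.data["value"]
    if spawned != end.data["total_value_spawned"]:
        raise MalformedLogError("spawn value sum disagrees with round_end record")
    return pts[HUMAN], pts[AI], spawned


def count_steals(log: Sequence[GameEvent], definition: str = "current_marker") -> int:
    """AI interceptions of a target the human was pursuing.

    ``current_marker`` (default): the human's cross-hair was on the target
    at the interception instant.  ``first_marker``: the human was the
    first player ever to mark that target.
    """
    if definition == "current_marker":
        return sum(
            1
            for ev in log
            if ev.type == EV_INTERCEPTION
            and ev.data["player"] == AI
            and ev.data.get("other_player_marked_same")
        )
    if definition == "first_marker":
        first_marker: dict = {}
        steals = 0
        for ev in log:
            if ev.type == EV_CLICK and ev.data.get("target") != "center":
                first_marker.setdefault(ev.data["target"], ev.data["player"])
            elif ev.type == EV_INTERCEPTION and ev.data["player"] == AI:
                if first_marker.get(ev.data["target_id"]) == HUMAN:
                    steals += 1
        return steals
    raise ValueError(f"unknown steal definition {definition!r}")


def count_path_intersections(log: Sequence[GameEvent]) -> int:
    """Number of onset events of the two players' trajectory segments
    crossing (debounced: sustained crossings count once)."""
    return sum(1 for ev in log if ev.type == EV_PATH_INTERSECTION)


def round_metrics(log: Sequence[GameEvent]) -> RoundMetrics:
    """All objective metrics of one round from its event log."""
    h, a, total = relative_scores(log)
    denom = total if total > 0 else 1
    return RoundMetrics(
        human_points=h,
        ai_points=a,
        total_value_spawned=total,
        human_relative_score=h / denom,
        ai_relative_score=a / denom,
        team_relative_score=(h + a) / denom,
        score_inequality=abs(h - a),
        steals=count_steals(log),
        path_intersections=count_path_intersections(log),
    )


def objective_features(m: RoundMetrics) -> dict:
    """The objective feature vector entering the preference model.

    Scores are relative (fraction of available points), and the
    inequality feature is on the same relative scale.
    """
    return {
        "human_score": m.human_relative_score,
        "ai_score": m.ai_relative_score,
        "score_inequality": abs(m.human_relative_score - m.ai_relative_score),
        "steals": m.steals,
        "path_intersections": m.path_intersections,
    }


def build_feature_table(
    round_metric_map: dict,
    ratings: Optional[pd.DataFrame],
    pairings: pd.DataFrame,
) -> pd.DataFrame:
    """Per-comparison feature table for the choice model.

    ``round_metric_map`` maps (participant_id, density, agent) ->
    RoundMetrics; ``ratings`` holds one row per (participant_id, block,
    density, agent) with columns q1..q8 (may be None to build an
    objective-only table); ``pairings`` has one row per comparison with
    participant_id, block, density, agent_first, agent_second and
    optionally choice.  Output columns follow the documented schema:
    identifiers, then first_<feature>, second_<feature> for the objective
    family and, when ratings are given, the subjective family.
    """
    if ratings is not None:
        rkey = ratings.set_index(["participant_id", "block", "agent"])
    rows = []
    for rec in pairings.to_dict("records"):
        pid, block, density = rec["participant_id"], rec["block"], rec["density"]
        row = {
            "participant_id": pid,
            "block": block,
            "density": density,
            "agent_first": rec["agent_first"],
            "agent_second": rec["agent_second"],
        }
        if "choice" in rec:
            row["choice"] = rec["choice"]
        for pos, agent in (("first", rec["agent_first"]), ("second", rec["agent_second"])):
            key = (pid, density, agent)
            if key not in round_metric_map:
                raise KeyError(f"missing round metrics for {key}")
            feats = objective_features(round_metric_map[key])
            if ratings is not None:
                try:
                    rrow = rkey.loc[(pid, block, agent)]
                except KeyError as exc:
                    raise KeyError(f"missing ratings for {(pid, block, agent)}") from exc
                for q in SUBJECTIVE_FEATURES:
                    feats[q] = rrow[q]
            for name, val in feats.items():
                row[f"{pos}_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
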