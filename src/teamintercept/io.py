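"""Readers and writers: line-delimited event logs and delimited tables.

Event logs are one JSON record per line -- a header with the full game
config and provenance first, then one record per event with fields
``t``, ``type`` and the event payload.  JSON float serialization is
shortest-round-trip, so write -> read -> write reproduces files
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import GameConfig
from .engine import GameEvent

OSF_URL = "https://osf.io/ybweq/"


def load_config(path, **overrides) -> GameConfig:
    """GameConfig from a YAML file; unknown keys are rejected.

    Keyword overrides (e.g. seed from the command line) take precedence
    over file values.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "target_speed_range" in data:
        data["target_speed_range"] = tuple(data["target_speed_range"])
    data.update(overrides)
    try:
        return GameConfig(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: unknown config key ({exc})") from None


def config_to_dict(config: GameConfig) -> dict:
    d = dataclasses.asdict(config)
    d["target_speed_range"] = list(d["target_speed_range"])
    return d


def config_hash(config: GameConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_event_log(path, events: Sequence[GameEvent], config: GameConfig) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "type": "header",
            "config": config_to_dict(config),
            "config_hash": config_hash(config),
            "version": __version__,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for ev in events:
            rec = {"t": ev.t, "type": ev.type}
            rec.update(ev.data)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_event_log(path) -> tuple[GameConfig, list[GameEvent]]:
    path = Path(path)
    events: list[GameEvent] = []
    config = None
    with path.open() as fh:
        for line in fh:
            rec = json.loads(line)
            if rec.get("type") == "header":
                cfg = dict(rec["config"])
                cfg["target_speed_range"] = tuple(cfg["target_speed_range"])
                config = GameConfig(**cfg)
                continue
            t = rec.pop("t")
            typ = rec.pop("type")
            data = rec
            for key in ("position", "velocity"):
                if key in data:
                    data[key] = list(data[key])
            events.append(GameEvent(t=t, type=typ, data=data))
    if config is None:
        raise ValueError(f"{path}: missing header record")
    return config, events


def write_table(path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Deposited-study loader (best effort; never downloads)
# ---------------------------------------------------------------------------

_OSF_CHOICE_COLUMNS = {
    "participant_id": ["participant_id", "participant", "subject", "subject_id", "pid"],
    "block": ["block", "block_id"],
    "density": ["density", "target_density"],
    "agent_first": ["agent_first", "first_agent", "agent_a", "agent1"],
    "agent_second": ["agent_second", "second_agent", "agent_b", "agent2"],
    "choice": ["choice", "chosen", "preference", "selected"],
}


def load_osf_tables(path) -> pd.DataFrame:
    """Load a locally downloaded copy of the study's deposited choice data.

    The deposit must be fetched manually from the project's OSF page
    (%s); this loader never downloads anything.  It maps common column
    spellings onto the package's choice schema and reports exactly which
    required columns could not be found.
    """ % OSF_URL
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. Download the behavioral dataset manually from "
            f"{OSF_URL} and point --osf-path at the choice table (CSV)."
        )
    table = pd.read_csv(path)
    lower = {c.lower(): c for c in table.columns}
    out = {}
    missing = []
    for canon, aliases in _OSF_CHOICE_COLUMNS.items():
        for alias in aliases:
            if alias in lower:
                out[canon] = table[lower[alias]]
                break
        else:
            missing.append(f"{canon} (any of: {', '.join(aliases)})")
    if missing:
        raise KeyError(
            "deposited table is missing required columns -- "
            + "; ".join(missing)
            + f". Check the deposit at {OSF_URL} for renamed columns."
        )
    result = pd.DataFrame(out)
    if result["choice"].dtype == object:
        vals = set(result["choice"].astype(str).str.lower())
        if not vals <= {"first", "second"}:
            # chosen-agent labels: translate to first/second
            result["choice"] = [
                "first" if str(c) == str(a) else "second"
                for c, a in zip(result["choice"], result["agent_first"])
            ]
    return result
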