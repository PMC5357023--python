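"""Configuration files, recorded-experiment replay, and report serialization.

Configs are JSON or YAML documents with a ``dimensions`` list (one entry per
dithered attribute) and a ``run`` block (trial count, seed, shock schedule,
scenario).  Recorded experiments — per-trial tables of (trial, shown
attributes, rating) — load through an explicit column-mapping layer, since
field names of deposited datasets vary; replay re-runs the controller
deterministically against the recorded ratings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import DimensionConfig, LockInController, WarmupError
from .simulate import (
    ConfigError,
    NoiseModel,
    ResponseSurface,
    Scenario,
    ShockEvent,
    ShockSchedule,
)
from .trajectory import TrajectoryLog, TrialRecord

log = logging.getLogger("lifopt")

__all__ = [
    "ReplaySpec",
    "SchemaError",
    "load_config",
    "default_config",
    "config_hash",
    "parse_shock",
    "load_records",
    "replay",
    "write_report",
]


class SchemaError(ValueError):
    """A records table does not expose the mapped columns."""


# Dither parameters of the two-attribute rating study this package ships as
# its default configuration: two simultaneous lock-ins on a [1, 100] grid.
DEFAULT_CONFIG: dict = {
    "dimensions": [
        {"omega": 2.63, "delta": 8.0, "gamma": 0.0006, "n_window": 150,
         "x_init": 20.0, "lo": 1.0, "hi": 100.0, "direction": "maximize"},
        {"omega": 2.51, "delta": 8.0, "gamma": 0.0006, "n_window": 150,
         "x_init": 20.0, "lo": 1.0, "hi": 100.0, "direction": "maximize"},
    ],
    "controller": {"raw_sign": False, "baseline": "current", "quantize": False},
    "run": {
        "n_trials": 3600,
        "seed": 0,
        "shocks": [],
        "scenario": {
            "surface": {"a1": -0.01, "a2": -0.02, "x1m": 55.0, "x2m": 60.0,
                        "y0": 70.0, "cross": 0.0},
            "noise": {"kind": "gaussian", "sd": 25.0, "clip": [1.0, 100.0]},
            "round_response": False,
        },
    },
}


def default_config() -> dict:
    """A deep copy of the packaged default configuration."""
    return json.loads(json.dumps(DEFAULT_CONFIG))


def load_config(path) -> dict:
    """Read a JSON or YAML config; missing blocks fall back to the default."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} is not a mapping")
    merged = default_config()
    for key in ("dimensions", "controller", "run"):
        if key in doc:
            if key == "dimensions":
                merged[key] = doc[key]
            else:
                merged[key] = {**merged[key], **doc[key]}
    return merged


def dimension_configs(config: dict) -> list[DimensionConfig]:
    return [DimensionConfig(**d) for d in config["dimensions"]]


def controller_from_config(config: dict) -> LockInController:
    return LockInController(dimension_configs(config), **config.get("controller", {}))


def scenario_from_config(config: dict) -> Scenario:
    run = config["run"]
    sc = run.get("scenario", {})
    surface = ResponseSurface(**sc.get("surface", {}))
    noise_spec = dict(sc.get("noise", {}))
    clip = noise_spec.pop("clip", (1.0, 100.0))
    noise = NoiseModel(
        **noise_spec, clip=None if clip is None else tuple(clip),
        seed=int(run.get("seed", 0)),
    )
    shocks = ShockSchedule(tuple(
        ShockEvent(trial=int(s["trial"]), dim=int(s["dim"]), value=float(s["value"]))
        for s in run.get("shocks", [])
    ))
    return Scenario(
        surface=surface,
        noise=noise,
        shocks=shocks,
        n_trials=int(run["n_trials"]),
        round_response=bool(sc.get("round_response", False)),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration (order-insensitive)."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def parse_shock(text: str) -> ShockEvent:
    """Parse a ``DIM:TRIAL:VALUE`` shock flag, e.g. ``1:3637:90``."""
    parts = text.split(":")
    if len(parts) != 3:
        raise ConfigError(f"shock must be DIM:TRIAL:VALUE, got {text!r}")
    return ShockEvent(trial=int(parts[1]), dim=int(parts[0]), value=float(parts[2]))


# ---------------------------------------------------------------------------
# Recorded experiments


@dataclass(frozen=True)
class ReplaySpec:
    """Where a recorded rating stream lives and how to read it.

    ``trial_col`` may be None, in which case trials are numbered 1..N in row
    order.  ``shown_cols`` optionally names the displayed-attribute columns
    (carried through to the output; the replayed proposals are recomputed).
    """

    path: str
    response_col: str = "y"
    trial_col: Optional[str] = "trial"
    shown_cols: tuple = ()
    delimiter: Optional[str] = None


def _sniff_delimiter(path) -> str:
    head = Path(path).read_text().splitlines()[:5]
    sample = "\n".join(head)
    counts = {d: sample.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get)


def load_records(spec: ReplaySpec) -> list[TrialRecord]:
    """Load, validate and sort a recorded rating stream.

    Rows with a missing response are dropped (count logged); records are
    returned in trial order with a gapless 1..N numbering when the file has
    no trial column.
    """
    path = Path(spec.path)
    delim = spec.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    needed = [spec.response_col] + list(spec.shown_cols)
    if spec.trial_col is not None:
        needed.append(spec.trial_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks mapped column(s) {missing}; has {list(df.columns)}")
    n_raw = len(df)
    df = df.dropna(subset=[spec.response_col])
    dropped = n_raw - len(df)
    if dropped:
        log.info("dropped %d row(s) with missing response", dropped)
    if df.empty:
        raise ValueError(f"{path}: every row had a missing response")
    if spec.trial_col is not None:
        df = df.sort_values(spec.trial_col, kind="stable")
        trials = df[spec.trial_col].astype(int).to_numpy()
    else:
        trials = np.arange(1, len(df) + 1)
    log.info("loaded %d record(s) from %s", len(df), path)
    records = []
    for t, (_, row) in zip(trials, df.iterrows()):
        shown = tuple(float(row[c]) for c in spec.shown_cols)
        records.append(TrialRecord(trial=int(t), shown=shown,
                                   y=float(row[spec.response_col]), centers=()))
    return records


def replay(
    records: Sequence[TrialRecord],
    config: dict,
    shocks: ShockSchedule | None = None,
) -> TrajectoryLog:
    """Deterministically re-run the controller against recorded responses.

    Warm-up and updates proceed exactly as in a live run, but each trial's
    response is taken from the record stream instead of a simulator, and
    configured shocks are re-applied at their trials.  Proposal/center
    reconstruction uses the record's trial index as the dither phase.
    """
    records = sorted(records, key=lambda r: r.trial)
    configs = dimension_configs(config)
    max_n = max(c.n_window for c in configs)
    if len(records) < max_n:
        raise WarmupError(f"replay needs at least {max_n} records, got {len(records)}")
    trials = [r.trial for r in records]
    if any(b - a != 1 for a, b in zip(trials, trials[1:])):
        raise ValueError("record trial indices are not a gapless sequence")
    ctl = LockInController(
        dimension_configs(config),
        **config.get("controller", {}),
        first_trial=trials[0],
    )
    shocks = shocks or ShockSchedule()
    out = TrajectoryLog(k=ctl.k)
    for rec in records:
        for e in shocks.at(rec.trial):
            ctl.force_center(e.dim - 1, e.value)
        xs = ctl.propose(rec.trial)
        centers_used = [st.center_history[-1] for st in ctl.states]
        ctl.observe(rec.trial, rec.y)
        ylocks = [None if lk is None else lk.y_lock for lk in ctl.last_locks]
        out.append(rec.trial, xs, rec.y, centers_used, ylocks)
    return out


def write_report(report: dict, path, config: dict | None = None) -> None:
    """Serialize a report dict as JSON, stamping the config hash."""
    payload = dict(report)
    if config is not None:
        payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
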