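"""Event-log CSV read/write and run-configuration loading.

The event log is a single flat RFC-4180 CSV per run with a fixed header
``time,actor,event,payload``: ISO-8601 timestamps with milliseconds in
simulated wall-clock time (so light-phase analysis is self-contained), a
closed event vocabulary, and the payload as ``key=value`` pairs joined with
semicolons.  The reader is strict: unknown event kinds, malformed rows and
non-monotone timestamps are rejected with the offending row number.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path
from typing import Optional

from .agents import AgentParams, preset
from .engine import EVENT_VOCAB, EventLog, LightCycle, SimConfig
from .protocol import MINUTE, PhaseId, phase_config

HEADER = ["time", "actor", "event", "payload"]


class LogValidationError(ValueError):
    pass


def _iso(origin_date: str, t_ms: int) -> str:
    base = dt.datetime.fromisoformat(origin_date)
    stamp = base + dt.timedelta(milliseconds=t_ms)
    return stamp.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3]


def _from_iso(origin_date: str, stamp: str) -> int:
    base = dt.datetime.fromisoformat(origin_date)
    parsed = dt.datetime.fromisoformat(stamp)
    delta = parsed - base
    return round(delta.total_seconds() * 1000)


def write_event_log(log: EventLog, dest) -> None:
    """Write a log as CSV; the origin date is recoverable from the first
    row's date."""
    dest = Path(dest)
    with dest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(HEADER)
        for row in log.rows:
            payload = ";".join(f"{k}={v}" for k, v in row.payload)
            w.writerow([_iso(log.origin_date, row.t), row.actor, row.event,
                        payload])


def read_event_log(src, origin_date: Optional[str] = None) -> EventLog:
    """Strictly parse a log CSV back into an :class:`EventLog`.

    Round-trips exactly: ``read_event_log(write_event_log(x)) == x`` for
    any log the simulator produces.
    """
    src = Path(src)
    with src.open(newline="") as fh:
        rdr = csv.reader(fh)
        try:
            header = next(rdr)
        except StopIteration:
            raise LogValidationError("empty log file") from None
        if header != HEADER:
            raise LogValidationError(f"bad header {header!r}")
        rows = list(rdr)
    if origin_date is None:
        if not rows:
            raise LogValidationError("log has no rows to infer a date from")
        origin_date = rows[0][0][:10]
    log = EventLog(origin_date=origin_date)
    for i, row in enumerate(rows, start=2):
        if len(row) != 4:
            raise LogValidationError(f"row {i}: expected 4 fields")
        stamp, actor, event, payload = row
        if event not in EVENT_VOCAB:
            raise LogValidationError(f"row {i}: unknown event kind {event!r}")
        try:
            t = _from_iso(origin_date, stamp)
        except ValueError:
            raise LogValidationError(
                f"row {i}: bad timestamp {stamp!r}") from None
        kv = {}
        if payload:
            for pair in payload.split(";"):
                if "=" not in pair:
                    raise LogValidationError(
                        f"row {i}: malformed payload item {pair!r}")
                k, _, v = pair.partition("=")
                kv[k] = v
        try:
            log.append(t, actor, event, **kv)
        except ValueError as exc:
            raise LogValidationError(f"row {i}: {exc}") from None
    return log


def validate_log(log: EventLog) -> list[str]:
    """Well-formedness checks beyond parsing; returns a list of problems
    (empty when the log is clean)."""
    problems: list[str] = []
    open_sessions: dict[str, int] = {}
    prev_t = None
    for i, r in enumerate(log.rows):
        if prev_t is not None and r.t < prev_t:
            problems.append(f"row {i}: timestamp decreases")
        prev_t = r.t
        if r.event == "session_start":
            if r.actor in open_sessions:
                problems.append(f"row {i}: nested session for {r.actor}")
            open_sessions[r.actor] = i
        elif r.event == "session_end":
            if r.actor not in open_sessions:
                problems.append(f"row {i}: session_end without start "
                                f"for {r.actor}")
            open_sessions.pop(r.actor, None)
    for actor, i in open_sessions.items():
        problems.append(f"row {i}: session_start for {actor} never ends")
    return problems


# -- run configuration -------------------------------------------------------

_SIM_KEYS = {"animals", "seed", "start_date", "start_clock", "duration_h",
             "curriculum", "late_learner_window_h", "count_corrections"}
_AGENT_KEYS = {f.name for f in
               __import__("dataclasses").fields(AgentParams)} | {"preset"}
_PHASE_KEYS = {"max_trials", "max_session_duration", "iti", "passive_timer",
               "reward_active", "reward_passive", "timeout_on_error",
               "sample_choice_delay", "sample_reward_prob",
               "intersession_interval", "max_sessions_per_24h",
               "separation_class"}


class RunConfig:
    def __init__(self, sim: SimConfig,
                 agent_params: dict[str, AgentParams],
                 provenance: dict) -> None:
        self.sim = sim
        self.agent_params = agent_params
        self.provenance = provenance


def load_config(path: Optional[str] = None, text: Optional[str] = None
                ) -> RunConfig:
    """Load a TOML run configuration; unspecified keys fall back to the
    protocol defaults.  Sections: ``[sim]``, ``[phase.<NAME>]``,
    ``[agents.default]`` / ``[agents.<ANIMAL>]``.

    An empty file yields the full default configuration.  Every effective
    default is echoed into ``provenance`` so a run records exactly what it
    used; the simulate command writes it as a sidecar JSON.
    """
    import tomllib

    if text is not None:
        data = tomllib.loads(text)
    elif path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        data = {}

    known_top = {"sim", "phase", "agents"}
    for key in data:
        if key not in known_top:
            raise ValueError(f"unknown configuration section {key!r}")

    sim_raw = data.get("sim", {})
    for key in sim_raw:
        if key not in _SIM_KEYS:
            raise ValueError(f"unknown key 'sim.{key}'")
    sim_kwargs: dict = {}
    if "animals" in sim_raw:
        sim_kwargs["animals"] = tuple(sim_raw["animals"])
    if "seed" in sim_raw:
        sim_kwargs["seed"] = int(sim_raw["seed"])
    if "start_date" in sim_raw:
        sim_kwargs["start_date"] = str(sim_raw["start_date"])
    if "start_clock" in sim_raw:
        hh, _, mm = str(sim_raw["start_clock"]).partition(":")
        sim_kwargs["start_clock_min"] = int(hh) * 60 + int(mm or 0)
    if "duration_h" in sim_raw:
        sim_kwargs["duration"] = int(float(sim_raw["duration_h"]) * 60) \
            * MINUTE
    if "curriculum" in sim_raw:
        sim_kwargs["curriculum"] = tuple(
            PhaseId[p] for p in sim_raw["curriculum"])
    if "late_learner_window_h" in sim_raw:
        sim_kwargs["late_learner_window"] = int(
            float(sim_raw["late_learner_window_h"]) * 60) * MINUTE
    if "count_corrections" in sim_raw:
        sim_kwargs["count_corrections"] = bool(sim_raw["count_corrections"])

    phase_overrides: dict[str, dict] = {}
    for name, section in data.get("phase", {}).items():
        try:
            PhaseId[name]
        except KeyError:
            raise ValueError(f"unknown phase section 'phase.{name}'") \
                from None
        for key in section:
            if key not in _PHASE_KEYS:
                raise ValueError(f"unknown key 'phase.{name}.{key}'")
        phase_overrides[name] = dict(section)
    if phase_overrides:
        sim_kwargs["phase_overrides"] = phase_overrides

    sim = SimConfig(**sim_kwargs)

    agents_raw = data.get("agents", {})
    default_raw = agents_raw.get("default", {"preset": "calibrated"})
    agent_params: dict[str, AgentParams] = {}
    for animal in sim.animals:
        raw = dict(default_raw)
        raw.update(agents_raw.get(animal, {}))
        for key in raw:
            if key not in _AGENT_KEYS:
                raise ValueError(f"unknown key 'agents.{animal}.{key}'")
        name = raw.pop("preset", "calibrated")
        for k in ("response_latency", "magazine_latency", "exit_latency"):
            if k in raw:
                raw[k] = tuple(float(v) for v in raw[k])
        agent_params[animal] = preset(name, **raw)

    provenance = {
        "sim": {
            "animals": list(sim.animals), "seed": sim.seed,
            "start_date": sim.start_date,
            "start_clock_min": sim.start_clock_min,
            "duration_ms": sim.duration,
            "curriculum": [p.name for p in sim.curriculum],
            "late_learner_window_ms": sim.late_learner_window,
            "count_corrections": sim.count_corrections,
        },
        "phases": {
            p.name: _phase_dict(sim.config_for(p)) for p in sim.curriculum},
        "agents": {a: _agent_dict(agent_params[a]) for a in sim.animals},
    }
    return RunConfig(sim=sim, agent_params=agent_params,
                     provenance=provenance)


def _phase_dict(cfg) -> dict:
    import dataclasses
    d = dataclasses.asdict(cfg)
    d["phase"] = cfg.phase.name
    return d


def _agent_dict(params: AgentParams) -> dict:
    import dataclasses
    return dataclasses.asdict(params)


def write_provenance(cfg: RunConfig, dest) -> None:
    Path(dest).write_text(json.dumps(cfg.provenance, indent=2,
                                     default=str) + "\n")
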