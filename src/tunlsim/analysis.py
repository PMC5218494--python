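"""Analysis of event logs: per-session measured parameters, blocks-of-five
summaries, visit statistics, and psychometric parameter recovery.

Everything here consumes the event-log stream only (plus the light cycle),
so pre-recorded logs can be analysed without the simulator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import EventLog, LightCycle, LogRow, light_phase
from .protocol import DAY, SECOND, PhaseId, SessionRecord
from .sorter import detect_visits

# re-export the statistical battery under the analysis surface
from .stats import (  # noqa: F401
    TestResult, bonferroni, friedman_test, mann_whitney_u, quartile_overlap,
    wilcoxon_signed_rank,
)


class LogFormatError(ValueError):
    """Raised with row-level diagnostics when a log cannot be analysed."""


def _phase_from_name(name: str) -> PhaseId:
    try:
        return PhaseId[name]
    except KeyError:
        raise LogFormatError(f"unknown phase name {name!r}") from None


def session_metrics(log: EventLog,
                    count_corrections: bool = False) -> pd.DataFrame:
    """One row per session with every measured training parameter:
    completed trials, phase-appropriate percent correct, incorrect pokes,
    correction trials, mean choice/reward latencies, exit latency and
    duration.

    Latency definitions follow the recorded protocol: the choice latency is
    the interval from exiting the magazine after initiating the choice
    phase to the correct screen response (for pre-TUNL phases, from
    stimulus onset to the rewarded response); the reward latency runs from
    the correct response to the collecting magazine poke.
    """
    rows = log.rows
    # homeward R3 lookup for exit latencies
    r3_times: dict[str, list[int]] = {}
    for r in rows:
        if r.event == "reader_detect" and r.get("reader") == "R3":
            r3_times.setdefault(r.actor, []).append(r.t)

    open_sessions: dict[str, dict] = {}
    out: list[dict] = []
    for i, r in enumerate(rows):
        if r.event == "session_start":
            if r.actor in open_sessions:
                raise LogFormatError(
                    f"row {i}: session_start for {r.actor} while a session "
                    "is already open")
            open_sessions[r.actor] = {
                "animal": r.actor,
                "phase": _phase_from_name(r.get("phase", "")),
                "session_index": int(r.get("session_index", 0) or 0),
                "start": r.t,
                "active": 0, "passive": 0, "correct": 0, "incorrect": 0,
                "correction_trials": 0, "corr_correct": 0,
                "corr_incorrect": 0, "incorrect_pokes": 0,
                "choice_lats": [], "reward_lats": [],
                "cur_correction": False, "choice_onset": None,
                "stim_onset": None, "response_t": None,
            }
            continue
        if r.event == "session_end":
            s = open_sessions.pop(r.actor, None)
            if s is None:
                raise LogFormatError(
                    f"row {i}: session_end for {r.actor} without a start")
            s["end"] = r.t
            s["trials_logged"] = int(r.get("trials", -1))
            s["terminated_by"] = r.get("terminated_by", "")
            out.append(_finalize_session(s, r3_times, count_corrections))
            continue
        s = open_sessions.get(r.actor)
        if s is None:
            # habituation runs as one group session owned by SYSTEM; pokes
            # are attributed to whichever animal made them
            s = open_sessions.get("SYSTEM")
        if s is None:
            continue
        _accumulate(s, r)
    if open_sessions:
        raise LogFormatError(
            f"unmatched session_start for {sorted(open_sessions)}")
    df = pd.DataFrame(out)
    if not df.empty:
        df = df.sort_values(["animal", "start"]).reset_index(drop=True)
    return df


def _accumulate(s: dict, r: LogRow) -> None:
    if r.event == "stimulus_on":
        kind = r.get("kind")
        if kind == "choice":
            s["cur_correction"] = r.get("correction") == "1"
            s["choice_onset"] = r.t
        elif kind in ("all", "single", "sample"):
            s["stim_onset"] = r.t
    elif r.event == "screen_poke":
        outcome = r.get("outcome")
        if outcome == "inert":
            s["incorrect_pokes"] += 1
        elif outcome == "active":
            s["active"] += 1
            if s["stim_onset"] is not None:
                s["choice_lats"].append(r.t - s["stim_onset"])
            s["response_t"] = r.t
        elif outcome == "correct":
            if s["cur_correction"]:
                s["correction_trials"] += 1
                s["corr_correct"] += 1
                s["cur_correction"] = False
            else:
                s["correct"] += 1
            onset = s["choice_onset"] if s["choice_onset"] is not None \
                else s["stim_onset"]
            if onset is not None:
                s["choice_lats"].append(r.t - onset)
            s["choice_onset"] = None
            s["stim_onset"] = None
            s["response_t"] = r.t
        elif outcome == "incorrect":
            if s["cur_correction"]:
                s["correction_trials"] += 1
                s["corr_incorrect"] += 1
            else:
                s["incorrect"] += 1
            s["choice_onset"] = None
            s["stim_onset"] = None
    elif r.event == "reward":
        if r.get("kind") == "passive":
            s["passive"] += 1
    elif r.event == "magazine_poke":
        if r.get("role") == "collect" and s["response_t"] is not None:
            s["reward_lats"].append(r.t - s["response_t"])
            s["response_t"] = None


def _finalize_session(s: dict, r3_times: dict[str, list[int]],
                      count_corrections: bool) -> dict:
    phase: PhaseId = s["phase"]
    active, passive = s["active"], s["passive"]
    correct, incorrect = s["correct"], s["incorrect"]
    corrections = s["correction_trials"]
    if phase in (PhaseId.T1, PhaseId.T2):
        trials = active + passive
        pct = 100.0 * active / trials if trials else np.nan
    elif phase in (PhaseId.T3, PhaseId.T4, PhaseId.T5):
        trials = active + correct
        pct = 100.0 * trials / 50.0
    else:
        trials = correct + incorrect + corrections
        c, ic = correct, incorrect
        if count_corrections:
            c += s["corr_correct"]
            ic += s["corr_incorrect"]
        pct = 100.0 * c / (c + ic) if (c + ic) else np.nan
    exit_lat = np.nan
    nxt = [t for t in r3_times.get(s["animal"], []) if t >= s["end"]]
    if nxt:
        exit_lat = (nxt[0] - s["end"]) / SECOND
    return {
        "animal": s["animal"], "phase": phase.name,
        "session_index": s["session_index"], "start": s["start"],
        "end": s["end"], "duration_s": (s["end"] - s["start"]) / SECOND,
        "trials": trials, "active": active, "passive": passive,
        "correct": correct, "incorrect": incorrect,
        "correction_trials": corrections,
        "incorrect_pokes": s["incorrect_pokes"], "pct": pct,
        "choice_latency_mean_s":
            float(np.mean(s["choice_lats"])) / SECOND
            if s["choice_lats"] else np.nan,
        "reward_latency_mean_s":
            float(np.mean(s["reward_lats"])) / SECOND
            if s["reward_lats"] else np.nan,
        "exit_latency_s": exit_lat,
        "terminated_by": s["terminated_by"],
    }


def block_summary(metrics: pd.DataFrame, phase: str = "TUNL_ACQ",
                  block_size: int = 5) -> pd.DataFrame:
    """Blocks-of-five session summaries per animal: mean percent correct and
    mean correction trials, ordered by session."""
    df = metrics[metrics["phase"] == phase].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["animal", "block", "mean_pct", "mean_correction_trials"])
    df = df.sort_values(["animal", "start"])
    df["block"] = df.groupby("animal").cumcount() // block_size + 1
    out = df.groupby(["animal", "block"]).agg(
        mean_pct=("pct", "mean"),
        mean_correction_trials=("correction_trials", "mean"),
        n_sessions=("pct", "size")).reset_index()
    return out


def visit_stats(log: EventLog,
                cycle: LightCycle = LightCycle()) -> pd.DataFrame:
    """Per-animal chamber-visit statistics from the reader stream: visit
    count per 24 h, dark-phase fraction, and mean visit duration in the
    dark and light phases."""
    visits = detect_visits(log.reader_events())
    if not visits:
        return pd.DataFrame(columns=[
            "animal", "visits", "visits_per_24h", "dark_fraction",
            "mean_duration_dark_s", "mean_duration_light_s"])
    span = max(1, log.rows[-1].t - log.rows[0].t)
    rows = []
    by_animal: dict[str, list] = {}
    for v in visits:
        by_animal.setdefault(v.animal, []).append(v)
    for animal in sorted(by_animal):
        vs = by_animal[animal]
        dark = [v for v in vs if light_phase(v.enter_time, cycle) == "dark"]
        light = [v for v in vs if light_phase(v.enter_time, cycle) == "light"]
        rows.append({
            "animal": animal,
            "visits": len(vs),
            "visits_per_24h": len(vs) * DAY / span,
            "dark_fraction": len(dark) / len(vs),
            "mean_duration_dark_s":
                float(np.mean([v.duration for v in dark])) / SECOND
                if dark else np.nan,
            "mean_duration_light_s":
                float(np.mean([v.duration for v in light])) / SECOND
                if light else np.nan,
        })
    return pd.DataFrame(rows)


# -- psychometric parameter recovery ----------------------------------------


@dataclass(frozen=True)
class PsychometricFit:
    slope: float            # accuracy drop from separation 3 to 0
    delay_penalty_per_s: float
    intercept: float
    slope_se: float
    delay_penalty_se: float
    n_trials: int


def probe_trials_frame(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """Per-trial choice outcomes from probe session records (first
    presentations only; correction trials are excluded)."""
    rows = []
    for rec in records:
        for t in rec.trials:
            if t.kind not in ("correct", "incorrect") or t.spec is None:
                continue
            rows.append({
                "animal": t.animal,
                "separation": t.spec.separation,
                "delay_s": t.spec.delay / SECOND,
                "correct": 1 if t.kind == "correct" else 0,
            })
    return pd.DataFrame(rows)


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Recover the agents' psychometric parameters from probe choices.

    The generating model is linear in probability:
    P(correct) = a - slope * (3 - separation)/3 - penalty * delay_s,
    so a weighted least-squares fit on per-condition accuracies returns
    the slope and delay penalty directly (with their standard errors).
    """
    import statsmodels.api as sm

    if trials.empty:
        raise ValueError("no scored probe trials to fit")
    g = trials.groupby(["separation", "delay_s"]).agg(
        acc=("correct", "mean"), n=("correct", "size")).reset_index()
    x1 = (3.0 - g["separation"]) / 3.0
    x2 = g["delay_s"]
    X = sm.add_constant(np.column_stack([x1, x2]))
    model = sm.WLS(np.asarray(g["acc"]), X, weights=np.asarray(g["n"]))
    res = model.fit()
    return PsychometricFit(
        slope=float(-res.params[1]),
        delay_penalty_per_s=float(-res.params[2]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        delay_penalty_se=float(res.bse[2]),
        n_trials=int(trials.shape[0]))
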