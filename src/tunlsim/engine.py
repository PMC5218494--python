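"""Discrete-event simulation engine.

Couples simulated agents, the RFID sorter and the per-phase trial automata
on a single event queue with a global clock, a 12/12 h light cycle and an
append-only event log.  Two entry points:

* :func:`run_session` -- one chamber session for one agent (no sorter),
  used for exact cap checks and for desk-scale probe batteries;
* :func:`run_simulation` -- the full cohort: habituation with the open
  sorter, gated single-occupancy sessions, curriculum progression through
  acquisition criteria, inter-session intervals, per-24 h caps and
  late-learner access windows.

The simulation clock is integer milliseconds of wall time measured from
midnight of the start date, so light-phase analysis is self-contained.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import trialfsm as fsm
from .agents import AgentParams, AgentState, Stim, _latency, agent_act, \
    agent_learn, decide_visit, preset
from .des import Kernel, Signal, spawn
from .protocol import (
    DAY, DEFAULT_GRID, HOUR, MINUTE, SECOND, PhaseConfig, PhaseId,
    SessionRecord, TrialRecord, WindowGrid, criterion_met, phase_config,
)
from .sorter import (
    ChamberEntered, HoldExpired, HomeArrived, ReaderEvent, SessionEnded,
    SorterState, access_allowed, earliest_allowed, sorter_step, AccessPolicy,
)

# -- light cycle -------------------------------------------------------------


@dataclass(frozen=True)
class LightCycle:
    """12-12 h dark/light cycle; default dark phase 14:00-02:00 (inverted
    cycle, so the animals' active phase covers the afternoon and evening)."""

    dark_onset_min: int = 14 * 60
    dark_duration_min: int = 12 * 60


def light_phase(t: int, cycle: LightCycle = LightCycle()) -> str:
    """'dark' or 'light' at wall-clock time ``t`` (ms from midnight of the
    start date)."""
    minute_of_day = (t // MINUTE) % (24 * 60)
    return "dark" if (minute_of_day - cycle.dark_onset_min) % (24 * 60) \
        < cycle.dark_duration_min else "light"


# -- event log ---------------------------------------------------------------

EVENT_VOCAB = frozenset({
    "reader_detect", "gate_open", "gate_close", "session_start",
    "session_end", "screen_poke", "magazine_poke", "stimulus_on",
    "stimulus_off", "reward", "tone_high", "tone_low", "houselight_on",
    "houselight_off", "phase_transition", "sort_abort",
})


@dataclass(frozen=True)
class LogRow:
    t: int                    # ms from midnight of the origin date
    actor: str                # animal id or "SYSTEM"
    event: str
    payload: tuple[tuple[str, str], ...] = ()

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        for k, v in self.payload:
            if k == key:
                return v
        return default


class EventLog:
    """Append-only, time-ordered stream of chamber/sorter events."""

    def __init__(self, origin_date: str = "2024-01-01") -> None:
        self.origin_date = origin_date
        self.rows: list[LogRow] = []

    def append(self, t: int, actor: str, event: str, **payload) -> None:
        if event not in EVENT_VOCAB:
            raise ValueError(f"unknown event kind {event!r}")
        if self.rows and t < self.rows[-1].t:
            raise ValueError("event log timestamps must be non-decreasing")
        items = tuple(sorted((str(k), str(v)) for k, v in payload.items()))
        self.rows.append(LogRow(t=int(t), actor=str(actor), event=event,
                                payload=items))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and \
            self.origin_date == other.origin_date and self.rows == other.rows

    def reader_events(self) -> list[ReaderEvent]:
        return [ReaderEvent(reader=r.get("reader"), animal=r.actor,
                            timestamp=r.t)
                for r in self.rows if r.event == "reader_detect"]


# -- configuration -----------------------------------------------------------


def default_cohort(n: int = 6) -> tuple[str, ...]:
    return tuple(f"R{i}" for i in range(1, n + 1))


@dataclass(frozen=True)
class SimConfig:
    """Run configuration.  The default cohort is a single experimental group
    of six animals starting at 15:00 on the origin date."""

    animals: tuple[str, ...] = default_cohort()
    seed: int = 0
    start_date: str = "2024-01-01"
    start_clock_min: int = 15 * 60
    curriculum: tuple[PhaseId, ...] = (
        PhaseId.T1, PhaseId.T2, PhaseId.T3, PhaseId.T4, PhaseId.T5,
        PhaseId.T6, PhaseId.TUNL_ACQ)
    phase_overrides: dict = field(default_factory=dict)
    cycle: LightCycle = LightCycle()
    duration: int = 14 * DAY
    late_learner_window: int = 4 * HOUR
    count_corrections: bool = False
    grid: WindowGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if not self.animals:
            raise ValueError("cohort must be non-empty")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def start_ms(self) -> int:
        return self.start_clock_min * MINUTE

    def config_for(self, phase: PhaseId) -> PhaseConfig:
        overrides = self.phase_overrides.get(phase.name, {})
        return phase_config(phase, **overrides)


# -- single-session runner ---------------------------------------------------

_ACTIONABLE = {
    fsm.AWAIT_INITIATION: "magazine",
    fsm.AWAIT_CHOICE_INIT: "magazine",
    fsm.AWAIT_COLLECTION: "collect",
    fsm.AWAIT_RESPONSE: "response",
    fsm.SAMPLE: "response",
    fsm.CHOICE: "choice",
}


class SessionRunner:
    """Drives one chamber session: the phase automaton against one agent.

    ``gen()`` is a generator yielding integer delays so the session can run
    standalone (exhaust it) or be interleaved on the simulation kernel.
    """

    def __init__(self, cfg: PhaseConfig, agent: AgentState, log: EventLog,
                 start: int, grid: WindowGrid = DEFAULT_GRID,
                 session_index: int = 1) -> None:
        self.cfg = cfg
        self.agent = agent
        self.log = log
        self.t = start
        self.start = start
        self.grid = grid
        self.session_index = session_index
        self.record: Optional[SessionRecord] = None
        self._timers: dict[str, int] = {}
        self._agent_deadline: Optional[int] = None
        self._agent_action: Optional[tuple] = None
        self._planned_stage: Optional[str] = None
        self._trials: list[TrialRecord] = []
        self._incorrect_pokes = 0
        self._trial_start = start
        self._stim_onset: Optional[int] = None
        self._choice_onset: Optional[int] = None
        self._response_time: Optional[int] = None

    # -- logging helpers ----

    def _emit(self, event: str, **payload) -> None:
        self.log.append(self.t, self.agent.animal, event, **payload)

    @staticmethod
    def _pos_str(pos: tuple[int, int]) -> str:
        return f"{pos[0]}.{pos[1]}"

    def _apply(self, actions: Sequence) -> None:
        cfg = self.cfg
        for a in actions:
            if isinstance(a, fsm.StimulusOn):
                payload = {"kind": a.kind}
                if a.kind in ("single", "sample") and a.positions:
                    payload["position"] = self._pos_str(a.positions[0])
                if a.kind == "choice" and a.spec is not None:
                    payload.update(
                        splus=self._pos_str(a.spec.splus_loc),
                        sminus=self._pos_str(a.spec.sminus_loc),
                        separation=a.spec.separation,
                        delay=a.spec.delay,
                        correction=int(a.spec.is_correction))
                    self._choice_onset = self.t
                if a.kind in ("single", "all", "sample"):
                    self._stim_onset = self.t
                self._emit("stimulus_on", **payload)
            elif isinstance(a, fsm.StimulusOff):
                self._emit("stimulus_off", kind=a.kind)
            elif isinstance(a, fsm.Reward):
                self._emit("reward", pellets=a.pellets, kind=a.kind)
            elif isinstance(a, fsm.ToneHigh):
                self._emit("tone_high", sound=a.sound)
            elif isinstance(a, fsm.ToneLow):
                self._emit("tone_low")
            elif isinstance(a, fsm.HouselightOn):
                self._emit("houselight_on")
            elif isinstance(a, fsm.HouselightOff):
                self._emit("houselight_off")
            elif isinstance(a, fsm.StartTimer):
                self._timers[a.name] = self.t + a.duration
            elif isinstance(a, fsm.CancelTimer):
                self._timers.pop(a.name, None)
            elif isinstance(a, fsm.TrialComplete):
                self._complete_trial(a)

    def _complete_trial(self, a: fsm.TrialComplete) -> None:
        choice_lat = None
        reward_lat = None
        if a.kind in ("active", "correct", "correction_correct"):
            onset = self._choice_onset if self._choice_onset is not None \
                else self._stim_onset
            if self._response_time is not None and onset is not None:
                choice_lat = self._response_time - onset
                reward_lat = self.t - self._response_time
        self._trials.append(TrialRecord(
            animal=self.agent.animal, phase=self.cfg.phase,
            index_in_session=a.index, kind=a.kind, spec=a.spec,
            choice_latency=choice_lat, reward_latency=reward_lat,
            start=self._trial_start, end=self.t))
        self._trial_start = self.t
        self._choice_onset = None
        self._stim_onset = None
        self._response_time = None

    # -- agent planning ----

    def _plan_agent(self, state: fsm.TrialState) -> None:
        stage = state.stage
        role = _ACTIONABLE.get(stage)
        if role is None:
            self._agent_deadline = None
            self._planned_stage = None
            return
        if self._planned_stage == stage and self._agent_deadline is not None:
            return
        stim = self._stim_for(state, role)
        action, lat = agent_act(self.agent, stim)
        pr = self.agent.params
        if not pr.deterministic and pr.p_engage < 1.0 \
                and self.agent.rng.random() >= pr.p_engage:
            lat = int(self.agent.rng.uniform(30 * SECOND, 120 * SECOND))
        self._agent_deadline = self.t + max(1, lat)
        self._agent_action = action
        self._planned_stage = stage

    def _stim_for(self, state: fsm.TrialState, role: str) -> Stim:
        cfg = self.cfg
        if role in ("magazine", "collect"):
            return Stim(kind=role, phase=cfg.phase)
        if role == "choice":
            spec = state.tunl
            return Stim(kind="choice",
                        targets=(spec.splus_loc, spec.sminus_loc),
                        separation=spec.separation, delay=spec.delay,
                        phase=cfg.phase)
        # response stages
        if state.stage == fsm.SAMPLE:
            targets = (state.tunl.sample_loc,)
        elif cfg.phase in (PhaseId.T4, PhaseId.T5, PhaseId.T6):
            targets = (state.target,)
        else:
            targets = tuple(self.grid.positions())
        return Stim(kind="response", targets=targets,
                    all_positions=tuple(self.grid.positions()),
                    phase=cfg.phase)

    # -- main loop ----

    def gen(self):
        cfg = self.cfg
        self._emit("session_start", phase=cfg.phase.name,
                   session_index=self.session_index)
        state, actions = fsm.start_session(cfg, self.agent.rng, self.grid)
        self._apply(actions)
        self._plan_agent(state)
        cap = None if cfg.max_session_duration is None \
            else self.start + cfg.max_session_duration
        terminated = "time_cap"

        while True:
            deadlines = dict(self._timers)
            if self._agent_deadline is not None:
                deadlines["__agent__"] = self._agent_deadline
            if not deadlines:
                break  # nothing can ever happen again (defensive)
            name = min(deadlines, key=lambda k: (deadlines[k], k))
            nxt = deadlines[name]

            if cap is not None and nxt >= cap and state.stage in (
                    fsm.ITI, fsm.AWAIT_INITIATION):
                if cap > self.t:
                    yield cap - self.t
                    self.t = cap
                terminated = "time_cap"
                break

            if nxt > self.t:
                yield nxt - self.t
                self.t = nxt

            if name == "__agent__":
                self._agent_deadline = None
                self._planned_stage = None
                self._dispatch_agent(state)
            else:
                del self._timers[name]
                state, acts = fsm.trial_fsm_step(
                    cfg, state, fsm.TimerExpired(name))
                self._apply(acts)

            if cfg.max_trials is not None and \
                    len(self._trials) >= cfg.max_trials:
                terminated = "trial_cap"
                break
            self._plan_agent(state)

        self._emit("session_end", phase=cfg.phase.name,
                   trials=len(self._trials), terminated_by=terminated)
        self.record = SessionRecord(
            animal=self.agent.animal, phase=cfg.phase, start=self.start,
            end=self.t, trials=self._trials, terminated_by=terminated,
            incorrect_pokes=self._incorrect_pokes)

    def _dispatch_agent(self, state: fsm.TrialState) -> None:
        action = self._agent_action
        cfg = self.cfg
        if action[0] == "magazine":
            stage = state.stage
            role = {"await_initiation": "initiate",
                    "await_choice_init": "choice_initiate",
                    "await_collection": "collect"}.get(stage, "idle")
            state, acts = fsm.trial_fsm_step(cfg, state, fsm.MagazinePoke())
            self._emit("magazine_poke", role=role)
            self._apply(acts)
        else:
            pos = action[1]
            state, acts = fsm.trial_fsm_step(cfg, state, fsm.ScreenPoke(pos))
            outcome = self._poke_outcome(acts)
            self._emit("screen_poke", position=self._pos_str(pos),
                       outcome=outcome)
            if outcome in ("active", "correct", "sample"):
                self._response_time = self.t
            if outcome == "inert":
                self._incorrect_pokes += 1
            self._apply(acts)

    @staticmethod
    def _poke_outcome(acts: Sequence) -> str:
        for a in acts:
            if isinstance(a, fsm.Reward):
                return a.kind
            if isinstance(a, fsm.TrialComplete) and "incorrect" in a.kind:
                return "incorrect"
            if isinstance(a, fsm.StartTimer) and a.name == "delay":
                return "sample"
        return "inert"


def run_session(cfg: PhaseConfig, agent: AgentParams | AgentState | str,
                seed: int = 0, start: int = 0,
                grid: WindowGrid = DEFAULT_GRID,
                log: Optional[EventLog] = None,
                session_index: int = 1) -> tuple[SessionRecord, EventLog]:
    """Run one chamber session standalone and return its record and log."""
    if isinstance(agent, str):
        agent = preset(agent)
    if isinstance(agent, AgentParams):
        agent = AgentState(animal="A1", params=agent,
                           rng=np.random.default_rng(seed))
    if log is None:
        log = EventLog()
    runner = SessionRunner(cfg, agent, log, start=start, grid=grid,
                           session_index=session_index)
    for _ in runner.gen():
        pass
    return runner.record, log


# -- full simulation ---------------------------------------------------------


class _Simulation:
    def __init__(self, config: SimConfig,
                 agent_params: dict[str, AgentParams]) -> None:
        self.config = config
        self.kernel = Kernel(start=config.start_ms)
        self.log = EventLog(origin_date=config.start_date)
        self.t_end = config.start_ms + config.duration
        self.sorter = SorterState(cohort=frozenset(config.animals))
        self.chamber_free = Signal()
        self.admission_outcome: Optional[Signal] = None
        self.admission_result: Optional[str] = None
        self.window: Optional[tuple[frozenset[str], int, int]] = None
        self.crowding = 0.05   # P(a cage-mate follows through the open gate)

        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(len(config.animals) + 1)
        self.env_rng = np.random.default_rng(children[0])
        self.states: dict[str, AgentState] = {}
        for child, animal in zip(children[1:], config.animals):
            self.states[animal] = AgentState(
                animal=animal, params=agent_params[animal],
                rng=np.random.default_rng(child))

        curriculum = [p for p in config.curriculum]
        self.curriculum = curriculum
        start_idx = 1 if curriculum and curriculum[0] == PhaseId.T1 else 0
        self.phase_idx: dict[str, Optional[int]] = {
            a: start_idx if start_idx < len(curriculum) else None
            for a in config.animals}
        self.histories: dict[str, list[SessionRecord]] = {
            a: [] for a in config.animals}
        self.session_counter: dict[str, int] = {a: 0 for a in config.animals}
        self.completed_at: dict[str, Optional[int]] = {
            a: None for a in config.animals}

    # -- helpers ----

    def lp(self, t: int) -> str:
        return light_phase(t, self.config.cycle)

    def phase_of(self, animal: str) -> Optional[PhaseId]:
        idx = self.phase_idx[animal]
        return None if idx is None else self.curriculum[idx]

    def _phase_history(self, animal: str, phase: PhaseId
                       ) -> list[SessionRecord]:
        return [s for s in self.histories[animal] if s.phase == phase]

    def allowed(self, animal: str, now: int) -> bool:
        phase = self.phase_of(animal)
        if phase is None:
            return False
        cfg = self.config.config_for(phase)
        interval_policy = AccessPolicy(
            intersession_interval=cfg.intersession_interval,
            late_learner_window=self.window)
        if not access_allowed(animal, now, interval_policy,
                              self.histories[animal],
                              self.sorter.chamber_occupant):
            return False
        if cfg.max_sessions_per_24h is not None:
            cap_policy = AccessPolicy(
                max_sessions_per_24h=cfg.max_sessions_per_24h)
            if not access_allowed(animal, now, cap_policy,
                                  self._phase_history(animal, phase),
                                  self.sorter.chamber_occupant):
                return False
        return self.sorter.mode == "idle"

    def policy_wait_time(self, animal: str, now: int) -> int:
        """Earliest policy-permitted attempt time (ideal agents)."""
        phase = self.phase_of(animal)
        cfg = self.config.config_for(phase)
        t = earliest_allowed(
            animal, now,
            AccessPolicy(intersession_interval=cfg.intersession_interval),
            self.histories[animal])
        if cfg.max_sessions_per_24h is not None:
            t = max(t, earliest_allowed(
                animal, t,
                AccessPolicy(max_sessions_per_24h=cfg.max_sessions_per_24h),
                self._phase_history(animal, phase)))
        if self.window is not None:
            animals, start, dur = self.window
            if animal not in animals and start <= t < start + dur:
                t = start + dur
        return t

    def do_sorter(self, event, verdict: bool = False) -> None:
        _, actions = sorter_step(self.sorter, event, policy_verdict=verdict,
                                 now=self.kernel.now)
        for act in actions:
            kind = act[0]
            if kind in ("gate_open", "gate_close"):
                self.log.append(self.kernel.now, "SYSTEM", kind, gate=act[1])
            elif kind == "start_hold_timer":
                _, dur, adm_id = act
                self.kernel.schedule(
                    dur, lambda i=adm_id: self.do_sorter(HoldExpired(i)))
            elif kind == "sort_abort":
                self.log.append(self.kernel.now, "SYSTEM", "sort_abort",
                                animals=",".join(sorted(act[1])))
                if self.admission_outcome is not None:
                    sig, self.admission_outcome = self.admission_outcome, None
                    self.admission_result = "abort"
                    sig.fire("abort")
            elif kind == "admitted":
                if self.admission_outcome is not None:
                    sig, self.admission_outcome = self.admission_outcome, None
                    self.admission_result = "pass"
                    sig.fire("pass")

    def reader(self, animal: str, rd: str, verdict: bool = False) -> None:
        now = self.kernel.now
        self.log.append(now, animal, "reader_detect", reader=rd)
        self.do_sorter(ReaderEvent(reader=rd, animal=animal, timestamp=now),
                       verdict=verdict)

    # -- curriculum ----

    def finish_session(self, animal: str, rec: SessionRecord) -> None:
        self.histories[animal].append(rec)
        st = self.states[animal]
        agent_learn(st, rec)
        phase = self.phase_of(animal)
        if phase is None:
            return
        cfg = self.config.config_for(phase)
        hist = self._phase_history(animal, phase)
        if cfg.criterion is not None and criterion_met(
                phase, hist, config=cfg,
                count_corrections=self.config.count_corrections):
            self._advance(animal, phase)

    def _advance(self, animal: str, phase: PhaseId) -> None:
        idx = self.phase_idx[animal]
        nxt = idx + 1
        now = self.kernel.now
        if nxt >= len(self.curriculum):
            self.phase_idx[animal] = None
            self.completed_at[animal] = now
            self.log.append(now, animal, "phase_transition",
                            source=phase.name, target="DONE")
        else:
            self.phase_idx[animal] = nxt
            self.log.append(now, animal, "phase_transition",
                            source=phase.name,
                            target=self.curriculum[nxt].name)
        # late-learner window: if at least half the group still needs
        # sessions of this phase, restrict access to those animals
        unmet = frozenset(
            a for a in self.config.animals
            if self.phase_idx[a] is not None
            and self.curriculum[self.phase_idx[a]] == phase)
        if unmet and len(unmet) >= len(self.config.animals) / 2:
            self.window = (unmet, now, self.config.late_learner_window)
        else:
            self.window = None

    # -- processes ----

    def agent_proc(self, animal: str):
        st = self.states[animal]
        pr = st.params
        while True:
            now = self.kernel.now
            if self.phase_idx[animal] is None or now >= self.t_end:
                return
            if pr.deterministic:
                t_next = self.policy_wait_time(animal, now)
                if t_next > now:
                    yield t_next - now
                    continue
                if self.sorter.mode != "idle" or \
                        self.sorter.chamber_occupant is not None:
                    yield self.chamber_free
                    continue
            else:
                t_next = decide_visit(st, now, st.rng, light_phase=self.lp)
                yield t_next - now
            if self.phase_idx[animal] is None or self.kernel.now >= self.t_end:
                return
            if st.location != "home":   # e.g. currently tailing another rat
                continue
            yield from self._attempt(animal)

    def _attempt(self, animal: str):
        st = self.states[animal]
        now = self.kernel.now
        verdict = self.allowed(animal, now)
        tailgate = (not verdict and not st.params.deterministic
                    and self.sorter.mode == "admitting"
                    and self.sorter.expected_animal != animal
                    and st.rng.random() < st.params.p_tailgate)
        self.reader(animal, "R1", verdict=verdict)
        if self.sorter.mode == "admitting" and \
                self.sorter.expected_animal == animal:
            yield from self._pass_sorter(animal)
        elif tailgate:
            yield from self._tailgate(animal)
        # otherwise: denied at the closed gate; retreat silently

    def _pass_sorter(self, animal: str):
        st = self.states[animal]
        st.location = "tube"
        outcome_sig = Signal()
        self.admission_outcome = outcome_sig
        self.admission_result = None
        if st.params.deterministic:
            d1, d2 = 2_000, 1_000
        else:
            d1 = int(st.rng.uniform(2_000, 15_000))
            d2 = int(st.rng.uniform(1_000, 4_000))
        yield d1
        self.reader(animal, "R2")
        # while Gate 1 stands open a cage-mate may slip in behind
        if not st.params.deterministic and \
                self.env_rng.random() < self.crowding:
            others = [a for a in self.config.animals
                      if a != animal and self.states[a].location == "home"
                      and not self.states[a].params.deterministic]
            if others:
                follower = others[int(self.env_rng.integers(0, len(others)))]
                spawn(self.kernel, self._tailgate(follower))
        yield d2
        self.reader(animal, "R3")
        if self.admission_result is None:
            outcome = yield outcome_sig
        else:
            outcome = self.admission_result
        if outcome != "pass":
            yield 2_000
            self.reader(animal, "R2")
            yield 1_000
            self.do_sorter(HomeArrived(animal))
            st.location = "home"
            self.chamber_free.fire()
            return
        yield 1_000
        self.do_sorter(ChamberEntered(animal))
        st.location = "chamber"
        yield from self._run_session(animal)

    def _tailgate(self, animal: str):
        st = self.states[animal]
        st.location = "tube"
        yield 2_500
        self.reader(animal, "R2")
        yield 800
        if self.sorter.mode in ("admitting", "holding"):
            self.reader(animal, "R3")
        yield 2_000
        self.reader(animal, "R2")
        yield 1_000
        self.do_sorter(HomeArrived(animal))
        st.location = "home"

    def _run_session(self, animal: str):
        st = self.states[animal]
        phase = self.phase_of(animal)
        cfg = self.config.config_for(phase)
        self.session_counter[animal] += 1
        runner = SessionRunner(cfg, st, self.log, start=self.kernel.now,
                               grid=self.config.grid,
                               session_index=self.session_counter[animal])
        yield from runner.gen()
        rec = runner.record
        self.do_sorter(SessionEnded(animal))
        # exit latency: session end -> homeward R3 detection
        lat = _latency(st, st.params.exit_latency)
        yield lat
        self.reader(animal, "R3")
        st.location = "tube"
        yield 1_500
        self.reader(animal, "R2")
        rec.exit_latency = lat
        rec.sorter_exit = self.kernel.now
        yield 1_000
        self.do_sorter(HomeArrived(animal))
        st.location = "home"
        self.finish_session(animal, rec)
        self.chamber_free.fire()

    # -- habituation (Training 1: open sorter, group session) ----

    def run_t1(self) -> int:
        cfg = self.config.config_for(PhaseId.T1)
        t0 = self.config.start_ms
        t1_end = t0 + (cfg.max_session_duration or DAY)
        self.log.append(t0, "SYSTEM", "gate_open", gate="G1")
        self.log.append(t0, "SYSTEM", "gate_open", gate="G2")
        self.log.append(t0, "SYSTEM", "session_start", phase="T1")
        chamber: set[str] = set()
        changed = Signal()

        def visitor(animal: str):
            st = self.states[animal]
            while True:
                now = self.kernel.now
                if now >= t1_end:
                    return
                nxt = decide_visit(st, now, st.rng, light_phase=self.lp)
                if nxt >= t1_end:
                    yield t1_end - now
                    return
                yield nxt - now
                self.reader(animal, "R2")
                yield 1_000
                self.reader(animal, "R3")
                st.location = "chamber"
                chamber.add(animal)
                changed.fire()
                if self.lp(self.kernel.now) == "dark":
                    dwell = max(5_000, int(st.rng.normal(62_000, 15_000)))
                else:
                    dwell = max(10_000, int(st.rng.normal(262_000, 208_000)))
                yield dwell
                self.reader(animal, "R3")
                yield 1_000
                self.reader(animal, "R2")
                st.location = "home"
                chamber.discard(animal)
                changed.fire()

        def trial_loop():
            rng = self.env_rng
            state, actions = fsm.start_session(cfg, rng, self.config.grid)
            timers: dict[str, int] = {}
            pending: Optional[tuple[int, str]] = None  # (deadline, animal)

            def apply(acts, actor="SYSTEM"):
                nonlocal pending
                for a in acts:
                    now = self.kernel.now
                    if isinstance(a, fsm.StartTimer):
                        timers[a.name] = now + a.duration
                    elif isinstance(a, fsm.CancelTimer):
                        timers.pop(a.name, None)
                    elif isinstance(a, fsm.StimulusOn):
                        self.log.append(now, "SYSTEM", "stimulus_on",
                                        kind=a.kind)
                    elif isinstance(a, fsm.StimulusOff):
                        self.log.append(now, "SYSTEM", "stimulus_off",
                                        kind=a.kind)
                    elif isinstance(a, fsm.Reward):
                        self.log.append(now, "SYSTEM", "reward",
                                        pellets=a.pellets, kind=a.kind)
                    elif isinstance(a, fsm.ToneHigh):
                        self.log.append(now, "SYSTEM", "tone_high",
                                        sound=a.sound)
                    elif isinstance(a, fsm.TrialComplete):
                        pass  # group trials are tallied from the log

            apply(actions)
            while self.kernel.now < t1_end:
                yield 1_000
                now = self.kernel.now
                if now >= t1_end:
                    break
                for name in [n for n, d in sorted(timers.items())
                             if d <= now]:
                    del timers[name]
                    state2, acts = fsm.trial_fsm_step(
                        cfg, state, fsm.TimerExpired(name))
                    apply(acts)
                stage = state.stage
                if stage in (fsm.AWAIT_RESPONSE, fsm.AWAIT_COLLECTION):
                    if pending is None and chamber:
                        actor = sorted(chamber)[
                            int(rng.integers(0, len(chamber)))]
                        lat = max(1_000, int(rng.normal(5_000, 2_500)))
                        pending = (now + lat, actor)
                    elif pending is not None and pending[0] <= now:
                        deadline, actor = pending
                        pending = None
                        if actor in chamber:
                            if stage == fsm.AWAIT_RESPONSE:
                                pos = self.config.grid.positions()[
                                    int(rng.integers(
                                        0, self.config.grid.n_positions))]
                                state2, acts = fsm.trial_fsm_step(
                                    cfg, state, fsm.ScreenPoke(pos))
                                self.log.append(
                                    now, actor, "screen_poke",
                                    position=f"{pos[0]}.{pos[1]}",
                                    outcome="active" if acts else "inert")
                            else:
                                state2, acts = fsm.trial_fsm_step(
                                    cfg, state, fsm.MagazinePoke())
                                self.log.append(now, actor, "magazine_poke",
                                                role="collect")
                            apply(acts)
                else:
                    pending = None

        for animal in self.config.animals:
            spawn(self.kernel, visitor(animal))
        spawn(self.kernel, trial_loop())
        return t1_end

    def _close_t1(self, t1_end: int) -> None:
        self.log.append(t1_end, "SYSTEM", "session_end", phase="T1")
        self.log.append(t1_end, "SYSTEM", "gate_close", gate="G1")
        self.log.append(t1_end, "SYSTEM", "gate_close", gate="G2")
        for animal in self.config.animals:
            self.states[animal].location = "home"
            self.log.append(t1_end, animal, "phase_transition", source="T1",
                            target=self.curriculum[
                                self.phase_idx[animal]].name)

    # -- top level ----

    def run(self) -> EventLog:
        include_t1 = bool(self.curriculum) and \
            self.curriculum[0] == PhaseId.T1
        if include_t1:
            t1_end = self.run_t1()
            self.kernel.run(until=t1_end)
            # drop any leftover habituation wakeups before gating begins
            self.kernel._heap.clear()
            self.kernel.now = t1_end
            self._close_t1(t1_end)
        for animal in self.config.animals:
            spawn(self.kernel, self.agent_proc(animal))
        self.kernel.run()
        return self.log


def run_simulation(config: SimConfig,
                   agents: dict[str, AgentParams] | AgentParams | str
                   ) -> tuple[EventLog, "SimResult"]:
    """Run the full cohort simulation; returns the event log and a summary
    with per-animal session records and curriculum completion times.

    Deterministic given ``config.seed``: one named RNG stream per animal
    plus one for the environment, spawned from the run seed.
    """
    if isinstance(agents, str):
        agents = preset(agents)
    if isinstance(agents, AgentParams):
        agents = {a: agents for a in config.animals}
    missing = set(config.animals) - set(agents)
    if missing:
        raise ValueError(f"no agent parameters for {sorted(missing)}")
    sim = _Simulation(config, agents)
    log = sim.run()
    result = SimResult(histories=sim.histories,
                       completed_at=sim.completed_at,
                       final_phase={a: sim.phase_of(a)
                                    for a in config.animals})
    return log, result


@dataclass
class SimResult:
    histories: dict[str, list[SessionRecord]]
    completed_at: dict[str, Optional[int]]
    final_phase: dict[str, Optional[PhaseId]]


def run_probe_battery(animals: Sequence[str], params: AgentParams,
                      base_seed: int = 0,
                      max_trials: Optional[int] = None,
                      log: Optional[EventLog] = None
                      ) -> tuple[list[SessionRecord], EventLog]:
    """Run the 12-session probe battery (3 separation classes x 2 delays x
    2 repeats, per-animal randomized order) for each animal post-acquisition.

    Sessions run back-to-back on the session simulator; the 7 h / twice-per-
    24 h access schedule does not change the within-session trial stream, so
    probe analyses are unaffected by compressing it.  Pass ``params`` with
    ``learning_rate=0`` to hold accuracy at its acquired level.
    """
    from .protocol import probe_schedule  # local to avoid cycle at import

    if log is None:
        log = EventLog()
    records: list[SessionRecord] = []
    t = 0
    ss = np.random.SeedSequence([base_seed, 7])
    for child, animal in zip(ss.spawn(len(animals)), animals):
        state = AgentState(animal=animal, params=params,
                           rng=np.random.default_rng(child))
        for i, (cond, _rep) in enumerate(probe_schedule(animal, base_seed)):
            overrides = dict(separation_class=cond.separation_class,
                             sample_choice_delay=cond.delay)
            if cond.iti_override is not None:
                overrides["iti"] = cond.iti_override
            if max_trials is not None:
                overrides["max_trials"] = max_trials
            cfg = phase_config(PhaseId.TUNL_PROBE, **overrides)
            runner = SessionRunner(cfg, state, log, start=t,
                                   session_index=i + 1)
            for _ in runner.gen():
                pass
            records.append(runner.record)
            t = runner.record.end + HOUR  # spacer between stitched sessions
    return records, log
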