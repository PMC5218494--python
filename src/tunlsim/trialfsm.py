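"""Per-phase trial state machines.

Each curriculum phase is a small automaton over three event kinds --
screen pokes, magazine pokes and named timer expiries.  ``trial_fsm_step``
consumes one event and returns the emitted chamber actions (stimuli, rewards,
tones, houselight, timers, trial completions).  Events that are illegal in
the current state are ignored, mirroring the tolerance of the control
software to hardware chatter; the session driver still logs them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .protocol import (
    DEFAULT_GRID, PhaseConfig, PhaseId, TunlTrialSpec, WindowGrid,
    draw_tunl_pair, sample_separation_block, separation_for_class,
)

# -- events ------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenPoke:
    pos: tuple[int, int]


@dataclass(frozen=True)
class MagazinePoke:
    pass


@dataclass(frozen=True)
class TimerExpired:
    name: str            # "passive" | "delay" | "timeout" | "iti"


# -- actions -----------------------------------------------------------------


@dataclass(frozen=True)
class StimulusOn:
    positions: tuple[tuple[int, int], ...]
    kind: str            # "all" | "single" | "sample" | "choice" | "magazine"
    spec: Optional[TunlTrialSpec] = None


@dataclass(frozen=True)
class StimulusOff:
    kind: str


@dataclass(frozen=True)
class Reward:
    pellets: int
    kind: str            # "active" | "passive" | "correct" | "sample"


@dataclass(frozen=True)
class ToneHigh:
    sound: str = "tone"  # "tone" (reward) or "click" (trial initiation)


@dataclass(frozen=True)
class ToneLow:
    pass


@dataclass(frozen=True)
class HouselightOn:
    pass


@dataclass(frozen=True)
class HouselightOff:
    pass


@dataclass(frozen=True)
class StartTimer:
    name: str
    duration: int        # ms


@dataclass(frozen=True)
class CancelTimer:
    name: str


@dataclass(frozen=True)
class TrialComplete:
    kind: str            # a protocol.TRIAL_KINDS member
    index: int
    spec: Optional[TunlTrialSpec] = None


Action = object

# -- state -------------------------------------------------------------------

# stages
ITI = "iti"
AWAIT_INITIATION = "await_initiation"     # magazine lit, poke to start
AWAIT_RESPONSE = "await_response"         # window stimuli lit
SAMPLE = "sample"                         # TUNL sample on screen
DELAY = "delay"                           # TUNL retention delay
AWAIT_CHOICE_INIT = "await_choice_init"   # magazine lit after the delay
CHOICE = "choice"                         # S+ / S- on screen
TIMEOUT = "timeout"                       # houselight punishment period
AWAIT_COLLECTION = "await_collection"     # pellet delivered, not yet collected

_LIT_ALL = (PhaseId.T1, PhaseId.T2, PhaseId.T3)
_INIT_PHASES = (PhaseId.T5, PhaseId.T6)


@dataclass
class TrialState:
    """Mutable automaton state for one session."""

    cfg: PhaseConfig
    grid: WindowGrid
    rng: np.random.Generator
    stage: str = ITI
    trial_index: int = 0          # 1-based once the first trial starts
    target: Optional[tuple[int, int]] = None
    tunl: Optional[TunlTrialSpec] = None
    pending_correction: Optional[TunlTrialSpec] = None
    pending_kind: Optional[str] = None     # outcome awaiting collection
    session_separation: Optional[int] = None  # fixed within probe sessions
    _sep_queue: list[int] = field(default_factory=list)

    def _next_separation(self) -> int:
        if self.cfg.separation_class is not None:
            if self.session_separation is None:
                self.session_separation = separation_for_class(
                    self.rng, self.cfg.separation_class)
            return self.session_separation
        if not self._sep_queue:
            self._sep_queue = sample_separation_block(self.rng)
        return self._sep_queue.pop(0)


def start_session(cfg: PhaseConfig, rng: np.random.Generator,
                  grid: WindowGrid = DEFAULT_GRID
                  ) -> tuple[TrialState, list[Action]]:
    """Create the automaton and emit the first trial's opening actions."""
    state = TrialState(cfg=cfg, grid=grid, rng=rng)
    return state, _begin_trial(state)


def _begin_trial(state: TrialState) -> list[Action]:
    cfg = state.cfg
    state.trial_index += 1
    state.pending_kind = None
    if cfg.phase.is_tunl:
        if state.pending_correction is not None:
            state.tunl = state.pending_correction.as_correction()
        else:
            sep = state._next_separation()
            state.tunl = draw_tunl_pair(
                state.rng, sep, state.grid,
                delay=cfg.sample_choice_delay or 0)
        state.stage = AWAIT_INITIATION
        return [StimulusOn(positions=(), kind="magazine")]
    if cfg.phase in _INIT_PHASES:
        state.target = _random_position(state)
        state.stage = AWAIT_INITIATION
        return [StimulusOn(positions=(), kind="magazine")]
    if cfg.phase == PhaseId.T4:
        state.target = _random_position(state)
        state.stage = AWAIT_RESPONSE
        return [StimulusOn(positions=(state.target,), kind="single")]
    # T1-T3: all windows lit
    state.stage = AWAIT_RESPONSE
    actions: list[Action] = [
        StimulusOn(positions=tuple(state.grid.positions()), kind="all")]
    if cfg.passive_timer is not None:
        actions.append(StartTimer("passive", cfg.passive_timer))
    return actions


def _random_position(state: TrialState) -> tuple[int, int]:
    positions = state.grid.positions()
    return positions[int(state.rng.integers(0, len(positions)))]


def _deliver(state: TrialState, kind: str, pellets: int) -> list[Action]:
    """Reward delivery: tray lights up with a brief high tone."""
    state.stage = AWAIT_COLLECTION
    state.pending_kind = kind
    return [Reward(pellets=pellets, kind=kind), ToneHigh(),
            StimulusOn(positions=(), kind="magazine")]


def _punish(state: TrialState, kind: str,
            off_kind: str = "response") -> list[Action]:
    cfg = state.cfg
    state.stage = TIMEOUT
    return [StimulusOff(kind=off_kind), ToneLow(), HouselightOn(),
            StartTimer("timeout", cfg.timeout_on_error or 0),
            TrialComplete(kind=kind, index=state.trial_index,
                          spec=state.tunl)]


def trial_fsm_step(cfg: PhaseConfig, state: TrialState, event
                   ) -> tuple[TrialState, list[Action]]:
    """Advance the phase automaton by one event.

    Returns the (mutated) state and the chamber actions to execute.  Illegal
    events produce no actions.
    """
    if cfg.phase.is_tunl:
        return state, _step_tunl(state, event)
    return state, _step_training(state, event)


def _step_training(state: TrialState, event) -> list[Action]:
    cfg = state.cfg
    stage = state.stage

    if stage == AWAIT_INITIATION and isinstance(event, MagazinePoke):
        state.stage = AWAIT_RESPONSE
        return [StimulusOff(kind="magazine"), ToneHigh(sound="click"),
                StimulusOn(positions=(state.target,), kind="single")]

    if stage == AWAIT_RESPONSE and isinstance(event, ScreenPoke):
        if cfg.phase in _LIT_ALL:
            kind = "active" if cfg.phase in (PhaseId.T1, PhaseId.T2) \
                else "correct"
            acts: list[Action] = [StimulusOff(kind="response")]
            if cfg.passive_timer is not None:
                acts.append(CancelTimer("passive"))
            return acts + _deliver(state, kind, cfg.reward_active)
        # single-target phases
        if event.pos == state.target:
            return [StimulusOff(kind="response")] + \
                _deliver(state, "correct", cfg.reward_active)
        if cfg.phase == PhaseId.T6:
            return _punish(state, "incorrect")
        return []  # T4/T5: off-target pokes are recorded but inconsequential

    if stage == AWAIT_RESPONSE and isinstance(event, TimerExpired) \
            and event.name == "passive" and cfg.passive_timer is not None:
        return [StimulusOff(kind="response")] + \
            _deliver(state, "passive", cfg.reward_passive or 1)

    if stage == AWAIT_COLLECTION and isinstance(event, MagazinePoke):
        kind = state.pending_kind or "correct"
        state.stage = ITI
        return [StimulusOff(kind="magazine"),
                TrialComplete(kind=kind, index=state.trial_index),
                StartTimer("iti", cfg.iti)]

    if stage == TIMEOUT and isinstance(event, TimerExpired) \
            and event.name == "timeout":
        state.stage = ITI
        return [HouselightOff(), StartTimer("iti", cfg.iti)]

    if stage == ITI and isinstance(event, TimerExpired) \
            and event.name == "iti":
        return _begin_trial(state)

    return []


def _step_tunl(state: TrialState, event) -> list[Action]:
    cfg = state.cfg
    stage = state.stage
    spec = state.tunl

    if stage == AWAIT_INITIATION and isinstance(event, MagazinePoke):
        state.stage = SAMPLE
        return [StimulusOff(kind="magazine"), ToneHigh(sound="click"),
                StimulusOn(positions=(spec.sample_loc,), kind="sample",
                           spec=spec)]

    if stage == SAMPLE and isinstance(event, ScreenPoke):
        if event.pos == spec.sample_loc:
            state.stage = DELAY
            return [StimulusOff(kind="sample"),
                    StartTimer("delay", spec.delay)]
        return []  # black windows are inert

    if stage == DELAY and isinstance(event, TimerExpired) \
            and event.name == "delay":
        state.stage = AWAIT_CHOICE_INIT
        acts: list[Action] = [StimulusOn(positions=(), kind="magazine")]
        p = cfg.sample_reward_prob or 0.0
        if p > 0 and state.rng.random() < p:
            acts.append(Reward(pellets=1, kind="sample"))
        return acts

    if stage == AWAIT_CHOICE_INIT and isinstance(event, MagazinePoke):
        state.stage = CHOICE
        return [StimulusOff(kind="magazine"),
                StimulusOn(positions=(spec.splus_loc, spec.sminus_loc),
                           kind="choice", spec=spec)]

    if stage == CHOICE and isinstance(event, ScreenPoke):
        if event.pos == spec.splus_loc:
            kind = "correction_correct" if spec.is_correction else "correct"
            state.pending_correction = None
            return [StimulusOff(kind="choice")] + \
                _deliver(state, kind, cfg.reward_active)
        if event.pos == spec.sminus_loc:
            kind = "correction_incorrect" if spec.is_correction \
                else "incorrect"
            # re-present the identical pair until a correct choice occurs
            state.pending_correction = spec
            return _punish(state, kind, off_kind="choice")
        return []  # black windows are inert

    if stage == AWAIT_COLLECTION and isinstance(event, MagazinePoke):
        kind = state.pending_kind or "correct"
        state.stage = ITI
        return [StimulusOff(kind="magazine"),
                TrialComplete(kind=kind, index=state.trial_index, spec=spec),
                StartTimer("iti", cfg.iti)]

    if stage == TIMEOUT and isinstance(event, TimerExpired) \
            and event.name == "timeout":
        state.stage = ITI
        return [HouselightOff(), StartTimer("iti", cfg.iti)]

    if stage == ITI and isinstance(event, TimerExpired) \
            and event.name == "iti":
        return _begin_trial(state)

    return []
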