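"""RFID animal-sorter finite-state machine, visit reconstruction and the
chamber access policy.

The sorter is a tube between the group home cage and the operant chamber
with two guillotine gates (G1 home side, G2 chamber side) and three RFID
readers: R1 just outside G1, R2 and R3 inside the tube (R3 at the chamber
end).  The machine guarantees single occupancy of the chamber: an identified
animal is admitted through G1, held for 30 s with both gates closed, and
passed through G2 only if it is alone in the tube; detection of a second
animal during the hold aborts the sequence and reopens G1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .protocol import DAY, HOUR, SECOND, SessionRecord

HOLD_MS = 30 * SECOND          # both gates closed during the hold
DEBOUNCE_MS = 1 * SECOND       # coalesce repeated same-reader detections

# -- events ------------------------------------------------------------------


@dataclass(frozen=True)
class ReaderEvent:
    reader: str                # "R1" | "R2" | "R3"
    animal: str
    timestamp: int             # ms


@dataclass(frozen=True)
class HoldExpired:
    admission_id: int


@dataclass(frozen=True)
class SessionEnded:
    animal: str


@dataclass(frozen=True)
class ChamberEntered:
    animal: str


@dataclass(frozen=True)
class HomeArrived:
    animal: str


# -- state -------------------------------------------------------------------


@dataclass
class SorterState:
    gate1: str = "closed"
    gate2: str = "closed"
    mode: str = "idle"         # idle | admitting | holding | passing | aborting
    hold_timer_deadline: Optional[int] = None
    animals_in_tube: set[str] = field(default_factory=set)
    chamber_occupant: Optional[str] = None
    direction: str = "in"      # "in" (admission) or "out" (homeward exit)
    expected_animal: Optional[str] = None
    admission_id: int = 0      # invalidates stale hold timers
    readers_seen: dict[str, set[str]] = field(default_factory=dict)
    cohort: Optional[frozenset[str]] = None

    def check_invariants(self) -> None:
        if self.mode == "holding":
            assert self.gate1 == "closed" and self.gate2 == "closed"


def _gate(state: SorterState, gate: str, position: str) -> list[tuple]:
    """Move a gate; commanding a gate already in position is a no-op."""
    current = getattr(state, gate)
    if current == position:
        return []
    setattr(state, gate, position)
    kind = "gate_open" if position == "open" else "gate_close"
    return [(kind, "G1" if gate == "gate1" else "G2")]


def sorter_step(state: SorterState, event, policy_verdict: bool = False,
                now: int = 0) -> tuple[SorterState, list[tuple]]:
    """Advance the sorter FSM by one event; returns (state, actions).

    Actions are tuples: ``("gate_open"|"gate_close", gate)``,
    ``("start_hold_timer", duration_ms, admission_id)``,
    ``("sort_abort", frozenset_of_animals)``, ``("admitted", animal)``.
    """
    actions: list[tuple] = []

    if isinstance(event, ReaderEvent):
        if state.cohort is not None and event.animal not in state.cohort:
            raise ValueError(f"reader event for unknown animal {event.animal!r}")
        animal, reader = event.animal, event.reader

        if reader == "R1":
            if state.mode == "idle" and state.chamber_occupant is None \
                    and policy_verdict:
                state.mode = "admitting"
                state.direction = "in"
                state.expected_animal = animal
                state.admission_id += 1
                state.readers_seen = {}
                actions += _gate(state, "gate1", "open")
            return state, actions

        # R2 / R3 inside the tube
        if state.mode == "admitting":
            state.animals_in_tube.add(animal)
            state.readers_seen.setdefault(animal, set()).add(reader)
            if state.readers_seen[animal] >= {"R2", "R3"}:
                state.mode = "holding"
                state.hold_timer_deadline = now + HOLD_MS
                actions += _gate(state, "gate1", "closed")
                actions.append(("start_hold_timer", HOLD_MS,
                                state.admission_id))
            return state, actions

        if state.mode == "holding":
            state.animals_in_tube.add(animal)
            if len(state.animals_in_tube) > 1:
                # a second animal in the tube aborts the sorting sequence
                state.mode = "aborting"
                state.hold_timer_deadline = None
                actions += _gate(state, "gate1", "open")
                actions.append(("sort_abort",
                                frozenset(state.animals_in_tube)))
            return state, actions

        if state.mode == "passing" and state.direction == "out" \
                and animal == state.chamber_occupant and reader == "R3":
            # occupant stepping back into the tube on the way home
            state.animals_in_tube.add(animal)
            actions += _gate(state, "gate2", "closed")
            actions += _gate(state, "gate1", "open")
            return state, actions

        return state, actions   # chatter outside any active sequence

    if isinstance(event, HoldExpired):
        if state.mode == "holding" and event.admission_id == state.admission_id:
            state.hold_timer_deadline = None
            if len(state.animals_in_tube) == 1:
                state.mode = "passing"
                state.direction = "in"
                actions += _gate(state, "gate2", "open")
                actions.append(("admitted", next(iter(state.animals_in_tube))))
            else:   # defensive: should have aborted on the reader event
                state.mode = "aborting"
                actions += _gate(state, "gate1", "open")
                actions.append(("sort_abort",
                                frozenset(state.animals_in_tube)))
        return state, actions

    if isinstance(event, ChamberEntered):
        if state.mode == "passing" and state.direction == "in":
            state.animals_in_tube.discard(event.animal)
            state.chamber_occupant = event.animal
            state.mode = "idle"
            state.expected_animal = None
            actions += _gate(state, "gate2", "closed")
        return state, actions

    if isinstance(event, SessionEnded):
        if state.chamber_occupant == event.animal:
            state.mode = "passing"
            state.direction = "out"
            actions += _gate(state, "gate2", "open")
        return state, actions

    if isinstance(event, HomeArrived):
        state.animals_in_tube.discard(event.animal)
        if state.chamber_occupant == event.animal:
            state.chamber_occupant = None
        if not state.animals_in_tube and state.mode in ("aborting", "passing"):
            state.mode = "idle"
            state.expected_animal = None
            actions += _gate(state, "gate1", "closed")
            actions += _gate(state, "gate2", "closed")
        return state, actions

    return state, actions       # unknown event: ignore


# -- visit reconstruction ----------------------------------------------------


@dataclass(frozen=True)
class VisitRecord:
    """A chamber visit: R2 detection followed by two R3 detections; the stay
    is the time between the two R3 detections."""

    animal: str
    enter_time: int            # first R3
    exit_time: int             # second R3

    @property
    def duration(self) -> int:
        return self.exit_time - self.enter_time


def debounce(events: Sequence[ReaderEvent],
             window: int = DEBOUNCE_MS) -> list[ReaderEvent]:
    """Coalesce repeated detections of the same animal at the same reader
    within ``window`` ms (keeps the first)."""
    last: dict[tuple[str, str], int] = {}
    out = []
    for ev in events:
        key = (ev.animal, ev.reader)
        if key in last and ev.timestamp - last[key] < window:
            last[key] = ev.timestamp
            continue
        last[key] = ev.timestamp
        out.append(ev)
    return out


def detect_visits(events: Sequence[ReaderEvent]) -> list[VisitRecord]:
    """Reconstruct chamber visits from a time-sorted reader-event stream.

    Per animal, each maximal R2 -> R3 -> R3 subsequence yields one visit;
    unmatched prefixes are discarded.  Interleaved streams of several animals
    give the same result as processing each animal's stream alone.
    """
    if any(b.timestamp < a.timestamp for a, b in zip(events, events[1:])):
        raise ValueError("reader events must be time-sorted")
    events = debounce(events)
    # state per animal: None (want R2) | ("r2",) | ("r3", t_first)
    st: dict[str, Optional[tuple]] = {}
    visits: list[VisitRecord] = []
    for ev in events:
        if ev.reader == "R1":
            continue
        cur = st.get(ev.animal)
        if ev.reader == "R2":
            st[ev.animal] = ("r2",)
        elif ev.reader == "R3":
            if cur == ("r2",):
                st[ev.animal] = ("r3", ev.timestamp)
            elif cur is not None and cur[0] == "r3":
                visits.append(VisitRecord(animal=ev.animal,
                                          enter_time=cur[1],
                                          exit_time=ev.timestamp))
                st[ev.animal] = None
    return sorted(visits, key=lambda v: (v.enter_time, v.animal))


# -- access policy -----------------------------------------------------------


@dataclass
class AccessPolicy:
    """Inter-session interval, per-24 h session cap and optional
    late-learner window restricting access to not-yet-passed animals."""

    intersession_interval: int = 0                  # ms
    max_sessions_per_24h: Optional[int] = None
    late_learner_window: Optional[tuple[frozenset[str], int, int]] = None
    # (animal set, window start ms, window duration ms)

    def __post_init__(self) -> None:
        if self.intersession_interval < 0:
            raise ValueError("inter-session interval must be >= 0")


def access_allowed(animal: str, now: int, policy: AccessPolicy,
                   history: Sequence[SessionRecord],
                   chamber_occupant: Optional[str] = None) -> bool:
    """Whether ``animal`` may be admitted to the chamber at time ``now``.

    ``history`` is the animal's own completed sessions, time-ordered.  The
    inter-session interval is anchored at the animal's exit from the sorter
    after its previous session.
    """
    if chamber_occupant is not None:
        return False
    if history:
        last = history[-1]
        anchor = last.sorter_exit if last.sorter_exit is not None else last.end
        if now - anchor < policy.intersession_interval:
            return False
    if policy.max_sessions_per_24h is not None:
        recent = sum(1 for s in history if now - s.start < DAY)
        if recent >= policy.max_sessions_per_24h:
            return False
    if policy.late_learner_window is not None:
        animals, start, duration = policy.late_learner_window
        if start <= now < start + duration and animal not in animals:
            return False
    return True


def earliest_allowed(animal: str, now: int, policy: AccessPolicy,
                     history: Sequence[SessionRecord]) -> int:
    """Earliest time >= now at which the policy itself (interval + cap)
    would admit the animal, ignoring chamber occupancy and windows."""
    t = now
    if history:
        last = history[-1]
        anchor = last.sorter_exit if last.sorter_exit is not None else last.end
        t = max(t, anchor + policy.intersession_interval)
    if policy.max_sessions_per_24h is not None:
        starts = sorted(s.start for s in history)
        cap = policy.max_sessions_per_24h
        while sum(1 for s in starts if t - s < DAY) >= cap:
            # wait until the oldest start inside the trailing window ages out
            inside = [s for s in starts if t - s < DAY]
            t = inside[0] + DAY
    return t


def intersession_interval(session_duration: int, group_size: int,
                          margin: int = 0) -> int:
    """Interval letting every other group member complete one session:
    session duration x (group size - 1) + margin."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    return session_duration * (group_size - 1) + margin


def min_days_for_sessions(n_sessions: int, session_duration: int,
                          policy: AccessPolicy) -> float:
    """Calendar days (fractional) to complete ``n_sessions`` as early as the
    access policy permits, constructed by stepping the policy itself."""
    history: list[SessionRecord] = []
    t = 0
    from .protocol import PhaseId
    for _ in range(n_sessions):
        t = earliest_allowed("a", t, policy, history)
        rec = SessionRecord(animal="a", phase=PhaseId.TUNL_ACQ, start=t,
                            end=t + session_duration,
                            sorter_exit=t + session_duration)
        history.append(rec)
        t = rec.end
    return history[-1].end / DAY
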