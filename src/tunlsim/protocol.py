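"""Curriculum phases, stimulus geometry, samplers, performance formulas and
acquisition criteria for automated touchscreen operant training.

The training curriculum comprises six shaping phases (habituation through
punished errors) followed by acquisition of the trial-unique non-matching to
location (TUNL) working-memory task, its probe battery (separation x delay)
and an interference variant.  All durations are integer milliseconds.
"""
from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

# -- time units (integer milliseconds) --------------------------------------
SECOND = 1_000
MINUTE = 60 * SECOND
HOUR = 60 * MINUTE
DAY = 24 * HOUR


class PhaseId(enum.IntEnum):
    """Curriculum phases, totally ordered by progression."""

    T1 = 1          # habituation / exploration, open sorter
    T2 = 2          # initial touch (all windows lit, passive fallback)
    T3 = 3          # must touch, all windows lit
    T4 = 4          # touch the single lit window
    T5 = 5          # magazine-poke trial initiation
    T6 = 6          # punishment for incorrect choices
    TUNL_ACQ = 7    # TUNL acquisition
    TUNL_PROBE = 8  # probe battery (separation class x delay)
    INTERFERENCE = 9  # short-ITI interference variant

    @property
    def is_tunl(self) -> bool:
        return self >= PhaseId.TUNL_ACQ


@dataclass(frozen=True)
class WindowGrid:
    """Response-window geometry of the touchscreen mask.

    The default is the standard rat mask: three rows by five columns of
    3.3 cm windows.  Positions are addressed (row, col), both 1-based.
    """

    rows: int = 3
    cols: int = 5
    window_size_cm: float = 3.3

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_positions(self) -> int:
        return self.rows * self.cols

    def positions(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(1, self.rows + 1)
                for c in range(1, self.cols + 1)]

    def contains(self, pos: tuple[int, int]) -> bool:
        r, c = pos
        return 1 <= r <= self.rows and 1 <= c <= self.cols


DEFAULT_GRID = WindowGrid()

#: probe separation classes: windows between the two choice stimuli
SEPARATION_CLASSES: dict[str, tuple[int, ...]] = {
    "small": (0,),
    "medium": (1, 2),
    "large": (3,),
}


@dataclass(frozen=True)
class CriterionSpec:
    """Per-phase acquisition criterion.

    window:
      * ``any_two``     -- n_sessions passing sessions, in any order
      * ``consecutive`` -- n_sessions passing sessions in direct succession
      * ``within_24h``  -- n_sessions passing sessions whose starts span <= 24 h
    ``min_total_sessions`` is a graduation floor on completed sessions of the
    phase regardless of performance (the TUNL 20-session minimum).
    """

    required_trials: Optional[int] = None
    required_pct_correct: Optional[float] = None
    n_sessions: int = 2
    window: str = "any_two"
    min_total_sessions: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.required_pct_correct is not None and not (
                0 < self.required_pct_correct <= 100):
            raise ValueError("required_pct_correct must be in (0, 100]")
        if self.window not in ("any_two", "consecutive", "within_24h"):
            raise ValueError(f"unknown criterion window {self.window!r}")


@dataclass(frozen=True)
class PhaseConfig:
    """All timing, cap and criterion parameters of one curriculum phase."""

    phase: PhaseId
    max_trials: Optional[int]              # None = unlimited
    max_session_duration: Optional[int]    # ms; None = unlimited
    iti: int                               # ms
    passive_timer: Optional[int] = None    # ms until a passive reward
    reward_active: int = 1                 # pellets for an active/correct trial
    reward_passive: Optional[int] = None   # pellets for a passive trial
    timeout_on_error: Optional[int] = None  # ms, houselight on
    sample_choice_delay: Optional[int] = None  # TUNL sample->choice delay, ms
    sample_reward_prob: Optional[float] = None  # P(pellet on sample completion)
    intersession_interval: int = 0         # ms, anchored at sorter exit
    max_sessions_per_24h: Optional[int] = None  # None = unlimited
    criterion: Optional[CriterionSpec] = None
    separation_class: Optional[str] = None  # None = blocked 0-3 sampling

    def __post_init__(self) -> None:
        if self.iti <= 0:
            raise ValueError("iti must be positive")
        if self.sample_reward_prob is not None and not (
                0 <= self.sample_reward_prob <= 1):
            raise ValueError("sample_reward_prob must be in [0, 1]")
        if self.separation_class is not None and \
                self.separation_class not in SEPARATION_CLASSES:
            raise ValueError(f"unknown separation class {self.separation_class!r}")


def _phase_defaults() -> dict[PhaseId, PhaseConfig]:
    tunl_common = dict(
        max_trials=84,
        max_session_duration=60 * MINUTE,
        iti=20 * SECOND,
        reward_active=1,
        timeout_on_error=5 * SECOND,
        sample_choice_delay=2 * SECOND,
        sample_reward_prob=1 / 3,
        intersession_interval=7 * HOUR,
        max_sessions_per_24h=2,
    )
    return {
        PhaseId.T1: PhaseConfig(
            phase=PhaseId.T1, max_trials=None,
            max_session_duration=24 * HOUR, iti=30 * SECOND,
            passive_timer=15 * MINUTE, reward_active=2, reward_passive=1,
            intersession_interval=0, criterion=None),
        PhaseId.T2: PhaseConfig(
            phase=PhaseId.T2, max_trials=17,
            max_session_duration=10 * MINUTE, iti=20 * SECOND,
            passive_timer=30 * SECOND, reward_active=2, reward_passive=1,
            intersession_interval=30 * MINUTE,
            criterion=CriterionSpec(required_trials=17, n_sessions=2,
                                    window="any_two")),
        PhaseId.T3: PhaseConfig(
            phase=PhaseId.T3, max_trials=50,
            max_session_duration=30 * MINUTE, iti=20 * SECOND,
            intersession_interval=int(2.5 * HOUR),
            criterion=CriterionSpec(required_trials=50, n_sessions=2,
                                    window="within_24h")),
        PhaseId.T4: PhaseConfig(
            phase=PhaseId.T4, max_trials=50,
            max_session_duration=30 * MINUTE, iti=20 * SECOND,
            intersession_interval=int(2.5 * HOUR),
            criterion=CriterionSpec(required_trials=50, n_sessions=2,
                                    window="consecutive")),
        PhaseId.T5: PhaseConfig(
            phase=PhaseId.T5, max_trials=50,
            max_session_duration=30 * MINUTE, iti=20 * SECOND,
            intersession_interval=int(2.5 * HOUR),
            criterion=CriterionSpec(required_trials=50, n_sessions=2,
                                    window="any_two")),
        PhaseId.T6: PhaseConfig(
            phase=PhaseId.T6, max_trials=50,
            max_session_duration=30 * MINUTE, iti=20 * SECOND,
            timeout_on_error=5 * SECOND,
            intersession_interval=int(2.5 * HOUR),
            criterion=CriterionSpec(required_trials=50,
                                    required_pct_correct=80.0,
                                    n_sessions=2, window="consecutive")),
        PhaseId.TUNL_ACQ: PhaseConfig(
            phase=PhaseId.TUNL_ACQ,
            criterion=CriterionSpec(required_pct_correct=70.0, n_sessions=2,
                                    window="consecutive",
                                    min_total_sessions=20),
            **tunl_common),
        PhaseId.TUNL_PROBE: PhaseConfig(
            phase=PhaseId.TUNL_PROBE, criterion=None, **tunl_common),
        PhaseId.INTERFERENCE: PhaseConfig(
            phase=PhaseId.INTERFERENCE, criterion=None,
            **{**tunl_common, "iti": 5 * SECOND,
               "separation_class": "large"}),
    }


_PHASE_DEFAULTS = _phase_defaults()


def phase_config(phase: PhaseId | str, **overrides) -> PhaseConfig:
    """Return the canonical configuration of a phase, optionally overridden.

    Defaults encode the published automated protocol: Training 2 caps a
    session at 17 trials or 10 min with a 30 min inter-session interval;
    Trainings 3-6 at 50 trials or 30 min with a 2.5 h interval (T6 adds a
    5 s error timeout); TUNL at 84 trials or 60 min with a 2 s delay, a 7 h
    interval and at most two sessions per 24 h.
    """
    if isinstance(phase, str):
        try:
            phase = PhaseId[phase]
        except KeyError:
            raise ValueError(f"unknown phase {phase!r}") from None
    if phase not in _PHASE_DEFAULTS:
        raise ValueError(f"unknown phase {phase!r}")
    cfg = _PHASE_DEFAULTS[phase]
    return replace(cfg, **overrides) if overrides else cfg


def interference_config(**overrides) -> PhaseConfig:
    """TUNL interference variant: ITI shortened to 5 s, 2 s delay, large
    separation (easy discrimination), so any carry-over from the previous
    trial can express itself."""
    return phase_config(PhaseId.INTERFERENCE, **overrides)


# -- TUNL trial geometry -----------------------------------------------------

@dataclass(frozen=True)
class TunlTrialSpec:
    """One TUNL trial: sample location (= later S-), rewarded novel S+,
    separation (windows between the two choice stimuli) and delay."""

    sample_loc: tuple[int, int]
    splus_loc: tuple[int, int]
    sminus_loc: tuple[int, int]
    separation: int
    delay: int                 # ms
    is_correction: bool = False

    def __post_init__(self) -> None:
        if self.sminus_loc != self.sample_loc:
            raise ValueError("S- must be the previous sample location")
        if self.splus_loc == self.sminus_loc:
            raise ValueError("S+ and S- must differ")
        if self.splus_loc[0] != self.sminus_loc[0]:
            raise ValueError("choice stimuli must share a row")
        gap = abs(self.splus_loc[1] - self.sminus_loc[1]) - 1
        if gap != self.separation:
            raise ValueError("separation inconsistent with column gap")
        if not 0 <= self.separation <= 3:
            raise ValueError("separation must be in 0..3")

    def as_correction(self) -> "TunlTrialSpec":
        return replace(self, is_correction=True)


@dataclass(frozen=True)
class ProbeCondition:
    """One probe-session condition: separation class x sample-choice delay."""

    separation_class: str
    delay: int                      # ms: 2 s or 6 s
    iti_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.separation_class not in SEPARATION_CLASSES:
            raise ValueError(
                f"unknown separation class {self.separation_class!r}")


# -- trial / session records -------------------------------------------------

TRIAL_KINDS = ("active", "passive", "correct", "incorrect",
               "correction_correct", "correction_incorrect")


@dataclass
class TrialRecord:
    animal: str
    phase: PhaseId
    index_in_session: int
    kind: str
    spec: Optional[TunlTrialSpec] = None
    choice_latency: Optional[int] = None   # ms
    reward_latency: Optional[int] = None   # ms
    start: int = 0                         # ms, simulation clock
    end: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("trial end precedes start")
        if self.kind.startswith("correction") and not self.phase.is_tunl:
            raise ValueError("correction trials only occur in TUNL phases")


@dataclass
class SessionRecord:
    animal: str
    phase: PhaseId
    start: int
    end: int
    trials: list[TrialRecord] = field(default_factory=list)
    terminated_by: str = "trial_cap"       # or "time_cap"
    exit_latency: Optional[int] = None     # session end -> homeward R3, ms
    sorter_exit: Optional[int] = None      # anchors the inter-session interval
    incorrect_pokes: int = 0               # off-target pokes (T5+)

    @property
    def duration(self) -> int:
        return self.end - self.start

    def trial_count(self, count_corrections: bool = True) -> int:
        if count_corrections:
            return len(self.trials)
        return sum(not t.kind.startswith("correction") for t in self.trials)


# -- constrained pseudo-random samplers -------------------------------------

def sample_separation_block(rng: np.random.Generator,
                            block_len: int = 20) -> list[int]:
    """One block of TUNL separations, each of {0,1,2,3} occurring >= twice.

    Construction: two forced copies of each separation (8 slots) plus
    ``block_len - 8`` uniform draws, then one uniform shuffle.  Deterministic
    satisfaction of the constraint -- no rejection loop.
    """
    if block_len < 8:
        raise ValueError("block_len must be >= 8 to fit two of each separation")
    block = [0, 0, 1, 1, 2, 2, 3, 3]
    block += list(rng.integers(0, 4, size=block_len - 8))
    block = [int(x) for x in block]
    rng.shuffle(block)
    return block


def draw_tunl_pair(rng: np.random.Generator, separation: int,
                   grid: WindowGrid = DEFAULT_GRID,
                   delay: int = 2 * SECOND) -> TunlTrialSpec:
    """Draw a TUNL stimulus pair at the given separation.

    Row uniform over grid rows; the column pair uniform among pairs whose gap
    minus one equals the separation; S+/S- roles assigned by fair coin; the
    sample location equals S-.
    """
    if not 0 <= separation <= grid.cols - 2:
        raise ValueError(
            f"separation {separation} unattainable on a {grid.cols}-column grid")
    row = int(rng.integers(1, grid.rows + 1))
    left = int(rng.integers(1, grid.cols - separation))  # leftmost column
    cols = (left, left + separation + 1)
    if rng.random() < 0.5:
        splus, sminus = (row, cols[0]), (row, cols[1])
    else:
        splus, sminus = (row, cols[1]), (row, cols[0])
    return TunlTrialSpec(sample_loc=sminus, splus_loc=splus, sminus_loc=sminus,
                         separation=separation, delay=delay)


def separation_for_class(rng: np.random.Generator, cls: str) -> int:
    choices = SEPARATION_CLASSES[cls]
    return int(choices[rng.integers(0, len(choices))])


# -- performance formulas ----------------------------------------------------

def pct_active(session: SessionRecord) -> float:
    """Training 2: percentage of trials answered with a screen poke.

    100 x active / (active + passive).  Undefined on an empty session.
    """
    if session.phase != PhaseId.T2:
        raise ValueError("pct_active is defined for Training 2 sessions")
    active = sum(t.kind == "active" for t in session.trials)
    passive = sum(t.kind == "passive" for t in session.trials)
    if active + passive == 0:
        raise ValueError("empty session: percent active is undefined")
    return 100.0 * active / (active + passive)


def pct_correct_fixed_denominator(session: SessionRecord,
                                  denominator: int = 50) -> float:
    """Trainings 3-5: completed trials over the 50-trial session maximum."""
    if session.phase not in (PhaseId.T3, PhaseId.T4, PhaseId.T5):
        raise ValueError("fixed-denominator percent applies to Trainings 3-5")
    completed = session.trial_count()
    if completed > denominator:
        raise ValueError("more completed trials than the session cap allows")
    return 100.0 * completed / denominator


def pct_correct_ratio(session: SessionRecord,
                      count_corrections: bool = False) -> float:
    """Training 6 / TUNL: correct over (correct + incorrect) choices.

    Correction trials are excluded by default (standard TUNL convention);
    set ``count_corrections`` to include them.
    """
    if session.phase not in (PhaseId.T6, PhaseId.TUNL_ACQ,
                             PhaseId.TUNL_PROBE, PhaseId.INTERFERENCE):
        raise ValueError("ratio percent applies to Training 6 and TUNL phases")
    if count_corrections:
        correct = sum(t.kind in ("correct", "correction_correct")
                      for t in session.trials)
        incorrect = sum(t.kind in ("incorrect", "correction_incorrect")
                        for t in session.trials)
    else:
        correct = sum(t.kind == "correct" for t in session.trials)
        incorrect = sum(t.kind == "incorrect" for t in session.trials)
    if correct + incorrect == 0:
        raise ValueError("no scored choices: percent correct is undefined")
    return 100.0 * correct / (correct + incorrect)


def session_pct(session: SessionRecord,
                count_corrections: bool = False) -> float:
    """Phase-appropriate percent for a session."""
    if session.phase == PhaseId.T2:
        return pct_active(session)
    if session.phase in (PhaseId.T3, PhaseId.T4, PhaseId.T5):
        return pct_correct_fixed_denominator(session)
    return pct_correct_ratio(session, count_corrections=count_corrections)


# -- acquisition criteria ----------------------------------------------------

def _session_passes(crit: CriterionSpec, session: SessionRecord,
                    count_corrections: bool) -> bool:
    if crit.required_trials is not None and \
            session.trial_count() < crit.required_trials:
        return False
    if crit.required_pct_correct is not None:
        try:
            pct = session_pct(session, count_corrections=count_corrections)
        except ValueError:
            return False
        if pct < crit.required_pct_correct:
            return False
    return True


def criterion_met(phase: PhaseId, history: Sequence[SessionRecord],
                  config: Optional[PhaseConfig] = None,
                  count_corrections: bool = False) -> bool:
    """Whether an animal's completed, time-ordered sessions of ``phase``
    satisfy its acquisition criterion."""
    cfg = config if config is not None else phase_config(phase)
    if any(s.phase != phase for s in history):
        raise ValueError("history contains sessions of a different phase")
    crit = cfg.criterion
    if crit is None:
        return False
    if len(history) < max(crit.n_sessions, crit.min_total_sessions):
        return False
    passes = [_session_passes(crit, s, count_corrections) for s in history]
    n = crit.n_sessions
    if crit.window == "any_two":
        return sum(passes) >= n
    if crit.window == "consecutive":
        return any(all(passes[i:i + n]) for i in range(len(passes) - n + 1))
    # within_24h: n passing sessions whose starts span at most 24 h
    starts = [s.start for s, ok in zip(history, passes) if ok]
    for i in range(len(starts) - n + 1):
        if starts[i + n - 1] - starts[i] <= DAY:
            return True
    return False


# -- probe scheduling --------------------------------------------------------

def probe_seed(animal: str, base_seed: int = 0) -> int:
    """Deterministic per-animal seed for the probe-session ordering."""
    return (zlib.crc32(str(animal).encode()) ^ (base_seed * 2654435761)) \
        % (2 ** 31)


def probe_schedule(animal: str, base_seed: int = 0
                   ) -> list[tuple[ProbeCondition, int]]:
    """The probe battery for one animal: three separation classes crossed
    with 2 s and 6 s delays, each condition run twice -- 12 sessions in a
    per-animal pseudo-random order with a recorded seed."""
    conditions = [
        (ProbeCondition(separation_class=cls, delay=delay), rep)
        for cls in ("small", "medium", "large")
        for delay in (2 * SECOND, 6 * SECOND)
        for rep in (1, 2)
    ]
    rng = np.random.default_rng(probe_seed(animal, base_seed))
    order = rng.permutation(len(conditions))
    return [conditions[i] for i in order]
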