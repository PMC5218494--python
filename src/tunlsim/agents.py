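"""Simulated rat agents.

Two families drive the system: a deterministic *ideal* agent (instant,
always correct -- used for exact cap and schedule tests) and *stochastic*
agents with latency distributions, a saturating-exponential learning curve,
a separation/delay-dependent psychometric for TUNL choices, and a
circadian-weighted visit process.  The agent model is this package's own;
its default constants are calibrated to the cohort statistics of the
automated-testing study it emulates (choice latency 5 +/- 2.5 s, reward
collection 1 +/- 0.6 s, 88 % of visits in the dark phase, TUNL criterion
reached in roughly 10-19 sessions).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .protocol import DAY, HOUR, MINUTE, SECOND, PhaseId, SessionRecord

# -- parameters --------------------------------------------------------------


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated rat.

    Latencies are (mean, sd) in ms, drawn from a normal truncated at 200 ms.
    ``psychometric_slope`` is the drop in choice accuracy from the maximal
    (3-window) to the adjacent (0-window) separation; ``delay_penalty_per_s``
    the accuracy cost per second of retention delay.  Learning moves the
    context accuracy toward ``p_asymptote`` by a fraction ``learning_rate``
    of the remaining gap per completed session.
    """

    response_latency: tuple[float, float] = (5_000.0, 2_500.0)
    magazine_latency: tuple[float, float] = (1_000.0, 640.0)
    exit_latency: tuple[float, float] = (2.6 * MINUTE, 3.1 * MINUTE)
    p_correct_base: float = 0.5
    p_asymptote: float = 0.92
    learning_rate: float = 0.11
    psychometric_slope: float = 0.20
    delay_penalty_per_s: float = 0.02
    activity_dark: float = 88.0
    activity_light: float = 12.0
    attempt_rate_per_h: float = 9.0     # mean visit-attempt rate
    p_engage: float = 0.95              # P(responding to a trial at all)
    p_tailgate: float = 0.10            # P(following another rat into the tube)
    deterministic: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_correct_base, self.p_asymptote, self.p_engage,
                  self.p_tailgate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.response_latency[0] <= 0 or self.magazine_latency[0] <= 0:
            raise ValueError("latencies must be positive")


def preset(name: str, **overrides) -> AgentParams:
    """Named parameter presets: ``ideal``, ``calibrated``, ``fast``, ``poor``."""
    presets = {
        "ideal": AgentParams(
            response_latency=(1_000.0, 0.0), magazine_latency=(1_000.0, 0.0),
            exit_latency=(1_000.0, 0.0), p_correct_base=1.0, p_asymptote=1.0,
            learning_rate=0.0, psychometric_slope=0.0,
            delay_penalty_per_s=0.0, activity_dark=1.0, activity_light=1.0,
            attempt_rate_per_h=60.0, p_engage=1.0, p_tailgate=0.0,
            deterministic=True),
        "calibrated": AgentParams(),
        # fast learners: high starting accuracy and quick saturation, still
        # stochastic in latencies and visits
        "fast": AgentParams(p_correct_base=0.85, p_asymptote=0.98,
                            learning_rate=0.5, psychometric_slope=0.05,
                            delay_penalty_per_s=0.005, p_engage=1.0,
                            response_latency=(2_000.0, 800.0),
                            exit_latency=(30_000.0, 15_000.0),
                            attempt_rate_per_h=20.0),
        "poor": AgentParams(p_correct_base=0.45, p_asymptote=0.75,
                            learning_rate=0.04, p_engage=0.85),
    }
    if name not in presets:
        raise ValueError(f"unknown agent preset {name!r}")
    base = presets[name]
    return replace(base, **overrides) if overrides else base


# -- state -------------------------------------------------------------------


@dataclass
class AgentState:
    """Mutable per-animal state: learned accuracy per task context and
    current location (transitions only via sorter passage)."""

    animal: str
    params: AgentParams
    rng: np.random.Generator
    p_learned: dict[str, float] = field(default_factory=dict)
    location: str = "home"          # home | tube | chamber

    def __post_init__(self) -> None:
        self.p_learned.setdefault("instrumental", self.params.p_correct_base)
        self.p_learned.setdefault("tunl", self.params.p_correct_base)


def _context(phase: PhaseId) -> str:
    return "tunl" if phase.is_tunl else "instrumental"


def _clamp(p: float, lo: float = 0.02, hi: float = 0.995) -> float:
    return min(hi, max(lo, p))


def choice_accuracy(state: AgentState, separation: int,
                    delay_ms: int) -> float:
    """Closed-form probability of choosing S+ at a given separation and
    delay: learned accuracy minus the psychometric separation and delay
    penalties."""
    pr = state.params
    p = state.p_learned["tunl"] \
        - pr.psychometric_slope * (3 - separation) / 3.0 \
        - pr.delay_penalty_per_s * (delay_ms / SECOND)
    return _clamp(p)


def _latency(state: AgentState, dist: tuple[float, float]) -> int:
    mean, sd = dist
    if state.params.deterministic or sd == 0:
        return int(mean)
    return int(max(200.0, state.rng.normal(mean, sd)))


# -- acting ------------------------------------------------------------------


@dataclass(frozen=True)
class Stim:
    """What the chamber currently shows the agent (from the session driver)."""

    kind: str                                   # magazine|response|choice|collect
    targets: tuple[tuple[int, int], ...] = ()
    all_positions: tuple[tuple[int, int], ...] = ()
    separation: Optional[int] = None
    delay: Optional[int] = None
    phase: Optional[PhaseId] = None


def agent_act(state: AgentState, stimulus: Stim,
              rng: Optional[np.random.Generator] = None
              ) -> tuple[tuple, int]:
    """Decide the agent's next poke for the current stimulus.

    Returns ``(action, latency_ms)`` with action ``("magazine",)`` or
    ``("screen", (row, col))``.  The ideal agent always pokes the correct
    target after its fixed latency; stochastic agents err with the
    psychometric probability and draw latencies from their distributions.
    """
    rng = rng if rng is not None else state.rng
    pr = state.params

    if stimulus.kind in ("magazine", "collect"):
        return ("magazine",), _latency(state, pr.magazine_latency)

    lat = _latency(state, pr.response_latency)
    if stimulus.kind == "choice":
        splus, sminus = stimulus.targets
        if pr.deterministic:
            return ("screen", splus), lat
        p = choice_accuracy(state, stimulus.separation or 0,
                            stimulus.delay or 0)
        pos = splus if rng.random() < p else sminus
        return ("screen", pos), lat

    # "response": one or more lit windows (training phases, TUNL sample)
    target = stimulus.targets[0]
    if pr.deterministic:
        return ("screen", target), lat
    if len(stimulus.targets) > 1:   # all-lit phases: any lit window will do
        target = stimulus.targets[
            int(rng.integers(0, len(stimulus.targets)))]
        return ("screen", target), lat
    phase = stimulus.phase
    if phase in (PhaseId.T4, PhaseId.T5, PhaseId.T6):
        p = _clamp(state.p_learned["instrumental"])
        if rng.random() >= p:
            others = [q for q in stimulus.all_positions if q != target]
            if others:
                pos = others[int(rng.integers(0, len(others)))]
                return ("screen", pos), lat
    return ("screen", target), lat


# -- learning ----------------------------------------------------------------


def agent_learn(state: AgentState, session: SessionRecord) -> AgentState:
    """Per-session saturating-exponential update toward the asymptote:
    p <- p + learning_rate * (asymptote - p) for the session's context."""
    ctx = _context(session.phase)
    pr = state.params
    p = state.p_learned[ctx]
    state.p_learned[ctx] = p + pr.learning_rate * (pr.p_asymptote - p)
    return state


def sessions_to_accuracy(p0: float, asymptote: float, rate: float,
                         target: float) -> int:
    """Closed-form session count for the learning update to reach
    ``target``: the smallest n with asymptote - (asymptote-p0)(1-rate)^n
    >= target."""
    if p0 >= target:
        return 0
    if rate <= 0 or asymptote < target:
        raise ValueError("target accuracy is unreachable")
    ratio = (asymptote - target) / (asymptote - p0)
    return math.ceil(math.log(ratio) / math.log(1.0 - rate))


# -- visit decisions ---------------------------------------------------------


def decide_visit(state: AgentState, now: int, rng: np.random.Generator,
                 light_phase=None) -> int:
    """Time of the agent's next visit attempt (ms, > now).

    Attempts form an inhomogeneous Poisson process whose dark:light
    intensity ratio is ``activity_dark : activity_light`` (thinning against
    the maximal intensity).  With ``light_phase`` None the process is
    homogeneous at the mean rate.
    """
    pr = state.params
    wd, wl = pr.activity_dark, pr.activity_light
    mean_w = (wd + wl) / 2.0
    base = pr.attempt_rate_per_h / HOUR          # events per ms at weight 1
    if light_phase is None or wd == wl:
        lam = base
        return now + max(1, int(rng.exponential(1.0 / lam)))
    lam_max = base * max(wd, wl) / mean_w
    t = now
    while True:
        t += max(1, int(rng.exponential(1.0 / lam_max)))
        w = wd if light_phase(t) == "dark" else wl
        if rng.random() < (base * w / mean_w) / lam_max:
            return t
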