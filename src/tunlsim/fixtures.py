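"""Programmatic test fixtures: small hand-constructed event logs with known
ground truth, used by the test suite and the ``gen-fixtures`` CLI command.

All fixtures are synthetic constructions of this package (no recorded animal
data): a perfect 50-trial Training-3 session, a TUNL session with a known
correction-run structure, and an interleaved two-animal reader stream with a
hand-countable set of visits.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import EventLog
from .protocol import SECOND

FIXTURE_KINDS = ("perfect_t3", "tunl_corrections", "two_animal_readers")


def perfect_t3(seed: int = 0) -> EventLog:
    """One Training-3 session, 50 completed trials: fixed-denominator
    percent correct is exactly 100."""
    log = EventLog()
    t = 0
    log.append(t, "R1", "session_start", phase="T3", session_index=1)
    for i in range(50):
        log.append(t, "R1", "stimulus_on", kind="all")
        t += 3 * SECOND
        log.append(t, "R1", "screen_poke", position="2.3", outcome="correct")
        log.append(t, "R1", "stimulus_off", kind="response")
        log.append(t, "R1", "reward", pellets=1, kind="correct")
        t += 1 * SECOND
        log.append(t, "R1", "magazine_poke", role="collect")
        t += 20 * SECOND
    log.append(t, "R1", "session_end", phase="T3", trials=50,
               terminated_by="trial_cap")
    return log


def tunl_corrections(seed: int = 0) -> EventLog:
    """A short TUNL session with a known outcome sequence.

    Trials: correct, incorrect followed by a 2-run correction (incorrect
    then correct), correct -- i.e. 3 first-presentation choices (2 correct,
    1 incorrect) and 2 correction trials.
    """
    log = EventLog()
    t = 0
    log.append(t, "R2", "session_start", phase="TUNL_ACQ", session_index=1)

    def trial(t: int, correction: bool, outcome: str) -> int:
        log.append(t, "R2", "stimulus_on", kind="magazine")
        t += SECOND
        log.append(t, "R2", "magazine_poke", role="initiate")
        log.append(t, "R2", "stimulus_on", kind="sample", position="1.1")
        t += SECOND
        log.append(t, "R2", "screen_poke", position="1.1", outcome="sample")
        log.append(t, "R2", "stimulus_off", kind="sample")
        t += 2 * SECOND
        log.append(t, "R2", "stimulus_on", kind="magazine")
        t += SECOND
        log.append(t, "R2", "magazine_poke", role="choice_initiate")
        log.append(t, "R2", "stimulus_on", kind="choice", splus="1.5",
                   sminus="1.1", separation=3, delay=2000,
                   correction=int(correction))
        t += 5 * SECOND
        if outcome == "correct":
            log.append(t, "R2", "screen_poke", position="1.5",
                       outcome="correct")
            log.append(t, "R2", "stimulus_off", kind="choice")
            log.append(t, "R2", "reward", pellets=1, kind="correct")
            t += SECOND
            log.append(t, "R2", "magazine_poke", role="collect")
        else:
            log.append(t, "R2", "screen_poke", position="1.1",
                       outcome="incorrect")
            log.append(t, "R2", "stimulus_off", kind="choice")
            log.append(t, "R2", "tone_low")
            t += 5 * SECOND
        return t + 20 * SECOND

    t = trial(t, correction=False, outcome="correct")
    t = trial(t, correction=False, outcome="incorrect")
    t = trial(t, correction=True, outcome="incorrect")
    t = trial(t, correction=True, outcome="correct")
    t = trial(t, correction=False, outcome="correct")
    log.append(t, "R2", "session_end", phase="TUNL_ACQ", trials=5,
               terminated_by="time_cap")
    return log


def two_animal_readers(seed: int = 0) -> EventLog:
    """Interleaved reader streams for two animals.

    Hand count: animal A makes two complete visits (durations 62 s and
    30 s), animal B one complete visit (duration 45 s) plus one aborted
    half-entry that must not produce a visit.
    """
    log = EventLog()
    seq = [
        (0, "A", "R2"), (5_000, "A", "R3"),
        (8_000, "B", "R2"), (12_000, "B", "R3"),
        (57_000, "B", "R3"), (59_000, "B", "R2"),        # B visit: 45 s
        (67_000, "A", "R3"), (69_000, "A", "R2"),        # A visit 1: 62 s
        (80_000, "B", "R2"), (84_000, "B", "R2"),        # B aborted entry
        (100_000, "A", "R2"), (103_000, "A", "R3"),
        (133_000, "A", "R3"), (135_000, "A", "R2"),      # A visit 2: 30 s
    ]
    for t, animal, reader in seq:
        log.append(t, animal, "reader_detect", reader=reader)
    return log


def gen_fixtures(kind: str, seed: int = 0, outdir: str | Path = ".") -> Path:
    """Write one fixture log as CSV; returns the written path."""
    from .io import write_event_log

    builders = {"perfect_t3": perfect_t3,
                "tunl_corrections": tunl_corrections,
                "two_animal_readers": two_animal_readers}
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    log = builders[kind](seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / f"{kind}.csv"
    write_event_log(log, out)
    return out
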