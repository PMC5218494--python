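"""Sorter FSM, visit reconstruction and the access policy."""
import pytest

from tunlsim.protocol import DAY, HOUR, MINUTE, PhaseId, SECOND, SessionRecord
from tunlsim.sorter import (
    AccessPolicy, ChamberEntered, HoldExpired, HomeArrived, ReaderEvent,
    SessionEnded, SorterState, access_allowed, detect_visits,
    earliest_allowed, intersession_interval, min_days_for_sessions,
    sorter_step,
)


def holding_state(animal="A"):
    st = SorterState()
    sorter_step(st, ReaderEvent("R1", animal, 0), policy_verdict=True, now=0)
    sorter_step(st, ReaderEvent("R2", animal, 2_000), now=2_000)
    st, acts = sorter_step(st, ReaderEvent("R3", animal, 3_000), now=3_000)
    assert st.mode == "holding"
    return st, acts


class TestSorterFsm:
    def test_admission_sequence(self):
        st = SorterState()
        st, acts = sorter_step(st, ReaderEvent("R1", "A", 0),
                               policy_verdict=True)
        assert st.mode == "admitting" and ("gate_open", "G1") in acts
        st, acts = holding_state()
        assert ("gate_close", "G1") in acts
        assert any(a[0] == "start_hold_timer" for a in acts)
        assert st.gate1 == "closed" and st.gate2 == "closed"

    def test_denied_admission_is_noop(self):
        st = SorterState()
        st, acts = sorter_step(st, ReaderEvent("R1", "A", 0),
                               policy_verdict=False)
        assert st.mode == "idle" and acts == []

    def test_second_animal_during_hold_aborts(self):
        """Detection of a second animal at R2 during the 30 s hold aborts
        the sequence and reopens Gate 1."""
        st, _ = holding_state("A")
        st, acts = sorter_step(st, ReaderEvent("R2", "B", 10_000), now=10_000)
        assert st.mode == "aborting"
        assert ("gate_open", "G1") in acts
        assert any(a[0] == "sort_abort" for a in acts)

    def test_hold_expiry_with_single_animal_passes(self):
        st, acts = holding_state("A")
        adm = next(a for a in acts if a[0] == "start_hold_timer")[2]
        st, acts = sorter_step(st, HoldExpired(adm), now=33_000)
        assert st.mode == "passing"
        assert ("gate_open", "G2") in acts
        assert ("admitted", "A") in acts

    def test_stale_hold_timer_ignored(self):
        st, acts = holding_state("A")
        adm = next(a for a in acts if a[0] == "start_hold_timer")[2]
        sorter_step(st, ReaderEvent("R3", "B", 5_000), now=5_000)  # abort
        st, acts = sorter_step(st, HoldExpired(adm), now=33_000)
        assert st.mode == "aborting" and acts == []

    def test_no_lockout_after_abort(self):
        """Gate 1 stays open until every tube animal is home again; the
        sorter then returns to idle."""
        st, _ = holding_state("A")
        sorter_step(st, ReaderEvent("R2", "B", 5_000), now=5_000)
        assert st.gate1 == "open"
        sorter_step(st, HomeArrived("A"), now=8_000)
        assert st.gate1 == "open"          # B still inside
        st, _ = sorter_step(st, HomeArrived("B"), now=9_000)
        assert st.mode == "idle" and st.gate1 == "closed"

    def test_exit_sequence_gate2_then_gate1(self):
        st, acts = holding_state("A")
        adm = next(a for a in acts if a[0] == "start_hold_timer")[2]
        sorter_step(st, HoldExpired(adm), now=33_000)
        sorter_step(st, ChamberEntered("A"), now=34_000)
        assert st.chamber_occupant == "A" and st.mode == "idle"
        st, acts = sorter_step(st, SessionEnded("A"), now=100_000)
        assert ("gate_open", "G2") in acts
        st, acts = sorter_step(st, ReaderEvent("R3", "A", 101_000),
                               now=101_000)
        assert ("gate_close", "G2") in acts and ("gate_open", "G1") in acts
        st, _ = sorter_step(st, HomeArrived("A"), now=103_000)
        assert st.chamber_occupant is None and st.mode == "idle"

    def test_unknown_animal_rejected(self):
        st = SorterState(cohort=frozenset({"A", "B"}))
        with pytest.raises(ValueError):
            sorter_step(st, ReaderEvent("R1", "X", 0), policy_verdict=True)

    def test_idle_ignores_stray_events(self):
        st = SorterState()
        st, acts = sorter_step(st, ReaderEvent("R3", "A", 0))
        assert st.mode == "idle" and acts == []


class TestVisits:
    def test_printed_rule_example(self):
        """R2 then two R3 detections at 5 s and 67 s: one 62 s visit."""
        events = [ReaderEvent("R2", "A", 0), ReaderEvent("R3", "A", 5_000),
                  ReaderEvent("R3", "A", 67_000)]
        visits = detect_visits(events)
        assert len(visits) == 1
        assert visits[0].duration == 62_000

    def test_incomplete_pattern_is_discarded(self):
        assert detect_visits([ReaderEvent("R2", "A", 0)]) == []
        assert detect_visits([ReaderEvent("R2", "A", 0),
                              ReaderEvent("R3", "A", 5_000)]) == []

    def test_interleaving_matches_per_animal_processing(self, rng):
        """Brute-force oracle: filtering each animal's stream first gives
        the same visits as the interleaved stream."""
        events = []
        t = 0
        for _ in range(200):
            t += int(rng.integers(1_500, 10_000))
            animal = ["A", "B", "C"][int(rng.integers(0, 3))]
            reader = ["R2", "R3"][int(rng.integers(0, 2))]
            events.append(ReaderEvent(reader, animal, t))
        merged = detect_visits(events)
        split = []
        for a in "ABC":
            split.extend(detect_visits([e for e in events if e.animal == a]))
        assert sorted(merged, key=lambda v: (v.enter_time, v.animal)) == \
            sorted(split, key=lambda v: (v.enter_time, v.animal))

    def test_debounced_chatter(self):
        events = [ReaderEvent("R2", "A", 0), ReaderEvent("R2", "A", 300),
                  ReaderEvent("R3", "A", 5_000),
                  ReaderEvent("R3", "A", 5_400),
                  ReaderEvent("R3", "A", 67_000)]
        visits = detect_visits(events)
        assert len(visits) == 1 and visits[0].duration == 62_000

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError):
            detect_visits([ReaderEvent("R2", "A", 5), ReaderEvent("R3", "A", 1)])


def past_session(start, end, phase=PhaseId.T3):
    return SessionRecord(animal="A", phase=phase, start=start, end=end,
                         sorter_exit=end)


class TestAccessPolicy:
    def test_interval_not_yet_elapsed(self):
        policy = AccessPolicy(intersession_interval=int(2.5 * HOUR))
        hist = [past_session(0, HOUR)]
        now = HOUR + int(2.4 * HOUR)
        assert not access_allowed("A", now, policy, hist)
        assert access_allowed("A", HOUR + int(2.5 * HOUR), policy, hist)

    def test_first_session_allowed(self):
        assert access_allowed("A", 0, AccessPolicy(), [])

    def test_chamber_occupied_blocks(self):
        assert not access_allowed("A", 0, AccessPolicy(), [],
                                  chamber_occupant="B")

    def test_tunl_two_per_24h_cap(self):
        policy = AccessPolicy(intersession_interval=7 * HOUR,
                              max_sessions_per_24h=2)
        hist = [past_session(0, HOUR, PhaseId.TUNL_ACQ),
                past_session(8 * HOUR, 9 * HOUR, PhaseId.TUNL_ACQ)]
        assert not access_allowed("A", 16 * HOUR, policy, hist)
        assert access_allowed("A", DAY + 1, policy, hist)

    def test_late_learner_window(self):
        policy = AccessPolicy(late_learner_window=(
            frozenset({"B", "C"}), 0, 4 * HOUR))
        assert not access_allowed("A", HOUR, policy, [])
        assert access_allowed("B", HOUR, policy, [])
        assert access_allowed("A", 5 * HOUR, policy, [])

    def test_earliest_allowed_respects_cap(self):
        policy = AccessPolicy(intersession_interval=7 * HOUR,
                              max_sessions_per_24h=2)
        hist = [past_session(0, HOUR), past_session(8 * HOUR, 9 * HOUR)]
        t = earliest_allowed("A", 16 * HOUR, policy, hist)
        assert t == DAY


class TestScheduleArithmetic:
    def test_printed_interval_formulas(self):
        """30 min x 5 remaining rats = 2.5 h; 1 h x 5 + 2 h margin = 7 h."""
        assert intersession_interval(30 * MINUTE, 6, 0) == int(2.5 * HOUR)
        assert intersession_interval(HOUR, 6, 2 * HOUR) == 7 * HOUR
        assert intersession_interval(10 * MINUTE, 1, 0) == 0

    def test_twenty_tunl_sessions_take_ten_days(self):
        policy = AccessPolicy(intersession_interval=7 * HOUR,
                              max_sessions_per_24h=2)
        days = min_days_for_sessions(20, HOUR, policy)
        import math
        assert math.ceil(days) == 10
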