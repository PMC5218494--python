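"""Phase configurations, performance formulas, acquisition criteria and the
constrained pseudo-random samplers."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tunlsim.protocol import (
    DAY, HOUR, MINUTE, SECOND,
    CriterionSpec, PhaseId, SessionRecord, TrialRecord, WindowGrid,
    criterion_met, draw_tunl_pair, interference_config, pct_active,
    pct_correct_fixed_denominator, pct_correct_ratio, phase_config,
    probe_schedule, sample_separation_block,
)


def make_session(phase, kinds, start=0, duration=10 * MINUTE, animal="A"):
    trials = [TrialRecord(animal=animal, phase=phase, index_in_session=i + 1,
                          kind=k, start=start, end=start + duration)
              for i, k in enumerate(kinds)]
    return SessionRecord(animal=animal, phase=phase, start=start,
                         end=start + duration, trials=trials,
                         sorter_exit=start + duration)


class TestPhaseConfig:
    def test_published_parameters(self):
        t2 = phase_config(PhaseId.T2)
        assert t2.max_trials == 17
        assert t2.max_session_duration == 10 * MINUTE
        assert t2.iti == 20 * SECOND
        assert t2.passive_timer == 30 * SECOND
        assert t2.reward_active == 2 and t2.reward_passive == 1
        assert t2.intersession_interval == 30 * MINUTE

        for p in (PhaseId.T3, PhaseId.T4, PhaseId.T5, PhaseId.T6):
            cfg = phase_config(p)
            assert cfg.max_trials == 50
            assert cfg.max_session_duration == 30 * MINUTE
            assert cfg.intersession_interval == int(2.5 * HOUR)
        assert phase_config(PhaseId.T6).timeout_on_error == 5 * SECOND

        tunl = phase_config(PhaseId.TUNL_ACQ)
        assert tunl.max_trials == 84
        assert tunl.max_session_duration == 60 * MINUTE
        assert tunl.sample_choice_delay == 2 * SECOND
        assert tunl.intersession_interval == 7 * HOUR
        assert tunl.max_sessions_per_24h == 2
        assert tunl.sample_reward_prob == pytest.approx(1 / 3)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            phase_config("T99")

    def test_overrides(self):
        cfg = phase_config(PhaseId.TUNL_ACQ, max_trials=10)
        assert cfg.max_trials == 10
        # defaults untouched
        assert phase_config(PhaseId.TUNL_ACQ).max_trials == 84

    def test_interference_config(self):
        cfg = interference_config()
        assert cfg.iti == 5 * SECOND
        assert cfg.sample_choice_delay == 2 * SECOND
        assert cfg.separation_class == "large"


class TestPerformanceFormulas:
    def test_pct_active(self):
        s = make_session(PhaseId.T2, ["active"] * 17)
        assert pct_active(s) == 100.0
        s = make_session(PhaseId.T2, ["active"] * 10 + ["passive"] * 10)
        assert pct_active(s) == 50.0

    def test_pct_active_empty_session_flagged(self):
        s = make_session(PhaseId.T2, [])
        with pytest.raises(ValueError):
            pct_active(s)

    def test_fixed_denominator(self):
        assert pct_correct_fixed_denominator(
            make_session(PhaseId.T3, ["correct"] * 50)) == 100.0
        assert pct_correct_fixed_denominator(
            make_session(PhaseId.T4, ["correct"] * 25)) == 50.0
        with pytest.raises(ValueError):
            pct_correct_fixed_denominator(
                make_session(PhaseId.T3, ["correct"] * 51))

    def test_fixed_denominator_monotone(self):
        vals = [pct_correct_fixed_denominator(
            make_session(PhaseId.T5, ["correct"] * n)) for n in range(51)]
        assert vals == sorted(vals)

    def test_ratio(self):
        s = make_session(PhaseId.T6, ["correct"] * 40 + ["incorrect"] * 10)
        assert pct_correct_ratio(s) == 80.0
        s = make_session(PhaseId.T6, ["correct"] * 5)
        assert pct_correct_ratio(s) == 100.0
        s = make_session(PhaseId.TUNL_ACQ, ["correct", "incorrect"] * 42)
        assert pct_correct_ratio(s) == 50.0

    def test_ratio_reorder_invariant(self, rng):
        kinds = ["correct"] * 30 + ["incorrect"] * 12
        base = pct_correct_ratio(make_session(PhaseId.TUNL_ACQ, kinds))
        for _ in range(5):
            rng.shuffle(kinds)
            assert pct_correct_ratio(
                make_session(PhaseId.TUNL_ACQ, kinds)) == base

    def test_correction_switch(self):
        kinds = ["correct"] * 7 + ["incorrect"] * 3 + \
            ["correction_incorrect", "correction_correct"] * 3
        s = make_session(PhaseId.TUNL_ACQ, kinds)
        assert pct_correct_ratio(s) == 70.0
        assert pct_correct_ratio(s, count_corrections=True) == \
            pytest.approx(100.0 * 10 / 16)


class TestCriteria:
    def test_t2_two_sessions(self):
        one = make_session(PhaseId.T2, ["active"] * 17)
        assert not criterion_met(PhaseId.T2, [one])
        two = make_session(PhaseId.T2, ["active"] * 10 + ["passive"] * 7,
                           start=HOUR)
        assert criterion_met(PhaseId.T2, [one, two])

    def test_t3_within_24h(self):
        a = make_session(PhaseId.T3, ["correct"] * 50, start=0)
        b = make_session(PhaseId.T3, ["correct"] * 50, start=25 * HOUR)
        c = make_session(PhaseId.T3, ["correct"] * 50, start=30 * HOUR)
        assert not criterion_met(PhaseId.T3, [a, b])
        assert criterion_met(PhaseId.T3, [a, b, c])

    def test_t4_consecutive_vs_t5_any_two(self):
        good = ["correct"] * 50
        poor = ["correct"] * 30
        hist4 = [make_session(PhaseId.T4, k, start=i * 3 * HOUR)
                 for i, k in enumerate([good, poor, good])]
        assert not criterion_met(PhaseId.T4, hist4)
        hist5 = [make_session(PhaseId.T5, k, start=i * 3 * HOUR)
                 for i, k in enumerate([good, poor, good])]
        assert criterion_met(PhaseId.T5, hist5)

    def test_t6_needs_80_pct(self):
        barely = ["correct"] * 40 + ["incorrect"] * 10   # 80 %, 50 trials
        below = ["correct"] * 39 + ["incorrect"] * 11    # 78 %
        assert criterion_met(PhaseId.T6, [
            make_session(PhaseId.T6, barely, start=i * 3 * HOUR)
            for i in range(2)])
        assert not criterion_met(PhaseId.T6, [
            make_session(PhaseId.T6, below, start=0),
            make_session(PhaseId.T6, barely, start=3 * HOUR)])

    def test_tunl_session_floor(self):
        """Graduation requires at least 20 sessions even when performance is
        at ceiling throughout."""
        perfect = ["correct"] * 60 + ["incorrect"] * 10   # 85.7 %
        hist = [make_session(PhaseId.TUNL_ACQ, perfect, start=i * 8 * HOUR)
                for i in range(19)]
        assert not criterion_met(PhaseId.TUNL_ACQ, hist)
        hist.append(make_session(PhaseId.TUNL_ACQ, perfect,
                                 start=19 * 8 * HOUR))
        assert criterion_met(PhaseId.TUNL_ACQ, hist)

    def test_minimal_sessions_ideal_agent(self):
        """A deterministic always-correct agent graduates each phase after
        exactly the minimal session count."""
        perfect = {
            PhaseId.T2: ["active"] * 17,
            PhaseId.T3: ["correct"] * 50,
            PhaseId.T4: ["correct"] * 50,
            PhaseId.T5: ["correct"] * 50,
            PhaseId.T6: ["correct"] * 50,
            PhaseId.TUNL_ACQ: ["correct"] * 84,
        }
        minimal = {PhaseId.T2: 2, PhaseId.T3: 2, PhaseId.T4: 2,
                   PhaseId.T5: 2, PhaseId.T6: 2, PhaseId.TUNL_ACQ: 20}
        for phase, n_min in minimal.items():
            hist = []
            for i in range(n_min):
                assert not criterion_met(phase, hist), (phase, i)
                hist.append(make_session(phase, perfect[phase],
                                         start=i * 8 * HOUR))
            assert criterion_met(phase, hist), phase

    def test_foreign_phase_rejected(self):
        hist = [make_session(PhaseId.T3, ["correct"] * 50)]
        with pytest.raises(ValueError):
            criterion_met(PhaseId.T4, hist)


class TestSeparationBlocks:
    def test_forced_multiset_at_minimum_length(self, rng):
        block = sample_separation_block(rng, block_len=8)
        assert sorted(block) == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_separation_block(rng, block_len=7)

    @given(seed=st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=300, deadline=None)
    def test_each_separation_at_least_twice(self, seed):
        block = sample_separation_block(np.random.default_rng(seed))
        assert len(block) == 20
        for v in range(4):
            assert block.count(v) >= 2

    def test_count_distribution_matches_construction(self, rng):
        """The count of any one value is 2 + Binomial(12, 1/4): Monte-Carlo
        frequencies match the exact pmf of the free draws."""
        from scipy.stats import binom
        n_blocks = 10_000
        counts = np.array([sample_separation_block(rng).count(0)
                           for _ in range(n_blocks)])
        assert counts.mean() == pytest.approx(5.0, abs=0.1)
        ks = np.arange(2, 15)
        exact = binom.pmf(ks - 2, 12, 0.25)
        emp = np.array([(counts == k).mean() for k in ks])
        assert np.max(np.abs(emp - exact)) < 0.02


class TestTunlPairs:
    def test_maximal_separation_forces_outer_columns(self, rng):
        for _ in range(50):
            spec = draw_tunl_pair(rng, 3)
            assert {spec.splus_loc[1], spec.sminus_loc[1]} == {1, 5}

    def test_adjacent_means_columns_differ_by_one(self, rng):
        for _ in range(50):
            spec = draw_tunl_pair(rng, 0)
            assert abs(spec.splus_loc[1] - spec.sminus_loc[1]) == 1

    def test_unattainable_separation_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_tunl_pair(rng, 4)

    @given(seed=st.integers(0, 2 ** 31 - 1), sep=st.integers(0, 3))
    @settings(max_examples=200, deadline=None)
    def test_type_invariants(self, seed, sep):
        spec = draw_tunl_pair(np.random.default_rng(seed), sep)
        assert spec.splus_loc != spec.sminus_loc
        assert spec.splus_loc[0] == spec.sminus_loc[0]
        assert spec.sample_loc == spec.sminus_loc
        assert abs(spec.splus_loc[1] - spec.sminus_loc[1]) - 1 == sep

    def test_uniform_over_pairs_at_fixed_separation(self, rng):
        """Chi-square of 10,000 draws at separation 1 against the
        enumeration oracle: 3 rows x 3 column pairs x 2 role assignments,
        all equally likely."""
        from scipy.stats import chisquare
        grid = WindowGrid()
        combos = {}
        n = 10_000
        for _ in range(n):
            s = draw_tunl_pair(rng, 1, grid)
            combos[(s.splus_loc, s.sminus_loc)] = \
                combos.get((s.splus_loc, s.sminus_loc), 0) + 1
        # enumeration: rows 1-3, left columns 1-3, two role assignments
        assert len(combos) == 3 * 3 * 2
        stat, p = chisquare(list(combos.values()))
        assert p > 0.001


class TestProbeSchedule:
    def test_twelve_sessions(self):
        sched = probe_schedule("R1")
        assert len(sched) == 12

    def test_every_condition_twice(self):
        sched = probe_schedule("R2", base_seed=4)
        counts = {}
        for cond, rep in sched:
            key = (cond.separation_class, cond.delay)
            counts[key] = counts.get(key, 0) + 1
        assert counts == {(c, d): 2 for c in ("small", "medium", "large")
                          for d in (2 * SECOND, 6 * SECOND)}

    def test_per_animal_deterministic_order(self):
        assert probe_schedule("R3", 1) == probe_schedule("R3", 1)
        assert probe_schedule("R3", 1) != probe_schedule("R4", 1)
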