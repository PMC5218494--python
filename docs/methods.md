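# Methods

## The system being modelled

The simulator reproduces, as a discrete-event system, an automated operant
testing rig in which six group-housed rats share one touchscreen chamber
reached through an RFID sorting tube. Three processes are coupled on a
single event queue with integer-millisecond time:

1. **Sorter finite-state machine.** States idle → admitting → holding →
   passing (and aborting). An animal identified at reader R1 is admitted
   (Gate 1 opens) only when the chamber is empty and its access policy
   allows; detection at R2 and R3 closes Gate 1 and starts a 30 s hold with
   both gates shut; any second animal detected at R2/R3 during the hold
   aborts the sequence and reopens Gate 1 so all tube animals can return
   home; a solitary animal passes through Gate 2 into the chamber. The exit
   choreography after a session is Gate 2 → tube → Gate 1 → home. Repeated
   same-reader detections within 1 s are coalesced (hardware debounce).
2. **Trial automata.** Each curriculum phase is a small state machine over
   screen pokes, magazine pokes and named timers. Events illegal in the
   current state are logged and ignored — the tolerance real control
   software needs against reader/beam chatter. Reward contingencies per
   phase: 2 pellets per active touch and 1 per passive timeout in the two
   habituation phases; 1 pellet per completed trial thereafter; in TUNL, a
   Bernoulli(1/3) pellet on sample completion and 1 pellet per correct
   choice. Errors in Training 6 and TUNL trigger a 0.5 s low tone and a
   5 s houselight timeout; TUNL errors additionally queue correction
   trials that re-present the identical stimulus pair until solved.
3. **Agents.** Simulated rats decide when to attempt a visit, what to poke
   and how fast, and improve with practice (below).

A session belongs to exactly one animal (Training 1 excepted), starts when
the sorter passes it into the chamber, and ends at the phase's trial cap or
session clock; a trial in flight at the clock finishes before the session
ends (no truncated trials). Everything observable is appended to a single
time-ordered event log with a closed vocabulary; all analyses consume that
log.

## Curriculum and criteria

Phase defaults (all overridable in the run configuration):

| phase | caps | ITI | special | interval | criterion |
|---|---|---|---|---|---|
| T1 | 24 h open sorter | 30 s | passive pellet after 15 min | — | — |
| T2 | 17 trials / 10 min | 20 s | passive pellet after 30 s | 30 min | 17 trials × 2 sessions |
| T3 | 50 / 30 min | 20 s | must touch, stimulus persists | 2.5 h | 50 × 2 sessions within 24 h |
| T4 | 50 / 30 min | 20 s | single lit window | 2.5 h | 50 × 2 consecutive |
| T5 | 50 / 30 min | 20 s | magazine-poke initiation | 2.5 h | 50 × 2 sessions |
| T6 | 50 / 30 min | 20 s | 5 s timeout on error | 2.5 h | 50 trials and ≥ 80 % × 2 consecutive |
| TUNL | 84 / 60 min | 20 s | 2 s delay, 2 sessions/24 h | 7 h | ≥ 70 % × 2 consecutive, ≥ 20 sessions |

The 2.5 h and 7 h intervals instantiate the formula *session duration ×
(group size − 1) + margin* (30 min × 5 = 2.5 h; 1 h × 5 + 2 h = 7 h),
exposed as `intersession_interval()`. Probe sessions cross the separation
classes small {0}, medium {1, 2} and large {3} with 2 s and 6 s delays,
each condition twice → 12 sessions per animal in a per-animal seeded random
order; the interference variant shortens the ITI to 5 s at large separation
and 2 s delay.

Design choices where the protocol text is open:

* **Correction trials and "% correct (all trials)".** The default excludes
  correction trials from both numerator and denominator (the standard TUNL
  convention); `count_corrections` includes them. The criterion evaluator
  honours the same switch.
* **Choice stimuli share a row.** "Separated by 0–3 windows" is only
  well-defined along a row of the 3 × 5 mask; the row is chosen uniformly.
* **"Within two sessions" (T5)** is read as *any* two passing sessions,
  versus T4's explicit *consecutive* pair — treated as written.
* **Late-learner windows.** When an animal passes a phase criterion while
  at least half the group has not, chamber access is restricted to the
  not-yet-passed animals for 4 h (configurable), mirroring how the rig
  lets stragglers catch up. Animals that pass always advance immediately;
  only chamber access is gated.
* **Training 1** is one 24 h group session with the sorter open; trials
  are attributed to whichever animal pokes. The analysis reports it as a
  group (SYSTEM) session because individual attribution of trial ownership
  is not defined in an open chamber.
* **Probe "medium" sessions** fix one separation (1 or 2) drawn at session
  start, since delay and distance are constant within a probe session.
* **The pre-loaded magazine pellet** at the start of T5/TUNL sessions is
  modelled as already present, not dispensed, so pellet bookkeeping equals
  exactly what trial outcomes prescribe.

## Agent model

The agent model is this package's own construction — the physical system
has none — with defaults calibrated to the behaviour of a trained cohort on
such a rig:

| parameter | default | unit | rationale |
|---|---|---|---|
| response latency | 5 000 ± 2 500 | ms | choice latency of trained rats |
| magazine latency | 1 000 ± 640 | ms | reward-collection latency |
| exit latency | 2.6 ± 3.1 | min | post-session exit behaviour |
| p_correct_base | 0.5 | — | chance on a two-alternative choice |
| p_asymptote / learning rate | 0.92 / 0.11 | per session | 70 % criterion reached in ≈ 14 sessions on the blocked separation mix |
| psychometric slope | 0.20 | accuracy drop, sep 3 → 0 | probe gradient between maximal and adjacent separations |
| delay penalty | 0.02 | per s | 2 s vs 6 s probe difference |
| activity dark : light | 88 : 12 | intensity ratio | fraction of visits in the dark phase |
| attempt rate | 9 | per h | ~200 visit attempts per 24 h |
| p_engage | 0.95 | — | occasional passive/slow trials |

Latencies are normal, truncated at 200 ms. Learning is a per-session
saturating exponential p ← p + λ(p∞ − p), tracked separately for the
instrumental (T2–T6) and TUNL contexts; `sessions_to_accuracy` gives the
closed form. Choice accuracy is linear in probability,
P(S+) = p − slope·(3 − sep)/3 − penalty·delay, clamped to [0.02, 0.995] —
linear by design so that psychometric recovery (weighted least squares on
per-condition accuracies, `fit_psychometric`) is exactly specified.
Visit attempts form an inhomogeneous Poisson process simulated by thinning
against the maximal intensity. The `ideal` preset is fully deterministic
(1 s latencies, always correct) and anchors the exact tests; `fast` and
`poor` bracket the calibrated learner. During an admission, a cage-mate
follows through the open Gate 1 with probability 0.05, which is what makes
sorting aborts occur at a realistic, low rate.

Seeding: one `numpy` `SeedSequence` per run spawns one named stream per
animal plus one environment stream, so runs are reproducible event-for-event
(byte-identical serialized logs) and single-animal trajectories do not
perturb each other.

## What the generator does and does not emulate

The simulator reproduces the *contingency structure* of the rig — gating,
caps, intervals, criteria, stimulus scheduling, reward logic — and produces
cohort statistics (visit counts, dark-phase fractions, latencies,
acquisition trajectories) in the plausible range of a real cohort. It does
not model: individual differences beyond parameter presets, satiety
dynamics, social facilitation during habituation (visits are independent
point processes), motor noise in poke placement, or hardware failures
beyond reader chatter. Tests passing on simulated logs therefore certify
the protocol logic and the analysis pipeline, not predictions about any
particular animal's behaviour.

## Numerical and statistical choices

* **Time** is integer milliseconds; all published durations convert
  exactly. Event ordering is (timestamp, sequence number), FIFO among
  simultaneous events.
* **Separation blocks** are built as a forced multiset (two of each
  distance, 8 slots) plus 12 uniform draws, then one shuffle — the
  at-least-twice constraint holds deterministically, with no rejection
  loop; the per-distance count is 2 + Binomial(12, ¼).
* **Nonparametric tests** use mid-ranks throughout; zero differences are
  dropped in the signed-rank test (Wilcoxon's original treatment). Exact
  null distributions are used for n ≤ 25 (signed-rank, by
  generating-function convolution over doubled ranks, so ties are exact
  too), n + m ≤ 20 (Mann-Whitney, by enumeration of labelings) and on
  request for Friedman (enumeration of within-row orderings); otherwise
  tie-corrected normal / chi-square approximations with continuity
  correction. Two-sided exact p is twice the smaller tail, clamped at 1.
  The published critical-value convention for the signed-rank table
  (reject when W falls *below* the tabulated value) is exposed by
  `signed_rank_critical_check`; for n = 12 the one-sided 0.025 entry is 14
  because P(W ≤ 13) = 87/4096 ≤ 0.025 < P(W ≤ 14) = 107/4096.
* **Quartile-overlap screening** before pairwise tests is reported as a
  flag (`quartile_overlap`), never silently enforced.
* **Bonferroni** m defaults to the number of p-values and is overridable
  (a full two-group battery compares 45 parameters).
* **Probe batteries** for parameter recovery run back-to-back on the
  session simulator; the 7 h / twice-daily access schedule changes only
  wall-clock spacing, not the within-session trial stream.

## Problem sizes

Exact checks run single sessions (17- and 84-trial caps) and closed-form
schedules. Property suites use 10 000 seeds for separation blocks and
10 000 draws for pair-uniformity chi-squares. Cohort invariants are
asserted on a 6-agent, 3-simulated-day randomized run (~50 000 events) and
curriculum feasibility on a 6-agent ideal run over the full T1–T6
curriculum; parameter recovery uses 12 agents × 12 probe sessions
(~7 000 scored choices). These sizes give Monte-Carlo error comfortably
below the asserted tolerances while keeping the whole suite under ten
seconds.

## Known limitations

* The sorter models the documented control sequence; undocumented corner
  cases (e.g. an animal retreating mid-admission before reaching R2) are
  resolved the simplest way: the admission times out only via the abort
  path, and re-admission always requires a fresh R1 detection.
* Training 1 visit dwell times are drawn from fixed dark/light
  distributions rather than emerging from a foraging model.
* The analysis attributes TUNL correction-trial *outcomes* to the log's
  choice-presentation flags; exotic hand-written logs that interleave
  events out of protocol order may parse differently than the simulator's
  own output (the strict validator catches malformed streams).
* `run_simulation` returns both the log and the simulator's own session
  records; analyses are deliberately computed from the log alone, and the
  test suite cross-checks the two.
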