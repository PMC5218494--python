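# tunlsim

A discrete-event simulator of **experimenter-free operant cognitive testing
of group-housed rats**: an RFID animal sorter couples a shared home cage to
a single Bussey-Saksida-style touchscreen chamber, and self-motivated
animals train themselves — with no human intervention — through a six-phase
shaping curriculum into the **trial-unique non-matching to location (TUNL)**
spatial working-memory task.

The package is for behavioural neuroscientists and tool builders who want
to reason about such automated-testing systems without hardware or animals:
to audit the gating logic that guarantees single occupancy of the chamber,
to explore how inter-session intervals, trial caps and session caps shape
cohort throughput, and to exercise the full analysis pipeline (session
metrics, visit statistics, nonparametric tests) on logs with known ground
truth.

## What is simulated

* **Sorter** — a tube with two guillotine gates (G1, G2) and three RFID
  readers (R1–R3). An identified animal is admitted through G1, held 30 s
  with both gates closed, and passed through G2 only if alone; a second
  animal detected at R2/R3 during the hold aborts the sequence and reopens
  G1. A visit is the reader pattern R2 → R3 → R3; its duration is the time
  between the two R3 detections.
* **Curriculum** — Training 1 (24 h open-sorter habituation, all 15
  windows lit, 2 pellets per touch, 1 pellet after a 15-min passive
  timeout), Training 2 (17 trials / 10 min, 30 s passive fallback, 30 min
  inter-session interval), Trainings 3–6 (50 trials / 30 min, 2.5 h
  interval; T4 single lit window, T5 magazine-poke initiation, T6 a 0.5 s
  low tone + 5 s houselight timeout for errors), then TUNL acquisition
  (84 trials / 60 min, 2 s sample–choice delay, 7 h interval, at most two
  sessions per 24 h, minimum 20 sessions), probe sessions (separation
  classes small/medium/large × 2 s and 6 s delays, 12 sessions per animal)
  and an interference variant (ITI 5 s).
* **TUNL trial** — magazine poke → sample window → delay → magazine poke →
  choice between the novel rewarded location S+ and the previous sample
  location S−, separated by 0–3 windows on one row; errors trigger
  correction trials that re-present the identical pair until solved.
  Separations are scheduled so each of {0,1,2,3} appears at least twice in
  every 20-trial block (forced multiset + shuffle, no rejection sampling).
* **Agents** — an *ideal* deterministic agent (1 s latencies, always
  correct; used for exact cap and schedule checks) and stochastic agents
  with latency distributions, a saturating-exponential learning curve
  p ← p + λ(p∞ − p) per session, a psychometric choice rule
  P(S+) = p − slope·(3 − sep)/3 − penalty·delay, and a circadian visit
  process with a dark:light intensity ratio of 88:12.
* **Analysis** — per-session measured parameters (percent active /
  fixed-denominator / ratio percent correct, correction trials, choice,
  reward and exit latencies), blocks-of-five summaries, visit statistics,
  and the nonparametric battery: Friedman, Wilcoxon signed-rank and
  Mann-Whitney U with mid-ranks, exact small-sample null distributions and
  Bonferroni correction.

## Worked example

```python
import tunlsim as ts

cfg = ts.SimConfig(seed=42, duration=2 * ts.DAY,
                   curriculum=(ts.PhaseId.T1, ts.PhaseId.T2, ts.PhaseId.T3))
log, result = ts.run_simulation(cfg, "calibrated")
metrics = ts.session_metrics(log)
print(metrics.groupby("phase")
             .agg(sessions=("pct", "size"), mean_pct=("pct", "mean"),
                  mean_trials=("trials", "mean"))
             .round(1))
visits = ts.visit_stats(log)
print(f"\nmean visits/24h: {visits['visits_per_24h'].mean():.0f}, "
      f"dark fraction: {visits['dark_fraction'].mean():.2f}")
```

prints

```
       sessions  mean_pct  mean_trials
phase
T1            1      99.7       1369.0
T2           14      94.1         16.9
T3           15      99.6         49.8

mean visits/24h: 104, dark fraction: 0.88
```

Reading: the six-rat cohort made 1369 group trials during the open-sorter
habituation day (virtually all by active screen touch); every rat then
cleared the 17-trial Training-2 criterion (mean 94 % active trials) and
moved into Training 3 within the two simulated days, with 88 % of chamber
visits in the dark phase. The event log (`ts.write_event_log`) is a flat
CSV that the `tunlsim analyze` / `tunlsim validate` CLI commands consume.

## Command-line interface

```
tunlsim simulate --config run.toml --seed 1 --out log.csv   # + provenance JSON
tunlsim analyze  --log log.csv --out results/run             # sessions/blocks/visits CSVs
tunlsim validate --log log.csv                               # strict log checks
tunlsim gen-fixtures --kind perfect_t3 --outdir fixtures/    # canned test logs
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
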