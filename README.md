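# attnbattery

A deterministic, headless-testable battery of visuomotor attention tasks
with synthetic agents and a psychometric analysis toolkit:

- **MOA** (Multiple Object Avoidance): a pointer-controlled disc must avoid
  an accumulating set of bouncing hazard discs on an 800×800 px playfield.
  Hazards appear unfilled (non-collidable) for a 1 s grace period, a new
  hazard is added every 10 s, speeds are uniform on 0–680 px/s, and the
  clock runs at 85 Hz. The score is survival time in seconds; a session is
  2 practice + 8 recorded trials, scored by the recorded-trial mean.
- **MOT** (Multiple Object Tracking): ten 30×30 px squares in a 1014×758 px
  window; five flash as targets, all drift along headings from a fixed
  12-direction set at 60/134/180 px/s, mirror-reflecting off edges and
  overlapping freely. Accuracy is the fraction of targets re-identified;
  a session averages 30 trials.
- **DSST** (Digit Symbol Substitution Test): 93-box forms with a random
  9-symbol key, scored as correctly substituted symbols within 60 s, plus a
  parametric simulated responder (rate, error probability).

Human participants are replaced by parametric agents: a TTC-greedy
avoidance controller (reaction latency, pointer-speed cap, motor noise),
stationary and random-walk baselines, and a capacity-*k* tracking observer
(*k* targets tracked perfectly, the rest guessed uniformly). A cohort
generator draws per-participant skill parameters from per-group
distributions and runs the full battery per participant, enabling designed
group-difference studies.

The `psychometrics` module provides the analysis layer: Pearson
correlations, paired *t*, one-way ANOVA, empirical-logit transforms for
proportion scores, hierarchical OLS with nested-model F-change, a
Pillai-trace multivariate group test (with optional covariate), and a
test–retest reliability report.

## Command line

```sh
moa run --seed 1 --trials 8 --practice 2 --agent greedy --out moa.csv
mot run --seed 1 --trials 30 --observer capacity:3 --out mot.csv
dsst simulate --rate 0.8 --error 0.05 --seed 1 --out dsst.csv
cohort simulate --config examples/cohort.yaml --out cohort.csv
analyze --cohort cohort.csv --out report.json
analyze --retest time1.csv time2.csv
```

Task verbs accept `--config` (JSON/YAML overriding any engine default,
unknown keys rejected) and `--display` for the mouse-controlled interactive
version. Session logs are UTF-8 CSV with a `#`-prefixed header block
(schema version, task, config hash, master seed) and are byte-identical
across repeated runs with the same seed.

A cohort config looks like:

```yaml
cohort:
  group_a: {n: 21, capacity_mean: 4.0, latency_mean: 0.10}
  group_b: {n: 26, capacity_mean: 3.0, latency_mean: 0.20}
  master_seed: 7
```

## Determinism

Every random draw derives from a master seed via a counter-based scheme:
`SeedSequence([master_seed, task_code, trial_index])` yields the per-trial
seed, and agent randomness is namespaced separately as
`SeedSequence([agent_code, agent_seed, trial_seed])`. No global RNG state
is used, so any trial can be reproduced in isolation and identical seeds
give bit-identical sessions and logs.

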