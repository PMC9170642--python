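# Two-group synthetic cohort: group A has higher tracking capacity and
# faster reactions.  Engine settings may be overridden per task, e.g. to
# shorten runs; absent fields use the published defaults.
cohort:
  group_a:
    n: 21
    capacity_mean: 4.0
    latency_mean: 0.10
  group_b:
    n: 26
    capacity_mean: 3.0
    latency_mean: 0.20
  moa_config:
    max_trial_duration: 60.0
  mot_config:
    move_duration: 2.0
  master_seed: 7
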