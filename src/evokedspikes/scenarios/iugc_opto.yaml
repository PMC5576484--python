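# iuGC-group optogenetic scenario: 82 units, same protocol and effect sizes
# as the control optogenetic scenario.
name: iugc_opto
group_label: iuGC
n_units: 82
seed: 1
protocol:
  kind: optical
  n_trains: 40
  pulses_per_train: 30
  train_rate_hz: 20.0
  pulse_width_ms: 15.0
  inter_train_s: 3.0
  start_s: 62.0
response:
  excitation: {latency_ms: 0.0, duration_ms: 1.0, gain: 3.0}
  inhibition: {latency_ms: 0.0, duration_ms: 1.0, gain: 0.1}
composition:
  excitation:
    proportion: 0.44
    classes: {pDAergic: 0.83, pGABAergic: 0.11, other: 0.06}
  inhibition:
    proportion: 0.27
    classes: {pDAergic: 0.36, pGABAergic: 0.55, other: 0.09}
  none:
    proportion: 0.29
    classes: {pDAergic: 0.333333333, pGABAergic: 0.333333333, other: 0.333333334}
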