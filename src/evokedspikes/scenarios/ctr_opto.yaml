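# Control-group optogenetic scenario: 72 VTA units, repeated 30-pulse 20-Hz
# trains of 15-ms light pulses (40 trains, 3-s onset interval), 60-s baseline
# and post windows. Responder modulation is sustained over the stimulation
# period (gain is the stim-window rate multiplier; latency/duration fields
# are unused for optical protocols). Composition transcribes the published
# increase/decrease/no-change percentages and their class shares; the
# no-change class split is unpublished and allocated in equal thirds.
name: ctr_opto
group_label: CTR
n_units: 72
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
    proportion: 0.48
    classes: {pDAergic: 0.69, pGABAergic: 0.17, other: 0.14}
  inhibition:
    proportion: 0.21
    classes: {pDAergic: 0.0, pGABAergic: 0.87, other: 0.13}
  none:
    proportion: 0.31
    classes: {pDAergic: 0.333333333, pGABAergic: 0.333333333, other: 0.333333334}
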