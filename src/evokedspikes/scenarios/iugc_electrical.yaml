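# iuGC-group electrical-stimulation scenario: 41 units (so the published
# composition allocates in whole units), same protocol and effect sizes as
# the control scenario.
name: iugc_electrical
group_label: iuGC
n_units: 41
seed: 1
protocol:
  kind: electrical
  n_pulses: 100
  interval_s: 2.0
  pulse_width_ms: 0.5
  start_s: 1.0
response:
  excitation: {latency_ms: 5.0, duration_ms: 40.0, gain: 8.0}
  inhibition: {latency_ms: 10.0, duration_ms: 50.0, gain: 0.0}
composition:
  excitation:
    proportion: 0.31
    classes: {pDAergic: 0.30, pGABAergic: 0.60, other: 0.10}
  inhibition:
    proportion: 0.44
    classes: {pDAergic: 0.57, pGABAergic: 0.29, other: 0.14}
  none:
    proportion: 0.25
    classes: {pDAergic: 0.333333333, pGABAergic: 0.333333333, other: 0.333333334}
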