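# Control-group electrical-stimulation scenario: 40 VTA units, 100 single
# 0.5-ms pulses at 0.5 Hz. Published response-kind composition and its
# class shares within the excited/inhibited groups; the class split of the
# no-response group is not published and is allocated in equal thirds.
name: ctr_electrical
group_label: CTR
n_units: 40
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
    proportion: 0.50
    classes: {pDAergic: 0.70, pGABAergic: 0.20, other: 0.10}
  inhibition:
    proportion: 0.30
    classes: {pDAergic: 0.21, pGABAergic: 0.50, other: 0.29}
  none:
    proportion: 0.20
    classes: {pDAergic: 0.333333333, pGABAergic: 0.333333333, other: 0.333333334}
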