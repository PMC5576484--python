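# Methods

## Model and procedure

The package analyses stimulus-locked extracellular single-unit recordings.
Its core is deterministic rule-based detection, not model fitting:

1. **PSTH construction.** Spike times (seconds) are binned at `bin_width_ms`
   (default 5 ms) relative to every stimulus event over a window of
   [−500, +500) ms and summed across trials. All intervals and bins are
   half-open, so an edge spike is counted exactly once. The baseline is the
   500-ms pre-stimulus epoch (100 bins at defaults).
2. **Epoch detection.** With baseline per-bin mean μ and SD σ, an
   excitatory epoch opens at the first post-stimulus bin starting
   `run_length` (default 5) consecutive bins each strictly above
   μ + `sd_multiplier`·σ (default 2), and closes at the first later bin
   starting a run of bins at or below that threshold (window end if none).
   Inhibition is symmetric with floor `inhibition_fraction`·μ (default
   0.30) and strict `<`. Magnitude is the epoch count minus μ times the
   epoch bin count (positive deficit for inhibition). When both detectors
   fire, the earlier onset wins; the tie falls to excitation (under the
   per-bin rule an exact tie is actually impossible, since one bin cannot
   be simultaneously above the excitation threshold and below the
   inhibition floor — the rule is retained defensively).
3. **Cell-type assignment.** Putative dopaminergic: rate < 10.0 Hz and
   waveform duration > 1.5 ms; putative GABAergic: rate > 10.0 Hz and
   duration < 1.5 ms; otherwise (including exact boundaries, because the
   inequalities are strict) "other". The waveform duration estimator is
   trough-to-peak by default (`full_width` at half trough depth is the
   config alternative); both are invariant to amplitude scaling and DC
   offset.
4. **Optogenetic responsiveness.** Rates over a 60-s baseline, the
   stimulation period (first pulse onset to last pulse offset, including
   inter-train gaps when trains repeat — a single rate, total spikes over
   total time), and a 60-s post window. Responsive means |percent change of
   the stimulation-period rate from baseline| > 20. A silent baseline with
   any stimulation activity counts as excited (the relative increase is
   infinite); silence in both windows is non-responsive. The post-window
   rate is reported descriptively and never enters the criterion.
5. **Behavior.** Progressive-ratio requirement ⌊1.4^(T−1)⌋ evaluated as
   `7**(T-1) // 5**(T-1)` in exact integers (floating-point powers can
   mis-floor near-integer values); breakpoint is the requirement of the
   highest completed trial, with a per-trial 15-min termination clock.
   CPP difference score is post-minus-pre ON-side seconds; percentages are
   two-sided (center-chamber time excluded when declared).

## Interpretive decisions in the detection rules

Two phrases in the field's customary description of the epoch rules are
ambiguous and are resolved as explicit configuration:

- "first of five bins whose mean value exceeded …" is read per-bin: each of
  five consecutive bins must individually cross the threshold
  (`onset_rule="each_bin"`). The moving-average reading is available as
  `onset_rule="window_mean"`. The per-bin reading keeps onset well-defined
  at bin resolution and is the common convention.
- "consistently within/above" for the offset is read as a run of
  `run_length` sub-threshold bins, mirroring the onset rule.
- Baseline SD uses the population divisor (ddof 0): the baseline bins are
  the entire reference population. `sd_ddof` is configurable.
- Onsets are reported at bin left edges. Sub-bin latencies cannot be
  produced by 5-ms bins; no sub-bin interpolation is attempted.

## The simulator and the packaged scenarios

Units are piecewise-constant-rate Poisson processes: baseline rate λ
everywhere, multiplied by `gain` inside stimulus-locked windows. Excitation
(gain > 1) is realized by superposing an independent Poisson process at
(gain−1)λ inside the windows — exact for a sum of Poisson processes;
inhibition (0 ≤ depth < 1) by thinning baseline spikes to keep-probability
depth — exact for a thinned Poisson process. Electrical modulation windows
follow each pulse at the spec'd latency/duration; optical modulation is
sustained over the stimulation period. Every draw is a pure function of the
seed (numpy `SeedSequence` spawning one child stream per unit).

Scenario defaults (the study conditions for all recovery tests):

- Electrical protocol: 100 pulses, 2-s interval, 0.5-ms width. Excitation:
  gain 8, latency 5 ms, duration 40 ms. Inhibition: a complete evoked pause
  (depth 0, latency 10 ms, duration 50 ms). The pause is complete because
  the detection floor 0.3μ demands strictly zero-count bins whenever
  μ < 3.3 counts/bin — which holds for most of the 2–8 Hz dopaminergic
  range at 100 trials — and any residual epoch rate breaks the required
  5-bin run often enough (10–25% per unit) to corrupt composition
  recovery; a full pause makes detection near-certain, which is the
  fixtures' purpose, and evoked pauses of dopaminergic firing are
  physiologically routine.
- Optical protocol: 40 trains of 30 × 15-ms pulses at 20 Hz, 3-s train
  onset interval (~118 s stimulation period), 60-s baseline and post
  windows. Responders get sustained stimulation-period multipliers 3.0
  (excited) / 0.1 (inhibited). A single 1.5-s train would leave the
  stimulation-rate estimate of a 2–8 Hz non-responder with a coefficient
  of variation far above the 20% criterion (flip probability 0.3–0.5 per
  unit); repeated trains with rate-level averaging bring it to ~3·10⁻³ so
  that composition recovery is limited by allocation, not estimator noise.
- Baseline rates: pDAergic U(2, 8) Hz, pGABAergic U(12, 25) Hz. "Other"
  units sit on the rate side of the 10-Hz cutoff that their injected
  response pushes them *away* from (excited: U(10.6, 12) Hz with broad
  waveforms; inhibited/none: U(8, 8.4) Hz with thin waveforms), because
  epoch modulation shifts the whole-recording mean rate by up to ~14% and
  must not carry a unit across the classification boundary.
- Waveform durations: pDAergic U(1.7, 2.5) ms, pGABAergic U(0.7, 1.3) ms,
  synthesized as biphasic Gaussian templates (trough–peak separation =
  target duration) at 40 kHz and then *measured* by the package's own
  trough-to-peak estimator, so classification consumes measured, not
  declared, durations.
- Compositions are allocated by largest remainder — response kinds first,
  then classes within each kind — so the packaged fixtures realize their
  target percentages exactly and recovery error is attributable to the
  detectors alone. The class split of no-response units is an equal-thirds
  choice (no published value constrains it).
- Classification uses the whole-recording mean rate for electrical
  scenarios (the default) but the 60-s baseline-window rate for optical
  scenarios, where sustained ×3/×0.1 modulation over ~half the recording
  would otherwise shift genuine responders across the 10-Hz boundary.

## What the simulator does not emulate

No refractoriness, bursting, or spike-waveform variability; no correlated
population noise; no electrical stimulus artifacts or light artifacts; no
drift or unit loss; effect sizes are deliberately strong and uniform rather
than matched to any real recording. Passing recovery tests therefore
demonstrates that the implementation of the rules is correct and that the
pipeline recovers known ground truth under clean conditions — not that the
rules themselves would achieve this accuracy on real recordings, where
effect sizes, stationarity and class separability are all less favorable.

## Numerical choices and degenerate inputs

- Zero-variance baseline: the excitation threshold degenerates to μ with
  the strict inequality retained. Zero baseline mean: inhibition is
  undetectable and reported as "none" (logged); excitation magnitude over a
  zero baseline is the raw epoch count.
- Runs shorter than `run_length` never open or close an epoch; an epoch
  that never closes ends at the window edge.
- Simulated spike trains pass through `np.unique` (exact ties are a
  measure-zero event but would violate strict monotonicity).
- Apportionment remainder ties break toward the earlier composition entry,
  keeping allocations deterministic.
- Times are exchanged in seconds; all millisecond quantities carry `_ms`
  suffixes and are converted at type boundaries.

## Problem sizes

Recovery tests use the packaged scenario sizes (40/41/72/82 units, 100
electrical trials, 40 optical trains) and 200 units for the
excitation-parameter recovery check; the detector-versus-brute-force
equivalence scan uses 250 randomized PSTHs of up to 60 bins plus a
derandomized property-based sweep. The full suite runs in a few seconds on
one CPU.

## Known limitations

- The epoch detectors report one epoch per unit and direction; biphasic or
  multi-epoch responses are out of scope.
- Onset latency is bin-resolution only.
- The "other" class absorbs all boundary and inconsistent units; no
  probabilistic or clustering-based reassignment is attempted.
- The group-comparison utilities (Welch t, one/two-way ANOVA with
  Bonferroni pairwise) are conveniences for users' own data; nothing in
  the package claims to reproduce inferential statistics from recordings
  it does not have.
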