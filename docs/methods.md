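# Methods notes

This note documents the models, parameter choices and numerical conventions
behind `vtamua`, and what the synthetic generator does and does not emulate.

## Task and neural model

The simulated task is a two-key visual discrimination: on each trial a green
(cue⁺) or red (cue⁻) light appears for 2 s; a green-key peck opens the feeder
for 2 s, red pecks and no-responses lead directly to a 2 s intertrial
interval. Sessions are preset to 100 trials by default.

Pooled-array spiking is an inhomogeneous Poisson process

```
λ(t) = r₀ + A_cue(s) · exp(−(t − t_cue − ℓ)²/2σ²) + A_rew(s) · exp(−(t − t_rew − ℓ)²/2σ²)
```

with baseline `r₀`, session-indexed bump amplitudes `A_cue(s)` (nondecreasing)
and `A_rew(s)` (nonincreasing; rewarded trials only), latency `ℓ` and width
`σ`. Learning is thus encoded purely as a redistribution of event-locked
gain from outcome to cue, which is the effect the analysis is designed to
detect. Sampling uses the standard thinning algorithm with the exact bound
`r₀ + ΣAᵢ`, so counts are exactly Poisson with mean ∫λ.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| baseline rate `r₀` | 40 spikes/s pooled (16 ch × 2.5 sp/s) | typical sparse midbrain MUA per channel; no published value for this preparation, free parameter |
| `A_cue` schedule | (8, 28, 48, 56, 64) sp/s | phasic gain up to ~1.6× baseline, in the range of mammalian dopamine burst modulation; increments shrink after session 3 (saturating learning) |
| `A_rew` schedule | (64, 44, 24, 16, 8) sp/s | mirror of the cue schedule: outcome-locked response strongest naive, fading with learning |
| bump latency `ℓ` | 150 ms | keeps the bump well inside the 0.5 s epoch; onset latency is not published |
| bump width `σ` | 100 ms | phasic-burst timescale; bump mass ≈ A·σ·√2π |
| accuracy curve | (0.62, 0.74, 0.84, 0.90, 0.92) | crosses the 85% phase criterion at session 4, matching the published 3+2 learning/consolidation split |
| premature / artifact / no-response rates | 0.15 / 0.10 / 0.05 | within the per-animal ranges implied by the published exclusion accounting |
| noise SD | 4 µV, spikes at 10× noise SD | comfortably above the 5× detection threshold, as for well-seated microwires |
| sampling | 30 kHz, 16 channels, 39-sample (1.3 ms) template | acquisition settings of the emulated recordings |

Reward onset equals response time (the peck opens the feeder immediately);
the behavioral model is a per-trial Bernoulli choice with session-level
probability and no within-session drift — the simplest generator meeting the
session-level emulation targets. Because the reinforcement schedule is
deterministic, a green selection identifies a cue⁺ trial and a red selection
a cue⁻ trial; no-response trials get a random cue label.

### What the generator does not emulate

No biophysics, refractoriness, bursting, LFP, waveform diversity,
electrode drift, or within-session learning. A green test therefore
establishes that the *analysis chain* recovers the statistical structure it
assumes (Poisson event-locked gain redistribution), not that real VTA data
have that structure.

### Trial-accounting fixture

`build_trial_count_fixture()` is a synthetic stand-in for the unreleased
behavioral records of the three animals (P109, P117, P121). Its margins are
exact — per-session extracted/valid key-peck counts, per-animal exclusion
reason totals (premature < 500 ms; large-amplitude wing flapping), 451 valid
trials overall — but the per-session split of exclusion reasons is not
published, so premature exclusions are allocated greedily session-by-session;
trial ordering, timing and the per-session accuracies are invented (the
accuracies are chosen to cross the 85% criterion at the documented session:
P109/P121 at S4, P117 at S3).

## Spike detection

* Filter: 4th-order Butterworth, 250–5000 Hz, applied forward–backward
  (`sosfiltfilt`) for zero phase; order and phase handling are this package's
  choices.
* Noise SD: median absolute deviation × 1.4826 by default — robust to spikes
  occupying a few percent of samples; a plain-SD mode exists for comparison.
* Threshold: negative-going only, at −5 × noise SD (polarity implied by
  negative-peak alignment).
* Lockout: 1.0 ms after each accepted crossing, preventing multiple counts of
  one waveform.
* Alignment: the waveform is re-centred on the signal minimum within ±0.4 ms
  of the crossing; events within half a waveform of an edge are dropped; two
  crossings aligning to the same minimum collapse to one event.

The detector is verified against a sample-by-sample brute-force scan (exact
event-index equality) and against injection logs (recall/false-discovery on
10× noise-SD templates).

## Behavioral QC and phases

Premature means response latency strictly < 0.5 s (a latency of exactly
0.5 s is retained); the rule is applied uniformly whether or not an upstream
flag is present. Artifact flags are taken as given — no artifact detector is
implemented. A doubly-flagged trial counts once, as premature, keeping
`valid = extracted − premature − artifact` exact. Accuracy is computed on all
key-peck trials (QC protects the neural analyses, not the behavioral
measure). The 85% phase criterion is one-way: once consolidation is entered
it is never revoked by a later dip.

## Epoch metrics

Windows are half-open `[start, end)` so a boundary spike is counted once.
Under QC the reward window cannot overlap the cue window (premature trials
are excluded); the code asserts this with a warning rather than assuming it.
Trials with zero spikes in every analysed epoch have undefined proportions
and are excluded from session means with a logged count. Session SD uses the
sample convention (n − 1); single-trial sessions report SD 0 with a
degeneracy flag.

## PSTHs and sliding windows

PSTH bins are whole multiples of the bin width (a trailing partial bin is
dropped), preserving the counting identity Σ rate·bin·n_trials = total
aligned spikes exactly. Display resolutions are 10 ms (fine) and 100 ms with
a 5-point centred moving average (coarse); the moving average uses shrinking
windows at the edges rather than padding, so a constant series is unchanged.
Both pooled-array (spikes/s) and channel-normalised (spikes/s/channel)
modes are provided. Sliding-window defaults are a 100 ms window advanced in
10 ms steps, matching the coarse PSTH resolution; area under the rate curve
uses the trapezoidal rule.

## Statistics

Both Wilcoxon tests are two-tailed with `p = 2·min(P(W ≤ w), P(W ≥ w))`
capped at 1. Ties receive mid-ranks everywhere. Exact null distributions are
computed in-package — signed-rank by convolution over sign assignments
(default for effective n ≤ 25, zero differences dropped), rank-sum by
enumeration over group labelings (default for n₁+n₂ ≤ 16) — because standard
exact routines refuse tied data. Larger samples use the tie-corrected normal
approximation without continuity correction. All-zero-difference inputs are
reported as undefined and non-significant. Because the exact null is
discrete, the attainable two-sided level just below 0.05 is 0.0488 for the
signed-rank test at n = 10 and 0.0499 for the rank-sum test at 8 vs 8; the
type-I calibration tests use these sample sizes so the attainable level sits
near the nominal α.

Within-session epoch contrasts pair epochs within trials (pre–cue always;
pre–reward and cue–reward on rewarded trials); which pairwise contrasts the
original analysis tested is not enumerated, so all three are reported. No
multiple-comparison correction is applied to the primary report; a
Holm-adjusted column is emitted alongside for transparency.
Learning-vs-consolidation contrasts treat trials of the two phases as
independent samples (rank-sum).

## Pipeline determinism

One global seed is fanned out to per-stage child seeds through SHA-256 of the
(seed, stage, …) path, truncated below 2³¹, so partial reruns reproduce
exactly; the manifest records a SHA-256 checksum per artifact and the fully
echoed configuration. Simulate-mode runs draw spike times directly from the
rate model by default; `render_raw: true` instead renders per-channel voltage
traces and runs the full detection chain (meant for small configurations —
a full 100-trial session at 30 kHz × 16 channels is expensive).

## Known limitations

* The Poisson model has no refractory period, so detection on rendered
  traces slightly undercounts near-coincident spikes within the 1 ms lockout.
* The precue window can contain anticipatory activity once learning is under
  way; as in the emulated study, precue-referenced effects should be read
  conservatively.
* Behavioral accuracy has no within-session dynamics; session-resolution
  learning curves only.
* cue⁻ analyses are 2-way by construction; nothing is inferred about reward
  omission (not part of the task).
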