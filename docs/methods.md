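# Methods

## Signal model and kinematic primitives

Each recording consists of two 3-axis gyroscope streams (wrist and medial
humerus of the throwing arm) sampled at fs = 128 Hz, in deg/s. The pattern
signal is the magnitude of the componentwise vector sum of the two streams,
|gyr1 + gyr2| = √((x₁+x₂)² + (y₁+y₂)² + (z₁+z₂)²). Both the single-sensor
magnitude and the sum magnitude are Euclidean norms; norms are invariant
under a common rigid rotation of both sensor frames, which the test suite
checks, so the score does not depend on how the upright-standing axes are
labelled.

Gyroscope units are taken as deg/s (typical for the device class). The
choice only rescales f₃'s raw penalties uniformly and cancels under the
max-to-100 normalisation, so it does not affect any score.

Filtering is a 4th-order Butterworth low-pass at 25 Hz applied zero-phase
(forward–backward), the biomechanics convention: it preserves event timing
exactly (the suite checks that a symmetric pulse's peak does not move), at
the cost that the effective magnitude response is the square of a single
pass. Edges are handled with reflective padding of length 3×(order+1),
which avoids start/end transients; a series must be longer than the padding
to be filterable. Filtering is applied to the combined |gyr1+gyr2| signal
of the *full* recording — after vector summation and magnitude, not per
axis, and before slicing pass windows — so windows carry no per-window edge
transients.

The sample period is Δt = 1/fs = 7.8125 ms at 128 Hz. Input CSVs may carry
a sample-index column, a timestamp column, or both; the sample index is
authoritative and a timestamp that disagrees with it by more than half a
sample period rejects the trace (no resampling is attempted).

## Windowing and the pattern integral

Pass windows come from annotations (video-derived in the original
protocol): a pass starts at ball reception and ends at release. Windows are
half-open [start, end) in 0-based indices, so n = end − start exactly and
contiguous windows partition a recording. Elapsed time is n/fs.

The per-pass movement-pattern summary is the left-endpoint rectangle-rule
integral Δt Σ|gyr1+gyr2| over the window, in degrees (an accumulated
angular-displacement proxy). The left-endpoint rule is used rather than the
trapezoid rule because it is the direct reading of the elementary-rectangle
construction the scoring method defines; on the smooth bursts that real
passes produce the two differ by at most one rectangle per monotone
segment, which the oracle tests assert.

## Penalty factors

* **f₁ (accuracy)** takes the five discrete values {0, 25, 50, 75, 100}.
  When impact geometry is available instead of a scored category, the
  overlap fraction of the ball's impact disc with the open square interior
  is computed (shapely polygon intersection; the discretised circle keeps
  the area error near 1e-6, verified against a 10⁶-point Monte-Carlo
  oracle) and binned: fraction 1 without boundary contact → 0; ≥ 2/3 → 25;
  (1/3, 2/3) → 50; (0, 1/3] → 75; 0 → 100. The 1/3 and 2/3 edges
  operationalise "most of the area"; a full cover that touches a boundary
  line is demoted from 0 to 25 because a clean hit must not touch the
  lines. f₁ is already on the 0–100 scale and is not re-normalised.
* **f₂ (time)** is round(|n − Ex_Tr|) **in samples**. The deviation is
  measured in samples rather than seconds because rounding to the nearest
  natural number is only meaningful on that scale (in seconds nearly every
  deviation would round to 0); this is recorded as a package assumption.
  Ex_Tr is the mean duration of the quickest pass type in the reference
  group, rounded to the nearest sample.
* **f₃ (variability)** is round(|integral − ExPT_ir|) against the
  per-pass-type reference mean ExPT_ir (five references, one per type).

Rounding is half-away-from-zero, matching "nearest natural number" for
non-negative values without banker's bias.

**Normalisation.** Raw penalties are scaled so the pool maximum maps to
exactly 100. f₃ pools per pass type (each type has its own reference and
maximum); f₂ pools across all executions of all pass types by default,
with a per-type pool available via configuration (`f2.normalization_pool`),
since either reading of "once all evaluations are completed" is defensible.
An all-zero pool normalises to all zeros — a cohort of perfect executions
receives zero penalty rather than a division by zero.

**References are artifacts.** Ex_Tr and ExPT_ir are computed from a
configurable reference group (default "A", the experienced players) and are
serialisable to JSON so a frozen reference can score a new cohort.

## Index and aggregation

Qualities are q = 100 − normalized penalty and the index is the weighted
sum x₁q₁ + x₂q₂ + x₃q₃ with x₁+x₂+x₃ = 1. Penalties measure deviation, yet
the published score is 0–100 with better players scoring higher; the
quality complement is the only direction consistent with both, and is the
package's reading. The neutral default weights are (1/3, 1/3, 1/3); the
original application weighted accuracy more for mature throwers, but the
exact weights were never published, so no attempt is made to reproduce the
published group means (also impossible without the raw recordings).

The modified mean removes exactly one maximum, one minimum and one median
(by position in the sorted order) before averaging; it needs ≥ 4 values.
For even lengths the lower of the two middle order statistics is removed —
exactly one element must go and the choice must be deterministic. Ties at
the extremes remove a single occurrence each.

## Statistics

SEM is √(MS_error) of the one-way repeated-measures decomposition of a
complete subjects × trials table: MS_error = SS_residual/((s−1)(t−1)) after
removing subject and trial main effects. It is invariant to adding a
constant or a per-subject constant, and recovers an injected within-subject
SD (simulation-checked at 50 subjects × 10 trials, 200 replicates, within
10%). CV = SEM/mean × 100. Group comparison uses the pooled-variance
Student's t (not Welch — matching a homogeneity-screened design) with a
95% CI of the mean difference, and Hedge's g with J = 1 − 3/(4N − 9)
(an exact gamma-function correction is available behind a flag). Labels on
|g|: < 0.2 negligible, [0.2, 0.5) small, [0.5, 0.8) medium, [0.8, 1.2)
large, ≥ 1.2 extra-large. Percent change between group means supports both
groups as base, because "X% greater" phrasing is ambiguous about its
denominator. No multiplicity correction is applied; p-values are raw.

## Synthetic cohort generator

The generator emulates the study design — 2 groups × 8 players × 5 pass
types × 25 executions (5 targets × 5 consecutive passes) at 128 Hz — so the
full pipeline and its statistics are testable without real data.

Each execution is a raised-cosine (Hann-shaped) angular-speed burst of
drawn duration and peak, split between wrist and humerus at a fixed 65:35
amplitude ratio along a common direction, embedded in 1–2 s of baseline
between passes, with additive white noise (SD 2 deg/s per axis) over the
whole recording. The raised-cosine is band-limited far below the 25 Hz
cutoff, so filtering is nearly transparent, and its rectangle integral has
the closed form peak × duration/2 — the analytic oracle used in tests.
Shape jitter multiplies the burst by a low-frequency (1–3 Hz) sinusoid of
relative amplitude equal to the jitter parameter.

Group templates encode the experienced/novice contrast: A-level players
are faster (chest ≈ 0.55 s vs 0.68 s, other types 7–10% quicker), reach
higher peaks (≈ 12% higher), are roughly half as variable trial-to-trial
(duration SD 0.04–0.06 s vs 0.09–0.11 s, jitter 0.05–0.06 vs 0.12–0.13)
and draw from more favourable accuracy distributions. The chest pass is
the quickest type in both templates, so it sets Ex_Tr, as in the original
protocol. Player-level heterogeneity multiplies each player's duration and
peak means by Gaussian factors (relative SD 0.06 and 0.08) so groups have
realistic between-player spread. These values were chosen once as a
plausible rendering of the described cohort; the generated contrast is
deliberately clear-cut, and the resulting between-group effects are larger
than a real young-player cohort would show, so passing tests demonstrate
pipeline correctness and direction of effects, not field-realistic effect
magnitudes.

What the generator does **not** model: multi-joint biomechanics, ball
flight (accuracy is drawn categorically, not simulated from trajectories),
accelerometer/magnetometer channels, sensor-frame differences between the
two IMUs (both share a direction vector), or skill drift across trials.
Conclusions from synthetic tests therefore cover the scoring arithmetic,
normalisation, references, statistics and determinism — not the validity
of the burst model as human movement.

All randomness flows from a single seed; a truth table records every drawn
parameter; identical seeds give byte-identical outputs (the run logs
contain no timestamps for this reason).

## Problem sizes used in the checked suites

Stochastic suites run at: 100 seeded full-size cohorts for the
skilled-beats-novice dominance check (the acceptance script uses 50); 15
seeded full-size matched-template cohorts for the null-effect check; 200
replicates of 50 × 10 tables for SEM recovery; 10⁶ Monte-Carlo points for
the overlap oracle; 1000 random sequences for the modified-mean oracle.

## Known limitations

- The published per-group Q-Pass means cannot be reproduced: the raw
  recordings and the weights used are unavailable. The published summary
  statistics are instead used as *inputs* to the reliability and
  effect-size worked examples.
- Published percent-change figures are not recoverable from the printed
  means under either base and are not asserted.
- Normalisation makes scores cohort-relative unless a frozen reference and
  a frozen normalisation pool are reused; scoring a lone execution is not
  meaningful.
- The f₂ samples-vs-seconds unit choice and the f₁ bin edges are package
  decisions where the method description is silent; both are configurable.
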