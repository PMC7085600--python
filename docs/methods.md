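# Methods

## The recognition problem

An overhand throw decomposes into six sequential phases: wind-up (Step 1),
stride (Step 2), arm cocking (Step 3), arm acceleration (Step 4), arm
deceleration (Step 5) and follow-through (Step 6), preceded by a
getting-ready gate (Step 0).  Two tri-axial accelerometers — one on the
forearm, one on the upper arm — observe the movement as raw signed 16-bit
counts.  `throwsense` decides, per phase, whether the athlete executed it
correctly, and if not, which catalogued error best describes the failure.

The method is symbolic: rather than comparing waveforms, each channel is
quantized into a string over a 27-letter alphabet and phases are matched
by longest common subsequence (LCS) against a template database.  LCS
makes the matching *speed-invariant*: a slower throw only lengthens the
symbol runs, and a subsequence match is indifferent to run length.

## Pipeline

1. **Kalman smoothing.**  Each of the six axis streams is filtered with a
   scalar constant-state (random-walk) Kalman filter — predict
   `x⁻ = x`, `p⁻ = p + q`; update `k = p⁻/(p⁻+r)`, `x = x⁻ + k(z − x⁻)`,
   `p = (1−k)p⁻` — with defaults `q = 0.01`, `r = 0.1` (counts are scaled
   to ±1 before leveling, so these are variances on the normalized scale
   after division; both are config-overridable).  The constant-state model
   is the simplest one consistent with Gaussian sensor noise around
   piecewise-steady postures.  At steady state the gain is ≈ 0.27, which
   suppresses noise by roughly √6 while delaying threshold crossings by
   only 2–3 samples at 100 Hz.
2. **Normalization.**  Counts are divided by the fixed full scale 32768
   (not by a per-trace maximum), so the leveling thresholds mean the same
   thing in every recording, and clipped to [−1, 1].
3. **Leveling.**  Each normalized axis value maps to a ternary level:
   +1 above +0.35, −1 below −0.35, 0 otherwise (boundaries inclusive in
   the dead band).
4. **Labeling.**  A level triple (x, y, z) maps to one of 27 symbols per
   channel via a single canonical status table; forearm symbols are
   'A'–'Z' plus '1' (rest, the all-zero triple), upper-arm symbols are the
   lowercase mirror plus '2'.  Rest symbols are retained in sequences.
5. **Matching.**  The symbol pair stream is scanned against thirteen
   ordered sub-templates (below) with a dual-channel LCS similarity test
   at threshold `theta` (default 0.7).

## Template database and class-order convention

The six phase templates list their classes chronologically:

| Step | Forearm | Upper arm |
|------|---------|-----------|
| 1    | P, E    | p         |
| 2    | Y, M, A | k, a      |
| 3    | G, B, H | m, y, r   |
| 4    | D, L, F, M | r, y   |
| 5    | A       | a         |
| 6    | K       | k         |

For continuous recognition the steps are refined into thirteen
sub-templates of one or two classes per channel, written in the
traditional brace notation — `Step 1 = {E-P}⊕{p}`, `Steps 1-2 = {Y-E}⊕{k-p}`,
`Step 2.1 = {M-Y}⊕{k}`, … , `Step 6 = {K-A}⊕{k-a}` — where `⊕` couples the
two channels over the same window.  Brace lists are *anti-chronological*:
read right-to-left, the thirteen templates chain head-to-tail with exactly
one overlapping class between neighbours on both channels (forearm
composite P E Y M A G B H D L F M A K; upper-arm composite
p k a m y r y a k).  The package stores the lists as printed
(`forearm_classes`) and exposes the matching order as `temporal_*`
properties.  A structural test asserts the chain.

Transition templates (Steps 1-2, 2-3, 3-4) are matched and reported but
advisory: only numbered-step verdicts enter the result, since the error
catalogue defines messages for Steps 0–6 only.

## Window search and similarity score

The forearm channel drives segmentation: for each sub-template, the next
runs realizing its temporal classes in order (runs shorter than `min_run`
= 3 samples are ignored as glitches) delimit a window from the first
class's run start to the last class's run end.  Both channels of that
window are then scored.

The similarity of a window against an ordered class list is
`LCS(segment, expansion) / len(expansion)` where the expansion repeats
each class as often as its symbol occurs in the segment.  Symbols foreign
to the template (quantizer transits between plateaus, noise glitches) are
simply left unmatched — the outlier tolerance LCS is chosen for — so the
ratio measures how much of the window's template-alphabet content occurs
in the right order, independently of throwing speed.  If any class is
absent the expansion falls back to an even split of the full window
length, capping the ratio at roughly `1 − 1/k`, far below `theta`.  A
cheap alphabet screen skips the DP entirely when no template class occurs
in the segment.  A step passes only when *both* channels reach `theta` on
*all* of its sub-templates, in order.

`theta = 0.7` tolerates boundary jitter and isolated glitches while
rejecting any window missing a class (score ≤ 0.5 for two-class
templates) and cross-phase windows (disjoint alphabets score 0).

Because consecutive templates share one class, a numbered-step template
begins with the *previous* step's final class (Step 5 = {A-M}: the M
belongs to Step 4).  When the previous numbered step failed, those overlap
classes are stripped (membership in the phase templates decides which are
"own"), so a corrupted phase cannot cascade into the phases after it.

## Error diagnosis

When a step fails, the stream suffix from the failure point is examined:

- a registered deviant pattern that matches names the error:
  - Step 4, "Elbow is not high enough": none of D/L/F/M on the forearm
    while the upper arm still proceeds through r and y — the forearm never
    whipped although the upper arm moved;
  - Step 6, "No follow-through": nothing but rest/standing remains — the
    arm stopped at release;
- otherwise, if only rest/standing remains and the failed step is before
  Step 6, this and all later steps are marked *incomplete* (an abandoned
  throw, not a misclassified one);
- otherwise the step's generic catalogue message (`Error-k`) is used.

The catalogue also carries "Inverted W", "Elbow is too low" and "Forearm
flyout"; no discriminating signal signature is defined for them, so they
can be produced only by user-registered deviant patterns, never by the
default rules.

Verdicts are rendered in two dialects: the display channel
(`S4: Elbow is not enough high!!`) and the report channel
(`STEP4: Elbow is not high enough`); the display phrasing follows the
device wording verbatim, ungrammatical as it is.

## Step 0 and stream segmentation

The readiness gate requires both channels to hold their standing-posture
triple — (0, −1, 0) on each arm, i.e. gravity on −y with the arm hanging —
for `min_hold` = 30 consecutive samples (0.3 s at 100 Hz).  A stable hold
of the *wrong* triple is reported as "Worn too inside or outside"; no
stable hold at all as "unstable".  No throw is recognized in a stream
whose gate never passes.

In continuous recordings the machine cycles: gate → onset (forearm leaves
the standing class for ≥ 3 samples) → window → recognition → gate.  The
window closes when rest/standing persists for `rest_hold_s` = 1.0 s.  This
value is deliberately longer than any single silent phase of an erroneous
throw at realistic speeds (≤ 0.6 s), so a throw whose failed step is pure
rest is not split in two, yet shorter than the ≥ 1.8 s idle gap between
consecutive throws.  `throw_timeout_s` = 12 s caps a window that never
returns to rest.  A window cut off by the stream end or the cap yields
incomplete verdicts for the unreached steps.

Left-handed mode mirrors the x axis of both channels before leveling;
the generator applies the same mirror to its raw output, so a left-hand
recording processed in left mode is symbol-identical to its right-hand
twin (asserted as a property test).

## Identification-rate aggregation

Per-step accuracy is 100·k/n over n attempts; a user's average is the mean
of their seven stage accuracies (Step 0 included), the per-stage average
is the mean across users, and the overall accuracy is the mean of the
per-user averages.  All percentages are computed exactly (rational
arithmetic) and *truncated toward zero* at two decimals — the convention
under which 640/7 % prints as 91.42 — so reported tables are reproducible
to the digit.

## Synthetic data: what it emulates and what it does not

The generator renders the template choreography directly: per step, each
forearm class becomes a plateau at ±0.6 on the normalized scale (outside
the ±0.35 band, inside ±1), with the step duration split equally among its
classes; upper-arm class changes are aligned to forearm class boundaries
(each upper class covers a contiguous block of forearm classes), which is
the simultaneity the ⊕ coupling asserts.  Plateaus are joined by linear
ramps (default 10 % of a class slot), Gaussian noise of configurable σ is
added, and the result is scaled to integer counts.  Defaults: 100 Hz,
0.4 s per step, 1.0 s standing lead-in, 0.8 s lead-out; "varied speed"
draws step durations uniformly from 0.3–0.6 s.  All randomness flows
through one seeded generator; identical profiles reproduce identical
traces.

Registered erroneous-action generators mutate one step's choreography:
rest on both channels (`Error-1` … `Error-5`, `Error-4`, and
"No follow-through" at Step 6), sign-inverted postures (`Error-6`, a
wrong but non-rest movement), forearm-only rest with the upper arm intact
("Elbow is not high enough"), and a rotated standing posture
("Worn too inside or outside", which trips the Step 0 gate).  Each
generator's ground truth records the intended per-step verdict, and an
end-to-end test asserts the recognizer reproduces it exactly at σ = 0.

The model is a *choreography*, not biomechanics: real throws produce
curved, overshooting, subject-specific accelerations, and real error modes
are not clean silences or sign flips.  Passing the synthetic suite
therefore demonstrates the correctness and internal consistency of the
pipeline — quantization, template chaining, gating, diagnosis, speed and
handedness invariance, noise robustness of the symbolic layer — not the
field identification rates achievable on human subjects, which depend on
inter-subject variability the generator does not model.  For the same
reason the published per-step rates (82–100 %) are inputs to the
aggregation stage here, not quantities the synthetic harness tries to
reproduce.

## Numerical choices and degenerate inputs

- Kalman filter: `x0` defaults to the first measurement (a constant series
  is a fixed point); non-positive variances and empty series are errors.
- Leveling boundaries (exactly ±threshold) quantize to 0, following the
  strict greater-than/below convention.
- Ground-truth symbol comparisons exclude a 0.1 s guard around intended
  class boundaries: the filter delays crossings by 2–3 samples, which is
  lag, not quantization error; plateau-interior samples are the meaningful
  error measure.
- Non-monotone timestamps and out-of-range counts are rejected with the
  offending row named, never repaired.
- LCS uses the full (m+1)×(n+1) DP table semantics (a matrix accessor is
  exposed for inspection); only lengths are needed, so no traceback is
  kept.
- Run-length and window logic is deterministic; ties cannot arise because
  adjacent temporal classes always differ.

## Problem sizes used by the verification harness

The test suite and `scripts/acceptance.py` use 50 noiseless throws with
varied durations and alternating handedness, 3 repetitions of each of the
nine registered error generators, speed factors ×1–×5, 60 throws at
σ = 0.05, 15 repetitions per σ ∈ {0, 0.05, 0.1, 0.2} for the noise-sweep
monotonicity check, and 500 random string pairs (lengths ≤ 10) against a
brute-force subsequence-enumeration oracle for the LCS core.  These sizes
give stable rates while keeping a full run in the low seconds.

## Known limitations

- The recognizer is a batch scanner over delimited windows, not the
  online per-sample state machine a wearable runs; interrupt handling is
  reconstructed through the rest-hold windowing rule.
- Error discrimination beyond the two registered deviant patterns is out
  of reach of the default rules (no signatures are defined for the other
  named errors).
- The readiness criterion (stable standing hold) is a reconstruction of a
  rule originally given only graphically.
- Sensitivities (2048/4096 LSB/g) are carried for physical-unit
  conversion only; the symbolic pipeline operates on the fixed-scale
  normalization and never uses them.
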