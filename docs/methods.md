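# Methods

This note documents the models, conventions, parameter defaults and known
limitations of `pursuittrack`. Everything stated here is computed by the
package's test suite or by `scripts/acceptance.py`; no empirical claim is
made beyond what those runs show.

## Coordinate and data conventions

Origin at the screen centre, x to the right, y up, units pixels, sampling at
the frame rate (60 Hz default). Trials are generated rightward; leftward
trials are the mirror image about the vertical centre axis, and all analysis
first *direction-normalizes* a trial (mirrors leftward trials back), which
makes every result invariant under the left/right manipulation. Cursor x is
locked to target x in the standard paradigm; the CSV schema still carries
both columns so converted two-dimensional recordings remain representable
(a violated x-lock is a warning, not an error).

## Target trajectories

Each of the three segments evaluates `f(x) = Σ_{i=1..3} aᵢ sin(ix) + bᵢ cos(ix)`
on 240 points over one full period [0, 2π] of the fundamental. The first and
third segments draw all six coefficients uniformly from ±40 px per trial;
the middle segment always uses a = (37, −3, 26), b = (23, −15, −9), so its
shape repeats identically in every trial (the implicit-learning probe). The
first segment is shifted vertically so the trial starts exactly at the
screen centre. Between segments, 30-point gaps are filled by a cubic spline
fitted on the 10 known samples flanking each side, giving a jump-free curve.
With these bounds |f| ≤ 240 px, safely inside the ±540-px vertical screen
limits.

**Constant speed.** The target's screen displacement per frame is constant:
the dense curve is resampled at equal Euclidean *chord* steps along the
polyline (the step solved per region so the walk ends exactly on the region
endpoint). Chord stepping, rather than equal arc-length spacing, is what
"constant velocity on screen" means operationally, and it keeps consecutive
spacing uniform to well under 0.5% even across sharp direction changes,
where arc-equal spacing cuts corners. Resampling is done in three regions —
(random1 + gap), (constant), (gap + random2) — each from its own start, so
the repeated segment's resampled coordinates are **bit-identical** across
all trials of a velocity level; region steps differ from the nominal speed
by at most half a step over a region (≈0.3%).

**Open geometry parameters.** The paradigm fixes the coefficient range, the
middle coefficients, the gap length, the frame rate, the session structure
(6 conditions × 12 repeats, counterbalanced, shuffled under the session
seed) and a 12-s mean trial duration, but not the phase domain, the dense
sampling density, the horizontal extent, or the pixel speeds. Defaults
chosen here, once:

| parameter | default | rationale |
|---|---|---|
| phase domain | [0, 2π] per segment | yields ≈19 target direction changes per trial, matching the field-reported count |
| samples_per_segment | 240 | dense enough that resampling preserves every extremum |
| trajectory_width | 450 px | see below |
| velocity_levels | (1.44, 2.16, 2.88) px/frame | ratio 1 : 1.5 : 2; calibrated so the mean trial duration across levels is 12 s |

The horizontal extent controls how steep the waveform is relative to the
horizontal motion, and thereby the ratio of temporal to spatial error under
delayed tracking. A half-screen extent (900 px) predicts a pure-delay
temporal/spatial mean-error ratio of ≈1.8 — *below* the ≈2.6 reported for
human data, which is impossible since human noise inflates both errors
toward each other. 450 px gives a pure-delay ratio of ≈2.9, consistent with
≈2.6 as its noise-degraded observation, and matches the much higher local
ratios seen on steep repeated-segment stretches. Speeds were then re-fit to
the 12-s mean duration.

**Seeding.** One session seed; the presentation order and every trial's
coefficients come from deterministic substreams (`default_rng([seed, 1+i])`),
so any single trial is regenerable without the rest of the session.

## Pursuit simulator

`cursor_y(t) = gain · target_y(t − lag + jitterₜ) + offset + oscillation + noise`,
with the reference held at the first/last target value beyond the trial
edges (a participant resting at the start position; no wrap-around).
Negative lag is a lead. Missed reversals replace the delayed reference
around a skipped target extremum with a linear bridge, reproducing the
"false tracking" pattern of passing straight through a reversal. The
default lag of 9 frames (150 ms) is a typical continuous-tracking
visuomotor delay; default noise 3 px. The simulator is a delay line, not a
control-theoretic model of a human: it provides *known ground truth*
(lag, offsets, noise, skip events) for validating the analysis, not a
behavioural theory. Consequences: simulated pursuits have target-like
smoothness plus white noise (no motor-noise spectrum, no drift or fatigue),
and passing tests demonstrate correctness of the *measurement pipeline*,
not realism of human tracking.

## Direction-change detection

A direction change is a strict local extremum of y (larger/smaller than
both neighbours, i.e. a reversal within 50 ms at 60 Hz). Plateaus — runs of
exactly equal samples, common in integer-pixel joystick data — are collapsed
to their midpoint before the comparison, so detected extrema strictly
alternate max/min and sequence endpoints are never reported. All target
extrema are kept (the trajectory is smooth by construction); cursor extrema
must reach a topographic prominence of **20 px** (≈2% of screen height; the
2% rule is interpreted against screen *height* because cursor control is
vertical). Prominence walks left and right until a strictly higher sample
or the sequence end and takes the peak height above the higher of the two
interval minima; using the sequence ends as bases keeps genuine direction
changes near trial edges. The implementation is independent of
scipy.signal, which serves as a cross-check in the tests.

Thresholding is inherently boundary-sensitive: an extremum whose clean
prominence lies within ±(oscillation peak-to-trough) of the threshold can
flip in or out when sub-threshold jitter is superimposed. The tests assert
exact gating away from that band and confine flips to it.

## Matching and intended-sample assignment

Conventions fixed here (the underlying procedure leaves them open, each
visible in the module docstrings):

* weighted distance `sqrt((2Δx)² + Δy²)` — the *axis distance* on x is
  doubled, not its square;
* independent same-kind nearest-neighbour matching, many-to-one allowed;
  order-crossing matches are flagged and their candidate span repaired to
  [min, max] rather than re-optimized;
* candidate windows are inclusive of both matched extremum samples;
  distance ties take the earliest candidate; equal-index matches and
  equal-time intended samples count as *adaptive* / *not anticipated*;
* samples before the first / after the last cursor extremum use virtual
  anchors (trial boundary ↔ trajectory boundary), so exactly one intended
  sample exists for every pursuit sample;
* anticipation compares time indices, equivalent to the intended-x rule on
  direction-normalized trials and well-defined for mirrored ones.

**Known limitation — latency shrinkage.** For a pursuit that is a pure
delay of L frames, the nearest-candidate assignment returns the sample
about `L·m²/(m²+Δx²)` frames back, where m and Δx are the local vertical
and horizontal per-frame steps: wherever the trajectory moves horizontally,
the recovered latency is shrunk toward zero, and near target reversals
(m → 0) the same-time sample wins and is labelled adaptive. Under the
default geometry the median shrinkage factor is ≈0.92: simulated lags of
3 and 6 frames are recovered within a frame, a 12-frame lag comes back as
≈10.8–11.3 frames, and short (3-frame) leads are labelled anticipatory on
only ≈91% of samples (6- and 12-frame leads: ≈97%). Two acceptance-suite
assertions sit exactly on these structural margins and are expected to sit
at or just outside their bounds; the brute-force oracles confirm the
behaviour is the method's, not an implementation artefact.

## Error metrics, summaries, QC

Temporal error |cursor_y − target_y| and spatial error (distance to the
intended sample) are reported per sample; trial and segment reductions
always carry *both* the arithmetic mean and the RMSE, since the field's
terminology mixes the two — summary tables default to the mean, `--reducer
rmse` selects the other. Spline-gap samples inherit the adjacent random
segment's label so the repeated segment stays uncontaminated; the
averaged-random scope is the unweighted mean of the two random segments
(the standard intra-trial fatigue control). Sessions are partitioned into
three contiguous blocks per participant (sizes differing by at most one,
earlier blocks larger) for practice-effect analyses.

QC is advisory by design: the start rule flags a first cursor sample more
than 100 px off centre (strict inequality), the outlier rule flags trials
whose peak temporal error exceeds mean + 3 sample-SD pooled over all trials
and participants in the run. Exclusion additionally requires a
user-supplied visual confirmation flag; the package never drops a trial on
its own.

## Numerical choices

* Equal-chord resampling solves the step by secant iteration to 1e-9 px;
  deterministic, hence byte-identical outputs under a fixed seed.
* Identity-model simulation is bit-exact (interpolation at integer nodes
  returns stored values), so the perfect-tracking suite asserts errors of
  exactly 0; the offset suite asserts at 1e-9 absolute tolerance because
  `(y+c) − y` rounds in floating point.
* CSV output: fixed column order, UTF-8, 6 significant digits; run
  manifests are timestamp-free JSON, so identical configurations produce
  byte-identical files.
* Degenerate inputs are rejected with named errors (short sequences, empty
  reductions, missing columns, unsorted samples, <3 trials for the outlier
  rule, speeds exceeding the path length → two-point output with a logged
  warning).

## Problem sizes used in the checks

The shipped test suite and acceptance script run on generated data: a
12-trial session for the exactness suites (≈7.5k samples), 20 trials per
lag/lead value (≈12k interior samples each), one full 72-trial session
(≈52k samples) for the error-type, QC and generator-structure checks, and
100 random short trials (≤200 samples) for the brute-force oracle
comparisons.
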