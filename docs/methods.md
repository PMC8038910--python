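# Methods

This note documents the models, parameter choices and numerical decisions
behind `tmpulse`, and what the synthetic-data experiments do and do not
show.

## Signal model

A tympanic-membrane pulsation (TMP) recording is modeled as a train of
cardiac cycles plus respiratory drift and additive white Gaussian sensor
noise.  Each cycle is rendered from a parametric template:

- a **piecewise-linear rise–fall envelope** from the pulse foot (value 0)
  up to the dominant peak at `rise_fraction · cycle_length` and back to 0
  at the next foot.  For the bare envelope the secant slope ratio is
  exactly `SR(r) = -r/(1-r)`, which anchors the generator analytically;
- three **Gaussian sub-peaks** (P1 percussion, P2 tidal, P3 dicrotic)
  superimposed on the envelope.  Their latencies, amplitudes and widths
  are fractions of the cycle.

The rise fraction is the simulator's intracranial-compliance surrogate:
elevated ICP delays the rise and shifts the dominant peak rightward,
lowering SR.  Ground truth records every cycle's foot/peak/end sample and
the template SR of the noise-free cycle, so detector and feature code can
be checked against exact fiducials.

## Maneuver states and default parameters

| state | rise fraction (mean ± per-pulse SD) | sub-peak amplitudes (P1,P2,P3) | truth class | duration |
|---|---|---|---|---|
| upright_baseline | 0.60 ± 0.01 | 0.05, 0.04, 0.03 | normal | 120 s |
| head_down_tilt | 0.85 ± 0.01 | 0.03, 0.05, 0.03 | elevated | 30 s |
| hyperventilation | 0.57 ± 0.01 | 0.05, 0.04, 0.03 | normal | 60 s |
| recovery | 0.60 ± 0.01 | 0.05, 0.04, 0.03 | normal | 120 s |

Sub-peak latencies default to (0.15, 0.45, 0.65) of the cycle with widths
(0.05, 0.06, 0.06).  Remaining defaults: sampling rate 200 Hz; subject
heart rate ~ N(70, 5) bpm (drawn once per subject and reused across that
subject's recordings, clipped to [40, 180]); cycle-to-cycle jitter CV 2%;
per-subject amplitude ~ N(1.0, 0.1); sensor noise SD 2% of the mean pulse
amplitude; respiratory sinusoid 0.25 Hz at 10% amplitude, switching to
0.5 Hz during hyperventilation segments.  Baseline, tilt and recovery
durations follow the experimental protocol (two-minute rests, 30-second
45° inversion); the hyperventilation duration is a package choice, as is
everything the protocol leaves unstated (heart rates, noise levels,
morphology magnitudes — only the direction and ordering of effects is
physiologically constrained).

Two default choices deserve their rationale:

- **Rise fractions are moderate (0.57–0.85), not extreme.**  The
  conditioning filter's 20 Hz upper edge shifts the detected peak of a
  sharp asymmetric corner a few milliseconds early.  The induced SR bias
  scales with that shift divided by the fall duration `(1-r)·T`, so for
  rise fractions near 0.95 the fall lasts well under 100 ms and the bias
  becomes strongly heart-rate dependent — between-subject heart-rate
  differences then dominate baseline SR spread and a threshold trained on
  three subjects cannot cover held-out subjects.  Keeping the fall at
  ~0.4 cycles (baseline) makes the measurement bias sub-dominant to pulse
  morphology jitter.  Hyperventilation sits slightly *above* baseline in
  SR (shorter rise) because hypocapnia lowers ICP below the resting
  baseline; tilt sits far below; recovery equals baseline.
- **Sub-peaks are shoulders, not free-standing local maxima.**  Default
  bump amplitudes are kept below the level at which a bump outgrows the
  envelope slope (≈ `1.65 · width / rise_fraction` in envelope units).
  Larger bumps create their own local maxima, which at low heart rates
  survive the detector's minimum-interval pruning, flood the candidate
  set, drag the median prominence down and split beats.  The morphology
  remains visibly triphasic; it is simply honest about what the detector
  is specified to tolerate.

## Pulse detection

Traces are band-pass filtered with a zero-phase (forward–backward)
4th-order Butterworth, default 0.3–20 Hz: zero phase is required because
group delay would bias the rise/fall asymmetry that SR measures.
Dominant peaks are `scipy.signal.find_peaks` local maxima separated by at
least 0.33 s whose prominence reaches 0.3× the median prominence of all
candidate maxima; feet are inter-peak global minima (earliest sample on
ties); the final peak, lacking a following foot, is discarded.  Detected
pulses therefore tile the covered span, and all indices are invariant to
positive rescaling of the trace.

## Slope ratio, windows, classification

Slopes are two-point secants between fiducials — the simplest reading of
"downslope divided by upslope" and the one with closed-form behavior on
triangular pulses.  Pulses with zero rise or fall duration, or
non-positive upslope, are flagged and excluded rather than patched.
Window averaging tiles non-overlapping 10 s windows from the first
pulse's peak time, assigns each pulse to the window containing its peak,
drops windows with fewer than 3 pulses (no single-beat windows), and never
lets a window straddle a maneuver-segment boundary.  A recording's SR is
the unweighted mean of window means; a recording with no surviving window
raises an explicit *unanalyzable* error and can never silently classify.

The decision threshold is `baseline mean − k·SD` with k = 3 and the
sample (n−1) SD, trained only on upright-baseline recordings of the
training cohort.  A recording is *elevated* iff its SR is strictly below
the threshold; a tie is *normal*, since the threshold bounds the normal
range.  Paired t-tests between maneuvers use the textbook statistic
`t = mean(d) / (SD(d)/√n)` with two-sided p-values from the t
distribution on n−1 degrees of freedom; zero-spread differences are
handled explicitly (all-zero d → t = 0, p = 1; constant nonzero d is
reported degenerate).  Sensitivity and specificity are reported as
not-applicable, never 0 or 100, when a truth class is empty.

## Study replication

The replication simulates a training cohort (3 subjects × 2 rounds) and a
held-out cohort (14 subjects × 1 round), one single-state recording per
(subject, round, state).  Counted states are baseline, tilt and
hyperventilation (18 + 42 = 60 classified recordings, 20 elevated);
recovery recordings are simulated only for the upright-vs-recovery
contrast.  Every recording has its own RNG stream seeded from
(master seed, subject, round, state), so cohorts are order-independent
and the held-out cohort — simulated only after the threshold is fitted —
cannot influence training.  Per-subject contrast values use first-round
recordings for training subjects and the single round for held-out
subjects, pooled over all 17 subjects.

## What passing tests do and do not show

The simulator produces clean, stationary, strongly separated states: it
emulates the *structure* of TMP data (morphology, jitter, drift, noise,
protocol), not its hard parts.  Real recordings add movement artifact,
sensor-seal variation, arrhythmia, non-stationary respiration, and
between-subject morphology differences far larger than the defaults here.
Perfect in-silico classification therefore validates the pipeline's
correctness and internal consistency — not clinical performance.

Two statistical properties of the method itself are worth stating:

- With k = 3 and only six training baseline recordings, the probability
  that a fresh normal recording falls below the fitted threshold is
  ≈ 2% (a Student-t prediction bound, independent of the noise scale).
  Across 100 seeded replications, 82 classified 60/60; the rest had one
  to three baseline false positives within ~0.01 SR of the threshold.
  This is intrinsic to a mean−3·SD rule estimated from six values.
- The upright-vs-recovery contrast is an exact null by construction, so
  its p-value is uniform and "p > 0.05" holds in ~95% of runs by
  definition of the test's size.

## Numerical choices

- Cycle rendering uses `n = round(T·fs)` samples over `[0, T)`; the foot
  is sample 0 and the envelope peak lands on a sample whenever `r·n` is
  integral, which the analytic tests exploit.
- Ties in maxima/minima resolve to the earliest sample; indices are
  0-based; annotation intervals are half-open `[start, end)`.
- Morphology draws are truncated to keep every pulse valid (rise fraction
  in [0.10, 0.985], nonnegative amplitudes, strictly increasing
  latencies).
- Identical (config, seed) pairs give bit-identical traces, ground truth
  and reports.
- Default problem sizes (full 17-subject replication, ~1.3 M samples)
  run in about one second; the 100-replication property checks run in a
  couple of minutes.

## Limitations

No hemodynamic or CSF mechanics (output is in arbitrary sensor units, not
mmHg); no arrhythmia or artifact model; no subject-as-own-control
longitudinal mode; the SR scale is not comparable across sensors or to
values reported from other hardware — only within-protocol comparisons
are meaningful.
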