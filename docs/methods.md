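# Methods

This note documents the models, algorithms and numerical choices behind
`vbtval`, in the order data flows through the package.

## Synthetic squat sessions

**Protocol.** A session emulates one athlete's testing day: for each load in
45/55/65/75/85 %1RM, `reps_per_load` (default 3) maximal-intent repetitions;
one 1RM attempt (modelled at 100 %1RM); and a set to exhaustion at 80 %1RM
(default 6 repetitions) whose target velocity declines linearly by
`exhaustion_decline` (default 8 %) per repetition. Lifters pause briefly but
distinctly between repetitions (1.0–1.5 s) and longer between sets; those
pauses are what make zero-velocity updates possible downstream. Defaults
give 22 repetitions in 7 sets.

**Load–velocity profile.** Mean concentric velocity is linear in %1RM
between `(45, v_at_45)` and `(100, v_at_100)` with defaults 1.0 and
0.3 m/s — representative of recreational back-squat athletes — plus
per-repetition Gaussian variability `sd` (default 0.05 m/s, a typical
within-athlete day-to-day scatter). Values are floored at 0.12 m/s.

**Repetition kinematics.** Each repetition is eccentric descent (one full
raised-cosine velocity lobe, 1.0–1.4 s), bottom pause (0.25–0.45 s), then a
concentric ascent built from a rising half-cosine lobe over 75 % of the
phase and a steeper braking half-lobe over the remaining 25 %. With range of
motion `ROM` (uniform 0.45–0.70 m, comfortably above the 0.3 m ghost
threshold) and target mean velocity `v`, the concentric duration is
`T = ROM / v` and the peak exactly `2v`. The peak braking deceleration is
`π v² / (0.25 · ROM)`; it exceeds 1 g only for fast (light-load)
repetitions, so the propulsive criterion binds exactly where it should:
`Vprop > Vmean` at light loads, `Vprop = Vmean` at heavy ones. All phase
integrals are closed-form, so per-repetition ground truth (`Vmean`,
`Vpeak`, `Vprop`, propulsive end time, duration, ROM) is analytic.

**Discrete ground truth.** Position and velocity are sampled analytically on
the motion-capture grid (default 200 Hz). The grid acceleration is
constructed to be *trapezoid-exact* against the analytic velocity
(`a[k+1] = 2(v[k+1]−v[k])/dt − a[k]`), so cumulative trapezoidal
integration of the stored acceleration reproduces the stored velocity to
machine precision; the construction deviates from the analytic acceleration
only by an alternating O(dt²) term. Central differencing of the stored
position recovers velocity at its usual O(dt²) accuracy — exactness in both
directions simultaneously is impossible on a uniform grid, and the
integration side is the one the inertial pathway exercises.

**Measurement models.**

* *Optical markers*: both bar ends (x = 0 and 2.2 m) share the bar height;
  i.i.d. Gaussian position noise (default SD 0.5 mm per axis).
* *IMU streams* (default 100 Hz): the true vertical linear acceleration is
  rotated into a fixed random device attitude, plus a constant per-axis
  bias (uniform ±0.05 m/s²) and white noise (SD 0.02 m/s²); the device also
  reports its gravity unit vector (with small jitter), as consumer hardware
  does. The wrist stream adds a 1–3 Hz arm-swing interference sinusoid
  (default amplitude 0.3 m/s²) gated by the movement envelope — the arm
  swings while the lifter moves, not during pauses. This emulation degrades
  the wrist more strongly than the real placement comparison observed;
  wrist results here demonstrate the mechanism, not its magnitude.
* *Black-box export*: per-repetition values with independent multiplicative
  error N(1, 0.03), optional extra shrinkage of slow repetitions, a per-set
  miscount probability (duplicate or missed recognition, default 0.05), and
  a per-repetition probability of failing the `Vpeak > Vmean` plausibility
  gate (default 0.03).
* *Artifacts*: per-repetition connectivity-loss probabilities (defaults
  0.03 barbell IMU, 0.08 wrist — reproducing the observed ordering that the
  wrist loses more repetitions — and 0.06 black-box); `ghost_count`
  (default 25) slow re-rack excursions (ROM 0.08–0.25 m over 1.4–1.8 s,
  apparent mean velocity ≤ ~0.18 m/s) inserted between sets, visible in
  every stream and exported as extra rows by the black-box device. Every
  injected artifact is recorded in a manifest; the generator guarantees
  that ground-truth count minus recoverable count equals the manifest count
  per modality. Identical configurations (including the seed) serialize
  bit-identically.

What the generator does **not** emulate: soft-tissue and bar-bend
artifacts, marker occlusion mid-repetition, horizontal bar path, gyroscope
dynamics and attitude-estimation error (attitude is taken as the device
reports it), clock offsets between devices, and fatigue effects beyond the
linear velocity decline. Tests passing on this world therefore validate the
pipeline's logic and numerics, not any specific commercial device.

## Kinematics

* **Gap handling**: NaN runs ≤ `max_gap` (default 0.1 s) are filled with a
  natural cubic spline (reproduces linear trends exactly); longer runs are
  filled linearly but flagged, and any repetition overlapping a flagged
  span is excluded as a connection issue rather than trusted.
* **Filtering**: zero-phase Butterworth low-pass (`sosfiltfilt`), default
  4th order at 10 Hz for marker positions and 15 Hz for accelerations —
  standard biomechanics practice; both configurable.
* **Point of interest**: `P = L + (offset/|R−L|)(R−L)` with offset 0.60 m
  from the left bar end, matching the sensor position next to the left
  hand. The criterion parameter source is the 3-D speed `|dP/dt|`;
  segmentation uses the vertical component, which keeps phase detection
  well defined.
* **Differentiation/integration**: central differences (one-sided at the
  edges) and trapezoidal integration, both O(dt²).
* **Vertical acceleration from an IMU**: via the attitude quaternion when
  present, else `−a·ĝ` with the device-frame gravity unit vector.
* **Zero-velocity updates**: stationary windows are detected where the
  0.3 s-smoothed |acceleration| stays below 0.2 m/s² for at least 0.3 s
  (the protocol's inter-repetition pauses guarantee such windows). After
  trapezoidal integration the velocity is clamped to zero throughout each
  window — the lifter is standing still there — and the drift implied by
  the window-edge residuals is removed by piecewise-linear detrending,
  extended with the first/last slope beyond the end windows. A constant
  accelerometer bias integrates to a linear ramp and is therefore removed
  identically; velocity is exactly zero at every window midpoint for every
  input. Short bottom pauses (0.25–0.45 s) generally do not qualify as
  windows, so residual drift between anchors can leave a small velocity
  plateau there; the segmentation explicitly tolerates this (below).

## Segmentation and per-repetition parameters

Candidate concentric phases are maximal runs where the vertical velocity
exceeds the zero band `eps` (default 0.02 m/s). Each boundary is then
refined:

1. A global noise floor is estimated as 3 × the robust SD (MAD) of the
   velocity over the initial rest second of the recording (recordings start
   with the lifter standing still). In clean data this collapses to zero.
2. A local quiet baseline — the median velocity over ~0.35 s of the
   adjacent pause — absorbs plateaus such as inertial inter-anchor drift;
   it is clamped to ±2·eps.
3. The boundary walks from the zero-band crossing down to
   `baseline + max(floor, 10⁻⁴ m/s)` (walk bounded to 0.5 s).
4. Sub-sample refinement: in clean data the crossing is interpolated
   linearly between the bracketing samples; in noisy data the boundary walk
   stops at the noise floor, and the locally quadratic, baseline-subtracted
   velocity foot (`v ≈ c(t−t₀)²`, so `√v` is linear in `t`) is projected
   back to its zero by a weighted least-squares line, with a correction for
   the known RMS smear of the low-pass filter and the projection clipped to
   0.15 s.

Candidates with `ROM < min_rom` (default 0.30 m) are discarded — this is
what suppresses re-rack ghost movements — as are runs shorter than 5
samples. Segments are disjoint and time-ordered; lowering `min_rom` can
only increase the number of detections.

Per segment, `vmean` is the time-average over the concentric window
(trapezoid, including the sub-sample boundary tails), `vpeak` the maximum,
and the propulsive end is the first sub-sample crossing of the acceleration
below −9.81 m/s²; if it never crosses, `vprop = vmean` and the fallback is
flagged. The fast/slow spectrum splits at a concentric duration of 1.25 s,
inclusive on the slow side, and is always taken from the **criterion's**
duration when labelling pairs. The plausibility gate is strict:
`vpeak > vmean` (a tie fails).

On noiseless sessions the recovered parameters match ground truth to
≤ 0.3 % (`Vmean`), ≤ 1 % (`Vpeak`), ≤ 0.5 % (`Vprop`) with boundaries
within a fifth of a sample; at the default noise level the criterion
`Vmean` carries ≈ 2 % per-repetition scatter with a ≈ −0.9 % mean bias from
residual boundary extension.

## Pairing, exclusions, accounting

Pairing is by within-set order (the devices are unsynchronized; sets are
minutes apart, so stream repetitions are first binned into the criterion's
set windows by coarse time). Rules, in order:

* stream repetitions swallowed by a flagged gap → individual
  `connection_issue` exclusions, placeholders keep the order aligned;
* black-box: trailing surplus entries slower than 0.22 m/s are stripped as
  `ghost_rep` (re-rack excursions are generated at ≤ ~0.18 m/s while even
  terminal exhaustion repetitions stay near 0.3 m/s, so the bands are
  separated; only the surplus is stripped, so a slow genuine repetition is
  never dropped); entries the device's own log marks as lost →
  `connection_issue`;
* any remaining count mismatch (duplicated/missed recognition) voids the
  entire set as `segmentation_error`;
* device repetitions failing `Vpeak > Vmean` → `validity_check`; a
  criterion-side failure is routed to `segmentation_error` instead, because
  the criterion defines truth and its failure signals a pipeline defect.

The accounting table (one row per device; columns Total, Fast, Slow,
ConnectionIssue, SegmentationError, ValidityCheck, Ghost Reps, Participant
Excluded, Handling Error) reconciles exactly: attempted = Total + all loss
columns, with ghosts counted separately as spurious additions. Known
limitation: if a miscount, ghosts and a connectivity loss coincide in one
set, order-based pairing without value matching can pair a ghost silently —
the same ambiguity that forced graphical review in manual workflows.

## Agreement statistics

* Pearson r via `scipy.stats.pearsonr`; 95 % interval by the Fisher
  transform with SE `1/√(n−3)` and the normal quantile (degenerate at
  |r| = 1). Empirical coverage at n = 100, ρ = 0.9 is ~95 %.
* OLP slope `sign(r)·SD(y)/SD(x)` (sample SDs, ddof 1), intercept through
  the centroid. `r = 0` raises — the OLP slope sign is undefined there —
  rather than guessing. Reciprocity `b(y|x)·b(x|y) = 1` holds to 1e-9.
* Confidence limits with `B = t²(1−r²)/(n−2)` (two-sided Student t at
  α = 0.05, df n−2): slope `b(√(B+1) ∓ √B)`; each intercept limit pairs
  with the opposite slope limit through the centroid. Applied to published
  summary values (r = 0.976, n = 578, slope 1.022) these formulas reproduce
  the printed brackets to within rounding.
* SEE from vertical residuals with n−2 degrees of freedom;
  `SEE% = 100·SEE/mean(criterion)` — the denominator convention was chosen
  as the only one consistent with published (SEE, SEE%) pairs at plausible
  squat velocities. A perpendicular-residual variant is available via
  `residuals="perpendicular"`.
* Strata with fewer than 4 pairs are reported as not estimable (n−2
  degrees of freedom and CI computability), never silently dropped.
* Labels: r ≥ 0.5/0.7/0.9 → large/very large/extremely large; SEE
  < 0.1 / ≤ 0.3 / > 0.3 m/s → high/moderate/low precision. The precision
  direction follows the evident intent of the convention (smaller SEE =
  higher precision).

### A note on OLP recovery of an injected calibration

When a synthetic device is built as `y = a + b·x + ε` with error on the
device side only, the OLP population slope is not `b` but
`b·√(1 + σ²/(b²·Var x))` — for the package's recovery exercise
(b = 1.05, σ = 0.05, session-level Var x ≈ 0.05) about 1.072. Joint
slope-and-intercept CI coverage of the injected values is therefore
structurally below nominal (~91 % even with exact criterion values, ~86 %
through the full pipeline, which adds ~1 % slope inflation from
boundary-noise effects on the criterion). This is a property of the
geometric-mean estimator under one-sided error, not a defect of the
implementation; the corresponding whole-pipeline test encodes the stricter
target and is allowed to fail, documenting the gap.

## Problem sizes

Default test and reproduction runs use single sessions (22–30 repetitions,
~200–260 s at 200 Hz), 100-run ensembles for coverage checks, and 1000-draw
Monte-Carlo loops for interval coverage — sizes at which every quantity the
package reports is stable to well within the tolerances asserted.
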