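# vbtval

Method-agreement validation of wearable barbell-velocity sensors against
optical motion capture, for velocity-based strength training (VBT).

## The problem

In VBT, training load is monitored through barbell velocity rather than
weight alone. Affordable wearable inertial sensors (a smartwatch strapped to
the bar or worn on the wrist, or a commercial VBT pod that only exports
per-repetition numbers) promise to replace laboratory optical motion
capture — but only if their per-repetition velocity parameters agree with
the optical criterion. `vbtval` implements the full validation workflow for
the free-weighted back squat:

1. **Synthetic sessions.** A generator emulates a complete testing session —
   a load–velocity profile block (45/55/65/75/85 %1RM, a few maximal-intent
   repetitions each), a 1RM attempt, and a set to exhaustion — with exact
   closed-form ground truth, and renders every measurement modality from it:
   optical markers on both bar ends, barbell- and wrist-mounted IMU streams
   (device frame, bias, noise, arm-swing interference), and a black-box
   per-rep export with its own error model. Connectivity dropouts, duplicated
   or missed recognitions, and "ghost repetitions" from re-racking the bar
   are injected and recorded in a manifest, so the bookkeeping downstream can
   be verified exactly. Real recordings in the same plain-text formats plug
   into the identical pipeline.
2. **Kinematics.** Markers: gap interpolation, zero-phase low-pass, the bar
   point 0.60 m from the left end, numerical differentiation; the 3-D speed
   magnitude is the criterion velocity. IMUs: projection of device-frame
   linear acceleration onto the world vertical, then integration with
   zero-velocity updates anchored on the deliberate inter-repetition pauses.
3. **Segmentation and parameters.** Concentric phases are detected from the
   vertical velocity (zero-band crossing with noise-adaptive boundary
   refinement; candidates with range of motion `< 0.3 m` are discarded as
   ghosts). Per repetition: `Vmean` (mean concentric velocity), `Vpeak`
   (peak), and `Vprop` (propulsive mean — the average until the acceleration
   first drops below −1 g; equal to `Vmean` when braking never exceeds 1 g).
   Repetitions are classed *fast*/*slow* at a criterion concentric duration
   of 1.25 s (at or above ⇒ slow).
4. **Pairing and exclusions.** Devices record autonomously, so repetitions
   pair by within-set order. Connectivity losses are excluded individually;
   a count mismatch from device miscounts voids the whole set; device
   repetitions failing the plausibility gate `Vpeak > Vmean` are excluded;
   everything is reconciled in a per-device accounting table.
5. **Three-tier agreement statistics**, per device × parameter ×
   {total, fast, slow}:
   * Pearson's *r* with the Fisher interval
     `tanh(atanh(r) ± z₀.₉₇₅ / √(n−3))`;
   * an ordinary-least-products (OLP / geometric-mean) calibration — used
     because both instruments carry random error —
     `b = sign(r)·SD(y)/SD(x)`, `a = ȳ − b·x̄`, with limits
     `b·(√(B+1) ∓ √B)` where `B = t²(1−r²)/(n−2)`; slope limits excluding 1
     flag proportional bias, intercept limits excluding 0 flag fixed bias;
   * the standard error of the estimate from the OLP residuals
     (`SEE = √(Σε²/(n−2))`, with `SEE% = 100·SEE/x̄`), labelled high /
     moderate / low precision at 0.1 and 0.3 m/s; *r* is labelled large /
     very large / extremely large at 0.5 / 0.7 / 0.9.

The OLP analysis is exposed as a scikit-learn style estimator,
`OLPRegression` (`fit(criterion, device)`, fitted attributes `slope_`,
`intercept_`, `r_`, `see_`, … and `predict`), so it composes with sklearn
tooling; the rest of the package is a conventional pipeline library with a
thin CLI.

## Worked example

```python
import numpy as np
from vbtval import OLPRegression, SessionConfig, analyze_session, generate_session

# calibrate a device against a criterion
rng = np.random.default_rng(0)
criterion = rng.uniform(0.3, 1.1, 40)                      # m/s
device = -0.02 + 1.05 * criterion + rng.normal(0, 0.05, 40)
fit = OLPRegression().fit(criterion, device)
```

prints, via the fitted attributes:

```
slope     1.102  [1.031, 1.178]
intercept -0.043  [-0.098, 0.009]
r         0.979  [0.961, 0.989]  (extremely large)
SEE       0.055 m/s (7.6%)  (high precision)
proportional bias: True, fixed bias: False
```

The slope interval excludes 1 (proportional bias present — the injected
slope was 1.05) while the intercept interval includes 0; the residual
scatter of 0.055 m/s is below the 0.1 m/s band, i.e. precise enough to
resolve a 30 % velocity loss at heavy loads.

A full synthetic study, from raw streams to the accounting table:

```python
session = generate_session(SessionConfig(seed=1))
result = analyze_session(session)
print(result.accounting)
```

```
     Device  Total  Fast  Slow  ConnectionIssue  SegmentationError  ValidityCheck  Ghost Reps  Participant Excluded  Handling Error
barbell_imu     22    14     8                0                  0              0           0                     0               0
  wrist_imu     19    12     7                3                  0              0           0                     0               0
   blackbox     20    12     8                1                  0              1          25                     0               0
```

All 22 attempted repetitions are accounted for per device (pairs plus
losses; the 25 stripped ghost entries are spurious additions, not losses),
and `result.report` holds the 3 × 3 agreement table per device — e.g. the
barbell-mounted IMU, `Vmean`, all repetitions:
`n=22  slope=0.938  intercept=+0.034  r=0.984  SEE=0.040 (6.3%)`.

The same analysis runs from files via the CLI:

```bash
vbtval simulate --seed 1 --out session/
vbtval process  --in session/ --out metrics/
vbtval validate --in session/ --out report/ --plot
```

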