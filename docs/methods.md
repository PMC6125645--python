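# Methods

`skifuse` estimates the absolute 3D center-of-mass (CoM) trajectory and
speed of an alpine skier from body-worn inertial sensors alone, without
any GNSS on the athlete.  Position drift from double-integrating
acceleration is corrected with sparse absolute position *anchor points*:
the surveyed positions of gate magnets, whose crossing times are detected
as peaks in the field norm of a sacrum-mounted magnetometer.  This note
records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Frames and conventions

All global frames are right-handed with Y up; gravity is
`(0, -g, 0)` with `g = 9.81 m/s^2` (configurable).  The inertial frame
`J` has X along the athlete's forward direction in the still posture at
the start, with its origin at the initial sacrum position and azimuth
defined as zero there.  The survey frame `G` holds the gate coordinates;
`J` and `G` share the vertical axis, so the transform between them is an
azimuth rotation `alpha` about Y plus a translation `o`, both estimated
by anchor matching.  A segment rotation maps segment-frame coordinates to
global coordinates.  The sacrum sensor is identified with the lumbar
joint center (LJC) throughout, so "sacrum trajectory" and "LJC
trajectory" are interchangeable.

## Processing chain

1. **Calibration surrogates.**  Static start/finish windows are detected
   from the joint rolling variance of the gyroscope *and* accelerometer
   (a quiet gyroscope alone cannot distinguish standing still from a
   straight-line speed ramp).  The gyroscope bias is the mean over the
   start window.  The sensor-to-segment rotation is the minimal rotation
   mapping the mean static specific force to the segment's longitudinal
   axis; for single-axis mounting tilts this recovery is exact and
   introduces no azimuth twist.
2. **Strap-down orientation.**  First-order quaternion exponential
   integration per sample (rate assumed constant over each 2 ms step).
   Inclination is steered toward the accelerometer gravity direction by a
   complementary correction with a 30 s time constant, gated to samples
   whose specific-force magnitude is within 5% of g.  The original
   processing chain delegates orientation drift reduction to a dedicated
   external procedure; this gated correction plays that role and leaves
   the residual drift to the smoother's three drift states.  A shorter
   time constant with a wide gate (10 s / 15%) was rejected: whenever the
   specific-force magnitude transits through g mid-turn its *direction*
   is not vertical, and the injected motion-correlated inclination error
   dwarfs the drift-state model.
3. **15-state smoother.**  States: position, velocity, acceleration
   (each 3D), a 3D position offset, and 3 small Euler angles of residual
   orientation drift.  Constant-acceleration transitions driven by white
   jerk; measurements are (i) the gravity-corrected global acceleration
   at every sample, with the drift angles entering through the lever
   `z - g_vec` (gravity leakage dominates the effect of orientation
   error), (ii) zero velocity during the static windows, (iii) sparse
   position anchors observing position plus the offset states.  The
   drift-angle Jacobian is evaluated at the *measured* acceleration,
   which makes the filter exactly linear given the data; forward
   filtering (Joseph-form updates) plus RTS backward smoothing is then
   the exact MAP estimate, a property verified against an independent
   sparse information-form solve.
4. **Relative anchor estimation.**  Ski-snow contact points sit 0.15 m
   distally of each ankle along the shank axis; their midpoint forms the
   ski line, and a total-least-squares plane through the ski line within
   ±0.4 s of each crossing models the local snow surface.  (Principal
   component, not vertical regression: on steep slopes vertical
   least squares is biased.)  The sacrum-to-magnet distance comes from
   the peak field norm via the two-segment linear calibration
   `r = -0.4 B + 1.0 (B < 1.62)`, `r = -0.062 B + 0.452` otherwise; the
   sacrum is projected onto the snow plane and the remaining lateral leg
   lies in the plane, perpendicular to the velocity, on the side given by
   the turn direction (sign of the sacrum angular velocity along the
   trunk axis; ties break to "left").  When the calibrated distance is
   shorter than the plane distance — possible because the 125 Hz
   magnetometer under-samples the peak — the lateral leg is clamped to
   zero and the crossing flagged.
5. **Matching.**  The azimuth is the angle between the first horizontal
   principal components of the surveyed and estimated anchor clouds, both
   oriented start-to-finish.  Stage one matches on neighbour-difference
   features plus a left/right label and a turn number; stage two, after
   applying the azimuth and the component-wise median offset, on absolute
   positions plus the same labels.  Matches sharing a surveyed gate are
   removed.  Turn numbers start at one at the first detection and a
   direction that violates alternation increments the number by two (a
   missed gate is assumed).
6. **Two fusion passes.**  Pass 1 fuses matched anchors at 1 m sigma;
   anchors are then re-estimated from the refined trajectory, re-matched
   with absolute-position features, and fused again at 0.1 m sigma.  The
   final CoM adds the azimuth-aligned body-model CoM offset to the
   refined sacrum trajectory; CoM speed is the three-point derivative,
   and both are zero-phase low-pass filtered (2nd-order Butterworth,
   5 Hz).  Zero-phase filtering is a deliberate choice — the comparison
   against a reference trajectory is sample-by-sample, so phase lag would
   masquerade as position error; the causal single pass remains available.

## Key parameters

| parameter | default | rationale |
| --- | --- | --- |
| jerk PSD | 50 (m/s³)²/Hz | covers the ~80 m/s³ peak jerk of 2.5 g turn sequences at 0.4 Hz |
| drift-angle random walk | 5e-6 rad²/s | residual strap-down drift after the complementary correction |
| position-offset random walk | 1e-8 m²/s | near-constant bias absorber; keeps the offset identifiable |
| accelerometer measurement sigma | 0.03 m/s² | sensor noise (0.015) plus linearization slack |
| ZUPT sigma | 0.01 m/s | static postures are genuinely still |
| anchor sigma, pass 1 / pass 2 | 1 m / 0.1 m | reflects relative-anchor quality before/after refinement |
| anchor innovation gate | 5 sigma | rejects spurious detections without aborting |
| detection threshold / peak separation | 1.05 / 1 s | field norm is 1 far from magnets; gates are >1 s apart |
| matching weights: left-right, turn number | 10 m, 1 m | a direction disagreement must override geometry (20 m); the turn number must not. A spurious detection that breaks alternation shifts all later numbers by two while *preserving* direction parity, so a heavy number weight drags the tail of the course onto gates two positions away — the number feature is a tie-breaker only |

The smoother parameters were chosen by coarse reasoning about the
dynamics and checked on the simulator; they are stored in `EKSConfig` and
are not per-run tuned.

## The simulator

The synthetic module plays the role of a field campaign and of the
reference measurement system.  It generates a ~30-gate giant-slalom
course on an inclined plane (700 m, 150 m drop, 3D gate spacing drawn
from 21.8–27.8 m, gates alternating ±3 m around the center line, the
whole course rotated by a seeded azimuth), threads a C² spline through
waypoints offset 0.3 m laterally outward of each gate, and drives it with
a smooth speed profile (cubic-smoothstep ramps, 20 m/s cruise, ≥2 s
static postures at both ends).  The lean angle follows the quasi-static
balance condition `atan(a_lat / g)`; the LJC rides above the snow plane
by the leg extent foreshortened with the lean.  Posture is a 7-segment
chain with fixed hip/knee flexion plus a lean-proportional differential
knee flexion (the inside leg flexes more); this angulation is what makes
the equal-ankle-distance turn-switch criterion observable — a perfectly
rigid posture keeps both ankle-to-CoM distances constant.

Two constructions make round-trip tests exact rather than approximate:
ground-truth sacrum kinematics are *defined* by trapezoid integration of
the (4th-order finite-difference) acceleration samples, so noise-free
re-integration reproduces the truth to ~1e-10 m; and the synthetic gyro
signal is the per-step rotation increment of the orientation timeline, so
noise-free strap-down integration is exact.

The magnet field norm follows a dipole power law `1 + c / max(r, r_min)^3`
with `c = 0.03`, `r_min = 0.1 m`, sampled at the native 125 Hz (deliberately
under-sampling fast passes).  `c` sits near the least-squares optimum for
consistency with the piecewise-linear distance calibration over
r in [0.2, 0.6] m; the calibration's first branch saturates at 0.6 m, so
consistency beyond that range is not attainable and distances of wide
passes are systematically underestimated — small gate distances come out
too long and large ones too short.  With `c = 0.03` the field exceeds the
1.05 detection threshold out to ≈0.8 m, so the first and last gates
(passed wide, at low lean) are usually missed — the matching stage is
exercised on realistic inputs by construction.

Default sensor noise: accelerometer 0.015 m/s², gyroscope 0.003 rad/s
white noise per 500 Hz sample, 0.01 rad/s constant gyro bias (removed to
first order by the static calibration), magnetometer 0.005 normalized
units at 125 Hz.

**What passing tests do not show.**  The simulator's orientation errors
are mild (exact synthesis plus small gyro noise/bias), its snow surface
is a perfect plane, the gate survey is error-free, posture is rigid up to
the lean/angulation model, and sensors never saturate or lose sync.
End-to-end errors on synthetic runs (~0.05–0.09 m mean CoM position,
~0.03 m/s speed RMSE) are therefore noticeably better than what the same
processing achieves on real snow; they demonstrate the correctness of the
estimation machinery and the qualitative behaviour (drift without
anchors, degradation with anchor thinning), not field accuracy.

## Validation machinery

Errors are decomposed per sample in the local skiing frame built from the
reference velocity (x along the velocity; z = x × up; y = z × x — the
frame is built from the *upward* vertical so that y points up-ish).
Per-run accuracy/precision are the mean/standard deviation of an error
signal; overall values average the per-run ones rather than pooling
samples.  The total speed error is the difference of speed norms, while
per-axis speed errors rotate the velocity-difference vector into the
skiing frame; the axis components therefore need not recombine into the
total, mirroring the asymmetry of the two definitions.  Turn performance
parameters (v_in, v_out, d_in, d_out, d_cross, l_tot) are taken at the
turn switches detected from the equal-ankle-distance criterion, and
method agreement is summarized with Bland–Altman 95% limits of agreement
(mean ± 1.96 sample standard deviations, n−1 denominator).

Downhill gate spacing is emulated by keeping only every third surveyed
gate as an anchor in the fusion (detection and matching are unchanged).

## Numerical notes and limitations

* The smoother is soft-constrained: with exactly consistent inputs it
  reproduces an analytic double integral to the millimetre, not to
  machine precision — acceleration steps carry a finite jerk cost, and
  the white-jerk model injects a direct position-noise channel of
  `sqrt(q dt^5 / 20)` per step.  The exact-MAP property is instead
  verified against an independent batch solve (relative agreement
  ~1e-7 on bounded-horizon instances).
* Anchor updates snap to the nearest 500 Hz sample; gate-crossing times
  are native 125 Hz peak samples, so each anchor carries an along-track
  error of up to ~0.08 m at race speed.  This, plus the saturating
  distance calibration, dominates the synthetic error budget.
* The turn-number "+2 on alternation violation" rule mis-numbers
  everything after a spurious detection; the matching survives because
  the direction labels keep parity and the number feature is weighted as
  a tie-breaker (see table above).
* Degenerate geometry (calibrated distance shorter than the snow-plane
  distance) collapses the lateral anchor leg to zero; the crossing is
  flagged and the anchor sigma absorbs the error.
* Plane fitting needs a non-collinear ski-line window; straight-line
  gliding sections would degrade it, but gates sit in curved sections by
  construction.
* Multi-magnet gate layouts, vector (non-norm) use of the magnetic
  field, real-time/causal filtering and GNSS fusion are out of scope.
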