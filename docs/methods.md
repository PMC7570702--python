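# Methods

This note documents the models, algorithms and numerical choices behind
`turnkit`, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Sensor model and conventions

Each location carries a 9-DOF IMU: tri-axial accelerometer (g), gyroscope
(deg/s) and magnetometer (Gauss), nominally 128 Hz. All internal arrays
are ordered (VT, AP, ML) — vertical, anterior–posterior, mediolateral;
the session sidecar declares how physical sensor axes map onto these,
including sign flips, and the loader applies the mapping once. Yaw ψ is
the rotation angle about VT; positive is counter-clockwise viewed from
above and a **left turn is negative** by convention, so the sign of a turn
angle encodes its direction. Time is 0-based seconds at the session
origin; events are half-open intervals [start, end).

## Yaw estimation

**Upper body (HD, C7, L5).** These segments are still for long stretches,
so the gyroscope bias is observable: the per-axis bias is the mean over
the window (default 2 s) with the minimum moving variance of the gyro
magnitude, provided that variance is below 4 (deg/s)²; otherwise the
whole-trace median is used with a warning. Yaw is the cumulative
trapezoidal integral of the corrected ω_VT. With a stable constant bias
this leaves only the integrated white noise (random walk ~ σ·√(t/fs), a
fraction of a degree over a minute at σ = 0.5 deg/s); an optional
zero-phase high-pass (0.02 Hz, off by default) exists for recordings with
slow bias wander. A residual bias error of ε deg/s grows to ε·t degrees of
yaw over t seconds — this bounds the bias-invariance tolerance used in
tests.

**Ankles (LA, RA).** Feet move too fast for still-window bias estimation,
so ankle yaw comes from a gradient-descent quaternion fusion filter of
the Madgwick family: the quaternion is propagated by the gyro and pulled
toward the directions implied by gravity (accelerometer) and the earth's
magnetic field (magnetometer, constrained each step to the earth x–z
plane) with gain β = 0.1. Yaw is extracted from the quaternion, unwrapped
across ±180°, re-zeroed at the trace start; its time derivative serves as
the vertical angular velocity for segmentation. Without a magnetometer the
filter degrades to gravity-only (6-DOF) correction with a warning —
heading then relies on the gyro alone, which is acceptable over turn
timescales. The filter contract is behavioural, asserted in tests: a
noiseless 90° rotation recovered within 2°, under 5° of drift over 60
stationary noisy seconds, and bit-for-bit determinism.

## Turn detection

Movement about VT is segmented at zero-crossings of ω_VT. A deadband
(default 5 deg/s; configurable to 0 for the literal rule) decides the
sign: |ω| below it counts as zero, which prevents noise from shredding
segments. A numerical epsilon (1e-6 deg/s) backs the deadband=0 case so
float residue from bias subtraction cannot register as rotation. Segment
boundaries are placed half a sample outside the first/last in-band
sample, since the true crossing lies between samples; each segment
carries its yaw displacement.

Gradual-turn merging: consecutive same-direction segments, each
exceeding 10°, separated by gaps shorter than 0.5 s, merge into one turn
whose angle is the sum of sub-angles (sub-turns are retained). The gap is
measured end-to-start; segments at or below 10° are treated as jitter —
they neither merge nor break a chain. The operation is idempotent.
Acceptance thresholds: |θ| ≥ 90° at L5, ≥ 30° elsewhere; 0.5 s ≤ duration
< 10 s (≥ / < at the stated boundaries).

Inner/outer ankle roles remove turn-direction bias: a right turn makes
the right ankle *inner* and the left *outer*, and vice versa. Step
counting inside a turn window (padded by 0.5 s, since ankle rotation can
lag the trunk) counts each same-sign rotation ≥ 30° in the turn's
direction. Steps deliberately use the raw zero-crossing segments, not the
merged ones: successive steps are separated by stance pauses shorter than
the gradual-turn gap, and merging would fuse them into one rotation.

## The 425-feature schema

The manifest (`turnkit.features.feature_manifest`) is the single source
of truth for feature identity and column order; its counts — 21
spatiotemporal + 88 signal-based per upper-body location (327 total), 9 +
40 per ankle role (49 each), 425 overall — are asserted in tests. The
per-ankle signal set covers the overall phase only (both sensors × 4 axes
RMS, plus 4 jerk and 4 angular-acceleration statistics × 4 axes): ankle
activity inside a turn is a burst of discrete steps, so start/mid/end
splits of the window are not stable quantities there.

Spatiotemporal characteristics summarise turn events: counts (total,
left, right), turn time and |angle| (mean/min/max/variability), angular
velocity θ/T in deg/s, peak angular frequency max|ω_VT| in rad/s, and the
mean of |ω_VT| over 0.1 s windows anchored at the turn start, midpoint
and end (rad/s). *Variability* is the sample SD across turns (defined as
0 for a single turn rather than NaN so single-turn sessions stay usable).

Signal-based characteristics are computed per turn window and averaged
over turns. Each axis is processed per window: linear least-squares
detrend, then a zero-phase (forward–backward) 4th-order Butterworth
low-pass at 20 Hz — zero-phase so event timing is not shifted; the
resultant R = √(VT²+AP²+ML²) is formed after filtering. RMS statistics
use the detrended signal. Jerk (da/dt, g/s) and angular acceleration
(dω/dt, rad/s², gyro converted to rad/s) are central differences of the
*filtered but not detrended* signal: removing a linear trend would remove
exactly the rate-of-change these statistics measure (a constant-slope
acceleration ramp must yield jerk equal to its slope, which is the
closed-form oracle the tests pin). Phase windows for signal statistics
default to equal thirds of the turn; a 0.1 s anchored-window mode is
configurable. Windows shorter than 3 samples are skipped with a warning.
Missing locations produce NaN features, never silent zeros.

## PLS-DA classification

Labels are dummy-coded PD = +1, control = −1; prediction is the sign of
the PLS regression output, with a tie at exactly 0 assigned to control.
The core PLS fit is scikit-learn's NIPALS `PLSRegression`; everything
around it is this package's: constant/all-NaN columns are dropped,
features are standardized and NaNs mean-imputed **inside each training
fold only** (the choice of per-fold rather than global standardization is
deliberate: it cannot leak the held-out subject), and the number of
components k is selected by the cumulated Q² rule — Q²(k) = 1 −
PRESS(k)/SS with PRESS from leave-one-out at each k, keep adding
components while Q² increases and stays positive; if even Q²(1) ≤ 0 the
model keeps one component and is flagged. Truncating the x-rotations of a
K-component fit reproduces the k < K sub-models (P'W is upper
triangular), which makes the per-component PRESS affordable.

VIP_j = √(p · Σ_k SSY_k w_jk² / Σ_k SSY_k) with unit-norm weights w_k and
SSY_k = ‖t_k‖²q_k²; the mean squared VIP over features is identically 1,
asserted to 1e-8. Cumulative per-component VIP profiles are available for
"VIP > 1.5 in any component" screening. Leave-one-out evaluation refits
everything on n−1 subjects and reports accuracy, sensitivity (PD
positive) and specificity from the pooled confusion counts.

## Agreement statistics

ICC(2,1) — two-way random effects, absolute agreement, single measures —
is computed from the ANOVA mean squares:
(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)), k = 2 raters.
Limits of agreement follow Bland–Altman: bias ± 1.96·SD of the paired
differences (1.96, not 2, by the standard convention), with the
percentage form dividing by the mean of the pairwise averages. Event
series are matched 1:1 greedily by nearest start within a tolerance
(default 2 s); unmatched events are excluded and counted. Multi-session
comparisons match within each session and pool the matched pairs. The
group comparison runs Shapiro–Wilk per group per feature and uses a
t-test when both groups look normal (p > 0.05), Mann–Whitney U otherwise;
no multiple-testing correction by default (a Benjamini–Hochberg option
exists but is off), and z-scores are taken against the pooled mean/SD.

## Synthetic data: what it emulates and what it does not

The simulator emulates the intermittent-walk protocol: initial stillness
(3 s, which gives the bias estimator its window), then walk (6 s) → turn
→ wait (2 s), repeated. Turn angles ~N(180°, 10°), durations ~N(2.5 s,
0.7 s) control-like or N(3.5 s, 1.0 s) PD-like, random direction. Upper-
body yaw per turn is a minimum-jerk S-curve — chosen because its endpoint
velocity is exactly zero, making ground-truth boundaries kinematically
sharp; onsets stagger head → neck → lower back by 0.15 s per segment
(control-like) or 0 (en-bloc, PD-like). Ankle yaw is the turn angle split
into 2–5 discrete per-step minimum-jerk rotations (3 ± 1 control-like,
5 ± 1 PD-like) separated by stance dwells, the two ankles half a step out
of phase. Gyro = analytic yaw rate + constant per-axis bias (0.5, −0.2,
0.3 deg/s) + white noise (0.5 deg/s); accel = gravity + a
double-frequency (2 Hz) vertical oscillation during walking (0.12 g upper
body, doubled at the ankles) + noise (0.02 g); mag = a constant earth
field rotated by the current yaw + noise (0.005 Gauss). Cohorts add
subject-level jitter (SD 0.25 s on duration mean, 0.5 on step count) so
between-subject variance exists on top of turn-to-turn variance. All
randomness flows from one seeded generator.

Not emulated: roll/pitch dynamics at any segment (ankle gravity stays
nominal — enough to exercise yaw fusion, not tilt tracking), freezing
episodes, turns initiated from standstill, magnetic disturbances, soft-
tissue artefact, or biomechanically validated full-body kinematics.
Passing tests therefore demonstrate that the algorithms implement their
definitions correctly and recover known ground truth under realistic
noise — not that the classifier's synthetic-cohort accuracy transfers to
any clinical population.

## Problem sizes and numerical choices

Test and acceptance runs use: 3 turns/session, 50 seeded sessions for
noisy boundary recovery, 10 + 10 subjects for cohort classification, 100
permutations for the chance-level check, 20 repetitions for VIP recovery,
and 10,000 null features for type-I calibration — sizes chosen so the
statistics of interest (medians, rates) are stable at the stated
tolerances. Degenerate inputs are handled explicitly: motionless traces
yield zero segments; zero accepted turns yield all-NaN features with
n_turns_used = 0; zero-variance ICC tables and zero grand means return
NaN with warnings; LOO folds with a single training class are fatal.

## Known limitations

Upper-body yaw integrates the sensor-frame vertical gyro component as
mapped by the sidecar, not the vertical component in a gravity-aligned
frame; for near-upright trunk sensors the difference is second order, but
severe stooped postures would bias the turn angle. The 30°/90° thresholds
and the 10°/0.5 s merge rule are fixed conventions of the detection
definition, configurable but not auto-tuned. The per-ankle 49-feature
split (9 + 40) is a pinned schema decision; the phase-resolved ankle
statistics it omits are exactly the ones unstable under stepping. LOO
evaluation with a fixed component count inherits that count from the
full-data selection unless per-fold selection is requested explicitly.
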