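# Methods

This note documents the models, conventions and design choices behind
`gaitbox`, in the spirit of a model-description chapter: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Frames, rotations and units

The world frame is right-handed with **X mediolateral** (subject's right
positive), **Y vertical** (up) and **Z anteroposterior** (direction of
progression positive).  All rotations are 3×3 proper orthonormal matrices
(orthonormality and determinant checked to 1e-9 where asserted); IMU
quaternions are scalar-first unit quaternions, renormalised when their norm
deviates from one by less than 1e-3 and rejected beyond that.  Angles are
degrees, lengths centimetres, time seconds throughout.

Joint angles use the intrinsic ("rotating-frame") **x–z–y Euler order**:
for a bone whose local frame coincides with the world frame in neutral
stance, the X component is flexion–extension, the Z component tilt or
ab/adduction, and the Y component axial rotation.  The decomposition's
principal ranges are x, y ∈ (−180°, 180°] and z ∈ [−90°, 90°].  Within
0.01° of the gimbal singularity (|z| = 90°) the x and y rotations merge;
the tie is broken by folding everything into x and reporting y = 0, with a
flag.  With the world X axis pointing to the subject's right, forward
flexion of a downward-hanging segment is a *negative* X rotation; the
anatomical "hip flexion–extension curve" used for event detection is
therefore the negated X component (one function, `hip_flexion_curve`).

IMU fusion frames are gravity-referenced with Z up; they are mapped to the
Y-up world convention by a fixed cyclic axis permutation applied once at
ingestion (`rotations.from_zup`), recorded in the capture header.

## Human model

The skeleton is a 20-bone hierarchy rooted at the pelvis (pelvis →
thorax → neck → head and arms; pelvis → thighs → calves → feet → toes), of
which 15 bones can carry a device; gait analysis uses eight (pelvis,
thorax, both thighs, calves and feet).  Each bone's local frame is aligned
with the world frame in the neutral standing pose, so neutral bone
rotations are the identity and the geometry lives in per-bone offset
vectors (the bone origin, i.e. its proximal joint centre, in the parent
frame).

In IMU mode all segment lengths scale linearly with standing height using
a classical segment-proportion table (thigh 0.245·H, shank 0.246·H, foot
length 0.152·H, ankle height 0.039·H, …, chosen so the chain sums exactly
to the stature); hip-joint spacing is 0.77 of the measured iliac-crest
width and shoulder spacing 0.40 of the elbow span.  In optical mode the
lower-limb joint centres come from pointer-measured landmarks (acromions,
greater trochanters, external malleoli, iliac crests); the knee divides the
trochanter–malleolus distance in the thigh:shank proportion of the table.
These simplified proportion-based placements stand in for the fuller
regression equations used in clinical practice; they are linear in the
measured inputs and documented in one table in `skeleton.py`.

Forward kinematics places each bone origin at
`parent origin + R_parent · offset`, with absolute (not composed) bone
rotations supplied per bone — matching a system in which every segment's
orientation is measured independently.  Bone lengths are preserved by
construction; the property suite asserts this to 1e-9.

## Anatomical calibration (magnetometer-free heading recovery)

Each magnetometer-free IMU fuses gravity and gyroscope data, so its fusion
frame shares the true vertical but has an arbitrary, sensor-specific
heading.  The calibration assumes that in the static neutral pose one
designated axis of each sensor (X or Y, per body part) lies parallel to
the ground at a known angle from the pelvis sensor's projected Y axis: 0°
for the chest and feet, 90° for head, thighs, calves and arms.  The
printed body-part table gives unsigned angles; internally the expected
angles are signed per device (left and right mountings point in opposite
lateral directions), preserving the printed magnitudes.

The correction angle is `α = expected − measured`, wrapped to
(−180°, 180°], where `measured` is the signed ground-plane angle between
the two projections, each read naively in its own frame.  An assumed axis
measured within 1° of vertical raises a calibration-pose error (the device
is mis-mounted).  The correction matrix is a rotation about the vertical
axis.

One additional anchoring step keeps the shared frame anatomical: the
pelvis sensor itself has an arbitrary heading, and correcting all other
sensors *relative to it* would leave every reported rotation conjugated by
an unknown yaw, mixing the X and Z Euler components of tilted segments.
Since the pelvis sensor is mounted on the sacrum with its Y axis along the
subject's mediolateral direction, the calibration yaws the whole shared
frame so that this projected axis coincides with the world X axis.  Under
ideal mounting the tracked frame then *is* the subject's anatomical frame;
mounting error enters as a small global yaw, as it does for a physical
system.  (The heading-invariance property — a common yaw applied to all
streams leaves all results unchanged — is tested.)

The sensor-to-bone rotation computed at the calibration instant is held
constant for the session: the device is assumed not to move on its
segment.  Calibration uses a single frame by default (the "instant 0"
reading); an optional averaging window (quaternion mean over e.g. 0.5 s)
is available behind a flag.  Optical clusters are already expressed in the
common camera frame, so their heading correction is the identity and their
sensor-to-bone link is read directly.

Drift is *not* corrected: the intended protocol recalibrates before each
short capture.  The simulator can inject drift so its effect is
measurable; the test suite confirms tracking error then grows roughly
linearly with time and is absent otherwise.

## Tracking

Per frame, bone orientation is `R_bi^G = R_si^G (R_s0^b)ᵀ` and the
parent-relative rotation `(R_pi^G)ᵀ R_bi^G` (the pelvis, as root, reports
its absolute rotation); joint angles are the Euler decomposition of the
relative rotation.  At the calibration frame all joint angles are zero by
construction (asserted to 1e-6).

Positions: optical mode reads each bone origin from its cluster's
translation.  IMU mode uses forward kinematics from a root pose; sensors
do not measure translation, so the root trajectory must be supplied — the
capture format carries an optional pelvis translation channel (the
simulator provides a kinematically consistent one).  Without it the root
stays at the origin and only translation-invariant quantities (step
length/width, supports, angle ranges) are meaningful; over-ground gait
speed and stride length require the channel.

Stream dropouts up to 0.1 s are interpolated (slerp on quaternions, linear
on translations); longer gaps are an error.

## Event detection

Six events per stride and side: T1 initial contact, T2 contralateral
toe-off, T3 mid-single-support reference, T4 contralateral initial
contact, T5 toe-off, T6 next initial contact, with the ordering invariant
T1 < T2 ≤ T3 < T4 < T5 < T6 enforced (violating strides are flagged
invalid, never reordered).

Curves: hip flexion–extension of both legs (IMU; depends only on the
pelvis and thigh sensors, the shortest error chain) or anteroposterior
ankle-centre displacement of both feet (optical treadmill; every cluster
is independently accurate).  Whether "anteroposterior" or vertical ankle
displacement is used is configurable; anteroposterior is the default
because its extrema are sharply defined on a treadmill.

The mapping from extrema to events: T1/T6 at ipsilateral flexion maxima
(anterior maxima), T5 at the ipsilateral extension minimum after T4, T2/T4
at the contralateral curve's minimum/maximum, T3 at the contralateral
curve's crossing of the midpoint between its T2 and T4 values.  T3 has no
closed definition in the source material beyond its use as the end of the
ankle inversion–eversion window; the mid-value-crossing choice
(approximately mid single support) is isolated in one function so it can
be revisited.

Numerics: curves are smoothed by convolution with a 0.2 s window
(Hann by default, flat available) with reflect padding, the classic
1-D sliding-window recipe; extrema are then found with a same-type
minimum separation of 0.4 s (half a conservative minimum stride time —
suppresses double peaks while leaving genuine max–min pairs, which can be
closer, untouched), alternation enforced by keeping the more extreme of
same-type runs with ties to the earliest frame.  Because a 0.2 s window
drags the peak of an asymmetric curve by roughly a frame, the final event
frame is refined to the local extremum of a lightly smoothed copy (window/3)
within half a window of the coarse location.  Events are reported at frame
resolution (no sub-frame interpolation), matching the 60/120 Hz captures.
A curve whose peak-to-peak range is below 2° (or 2 cm) raises a flat-curve
error: the method needs a minimum of flexion–extension to work with.

Over-ground captures are restricted to straight-walking sections, either
supplied manually (validated, non-overlapping) or found automatically by
keeping stretches where the pelvis yaw varies less than 20° over a 2 s
window — a heuristic that excludes turns, starts and stops.  Treadmill
captures are one continuous section.

## Gait variables

Per stride and side: step length and width (anteroposterior and
mediolateral ankle-centre separation at T1 — "sagittal-plane distance" is
read as the anteroposterior *component*, the conventional step-length
reading, not an in-plane norm); single support `100·(T4−T2)/(T6−T1)`;
double support `100·((T2−T1)+(T5−T4))/(T6−T1)`; gait speed = stride
length / stride time, where stride length is the ankle's T1→T6
anteroposterior displacement over ground, and on a treadmill the belt
speed (a configured, per-subject constant) times stride time is added to
the near-zero room-frame displacement — honouring both the displacement
and the "entire path" readings of stride length in their own settings.
Seven kinematic ranges (max − min of an Euler component between two
events): trunk tilt T2–T5, pelvic tilt T1–T4, hip flexion–extension T1–T4,
hip ab/adduction T4–T5, knee flexion–extension T4–T5, ankle dorsi/plantar
flexion T4–T5, ankle inversion–eversion T1–T3.

Angle and position curves are denoised before extraction with a
Savitzky–Golay filter (cubic, 0.15 s window) rather than the event
detector's moving window: max–min range estimation shares extremum
search's sensitivity to noise spikes, but a moving average of that size
measurably clips the genuine peaks the ranges are supposed to measure,
while local cubic fits preserve them.

Stride means are arithmetic means over valid strides only; invalid strides
are logged, never imputed.  A summary with fewer than 23 valid strides per
side carries a stability warning (stride statistics are conventionally
considered stable from about 23 strides; the reference protocol uses 25).

## Reliability statistics

For per-subject test/retest values (each a stride-set average):
ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed from the ANOVA mean squares and clipped to [−1, 1];
ICC(3,1) behind a flag.  Zero between-subject variance raises an explicit
undefined-ICC error rather than propagating NaN.  "Pooled average of the
SDs" is read as the RMS (variance-pooling) convention, with the arithmetic
mean behind a flag — the two coincide for equal SDs, which covers the
worked reference row.  Then `SEM = SD_pooled √(1−ICC)`,
`MDC95 = 1.96 √2 SEM`, `MDCes95 = MDC95/SD_test`,
`MDC95_group = MDC95/√n`.  Display rounding is decimal half-up at the
conventional printed precision; full precision is kept internally.  Note
that recomputing MDC95 from *printed* (1–2 d.p.) SDs and ICCs does not
always reproduce a printed MDC95 at 1 d.p. (e.g. 3.448 vs a printed 3.5
from unrounded internals); category summaries are robust to this.

Category summaries are unweighted means over step measures (step
length/width × sides), support percentages, gait speed and the 14
kinematic rows, plus the mean ICC and mean MDCes95 over all rows and
right–left-averaged MDC95 per variable.

## The simulator: what it emulates, and what it does not

Joint-angle curves are piecewise-cosine segments between extrema at
event-locked phases (phase 0 = ipsilateral contact; the contralateral leg
runs half a cycle behind; frontal/axial curves mirror between sides).
Defaults describe a healthy young adult at a natural pace: stride time
0.97 s, speed 121.8 cm/s, step 59 cm × 12 cm, hip flexion–extension range
35°, knee 35°, ankle dorsi/plantar 23°, hip ab/adduction 8°, pelvic tilt
4.8°, trunk tilt 10°, ankle inversion–eversion 8°, contralateral toe-off
at 10.1 % and toe-off at 60.3 % of the cycle (single support 39.9 %,
double support 20.4 %); subject height 173.1 cm.  A neutral 2 s standing
lead-in (the calibration segment) ramps smoothly into steady gait.

The construction is deliberately exact where the pipeline is validated
against it: relative bone rotations are composed in the same x–z–y order
the tracker decomposes, so commanded angle curves are recovered
identically; each kinematic range is gain-normalised over its measuring
window; commanded step length and width are met by a 1-D solve on the
generator's own closed-form geometry (shifting the knee mid-stance/swing
extrema together, which preserves the commanded knee range, and a constant
hip ab/adduction offset, iterated to joint convergence).  Hip and knee
extrema are placed exactly at the contact and toe-off phases, which makes
the forward-kinematics ankle anteroposterior curve peak at those phases
too — so the IMU and optical event definitions agree with the constructed
ground truth.  The cost of this event-structure exactness is physiological
fidelity: the knee curve lacks the late-swing flexion peak of real gait
(its swing maximum sits at toe-off), mid-stance knee values can leave the
physiological range when a long commanded step is solved for, and the
over-ground stance foot glides slightly instead of being exactly
stationary.  Passing tests therefore demonstrate the pipeline's internal
correctness and noise robustness, not its accuracy on physiological or
pathological gait.

Noise model (defaults chosen from the stated accuracies of the emulated
instruments): per-sensor heading offsets uniform on 0–360° (the defining
magnetometer-free behaviour); white orientation noise SD 0.3° (consumer
IMU roll/pitch accuracy is quoted at 0.2–1° RMS); a soft-tissue artefact
as low-pass-filtered rotational noise, RMS 0.3° with a 0.4 s time
constant, applied to the *sensor*, not the bone — a placement effect, with
no biomechanical realism claim; heading drift 0 by default (the emulated
protocol recalibrates before each capture) and injectable as a per-sensor
rate; optical marker positional noise SD 0.34 mm with per-cluster
orientation jitter drawn inside the cluster's maximum orientation error.
A fixed seed gives bit-identical streams.

## Validation scale and known limitations

The end-to-end suites run 27 simulated strides per capture (the reference
protocol's 25 plus margin) at the native rates, 60 Hz IMU / 120 Hz
optical; reliability recovery uses simulated cohorts of 33–200 subjects.

The full variable-tolerance recovery is demonstrated on the optical
(120 Hz) configuration.  At 60 Hz, events quantised to frames interact
with the steepest curve segments — near contact the contralateral ankle
moves several centimetres per frame, and near contralateral contact the
knee several degrees per frame — so a sub-frame event bias propagates into
biases of a few centimetres/degrees in the variables anchored there (step
length, double support, knee and ankle T4–T5 ranges).  This is an
intrinsic property of frame-resolution event anchoring, visible in the
wider reproducibility margins of real IMU configurations compared with
optical ones, and is covered by regression tests at documented looser
bounds rather than hidden by tuning.

Other limitations: no functional (movement-based) calibration; no
kinematic-constraint or zero-velocity drift correction (short captures
with recalibration instead); no pathological-gait robustness beyond the
flat-curve guard; optical landmark placement uses simplified proportion
rules; CSV/JSON only (no C3D/BVH import).
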