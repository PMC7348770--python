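# gaitbox

Clinical gait analysis from body-worn orientation sensors — either
magnetometer-free IMUs or clusters of optical reflective markers — with no
force platforms, no instrumented treadmill and no magnetically controlled
room.

`gaitbox` is aimed at movement-analysis researchers and engineers who need
the computational core of such a system as an importable, testable library:

* **Anatomical calibration** that recovers each IMU's arbitrary
  magnetometer-free heading from a single static neutral pose.  With the
  subject standing still, one axis of each sensor is known to lie parallel
  to the ground at a known angle (0° or 90°) from the pelvis sensor's
  projected Y axis; the measured deviation is the heading correction
  `α`, applied as a rotation about the vertical axis,

  ```
  R_Gs0^G = yaw(α)                       (heading correction)
  R_s0^G  = R_Gs0^G · R_s0^Gs            (sensor in the shared frame)
  R_s0^b  = (R_b0^G)ᵀ · R_s0^G           (constant sensor-to-bone link)
  R_bi^G  = R_si^G · (R_s0^b)ᵀ           (bone orientation at instant i)
  R_bi^p  = (R_pi^G)ᵀ · R_bi^G           (bone relative to its parent)
  ```

* **Skeletal tracking** over a 20-bone, pelvis-rooted hierarchy scaled from
  the subject's anthropometry, with joint angles as intrinsic x–z–y Euler
  components (X flexion–extension, Z tilt / ab-adduction, Y axial rotation)
  and joint centres by forward kinematics.

* **Kinematics-only gait-event detection**: six events per stride
  (T1 initial contact … T6 next contact) from extrema of smoothed
  kinematic curves — the hip flexion–extension curves (IMU, over-ground)
  or the ankle anteroposterior displacement curves (optical, treadmill).

* **Gait variables**: step length/width, single/double support, gait
  speed, and seven kinematic ranges between events, per stride and
  averaged over the stride set.

* **Reproducibility statistics**: ICC(2,1), `SEM = SD_pooled·√(1−ICC)`,
  `MDC95 = 1.96·√2·SEM`, its effect-size form `MDC95/SD_test` and the
  group form `MDC95/√n` — the minimal change a pre/post gait test can
  attribute to a real effect rather than measurement error.

* **Marker-cluster geometry checks**: worst-case cluster orientation error
  `Eo = 2·asin(Ep/Dmin)` and pairwise distinguishability of cluster
  distance triples.

* **A synthetic walking-avatar simulator** that emits IMU quaternion
  streams (60 Hz) and optical rigid-transform streams (120 Hz) with known
  ground-truth events and variables — including per-sensor random
  headings, heading drift, soft-tissue artefact and marker noise — so the
  entire pipeline is validated end-to-end without hardware.

## Worked example

`examples/05_gait_variables.py` simulates a noisy 27-stride optical
treadmill capture, calibrates, tracks, detects events and computes the
variable table:

```
variable                                                truth  mean R/L    err
Step length [cm]                                        59.00     59.16  +0.16
Step width [cm]                                         12.00     11.78  -0.22
Single support [%]                                      39.90     39.46  -0.44
Double support [%]                                      20.40     21.09  +0.69
Gait speed [cm/s]                                      121.80    121.82  +0.02
Range of trunk tilt T2 to T5 [deg]                      10.00      9.99  -0.01
Range of pelvic tilt T1 to T4 [deg]                      4.80      4.79  -0.01
Range of hip flexion-extension T1 to T4 [deg]           35.00     35.06  +0.06
Range of hip adduction-abduction T4 to T5 [deg]          8.00      7.63  -0.37
Range of knee flexion-extension T4 to T5 [deg]          35.00     34.44  -0.56
Range of ankle dorsi-plantar flexion T4 to T5 [deg]     22.98     23.14  +0.16
Range of ankle inversion-eversion T1 to T3 [deg]         8.00      8.12  +0.12
```

Every commanded quantity is recovered from the noisy sensor streams within
the capture's frame-rate and noise limits.  The other examples cover the
cluster geometry table, the heading-correction arithmetic, magnetometer-free
tracking closure (angles reproduced to ~1e-14 degrees under full-circle
random headings), event detection, and the reliability statistics.

A thin CLI mirrors the pipeline stages:

```
gaitbox simulate --modality imu --out capture.csv --truth-out truth.json
gaitbox calibrate capture.csv --frame0 60 --out cal.json
gaitbox events capture.csv --calibration cal.json --sections 180:99999 --out events.csv
gaitbox rbcheck
```

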