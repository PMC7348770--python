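"""Parameterised walking-avatar simulator.

Emits IMU quaternion streams (60 Hz) and optical rigid-transform streams
(120 Hz) for a walking avatar with known ("ground truth") gait events and
variables, so the whole calibration -> tracking -> event-detection ->
variable pipeline can be validated without hardware.  A test-retest cohort
generator for the reliability statistics is included.

Curve family
------------
Each joint-angle component is a piecewise-cosine curve: C1 segments of the
form ``v0 + (v1 - v0)(1 - cos(pi u))/2`` between consecutive extrema at
event-locked phases of the gait cycle (phase 0 = ipsilateral initial
contact; the contralateral leg runs half a cycle out of phase).  The
extremum placement is chosen so that

* the hip flexion-extension curves peak exactly at the contact (T1/T6) and
  toe-off (T5) phases — the IMU event rules recover the constructed events;
* the knee curve has extrema exactly at contact and toe-off, which makes the
  forward-kinematics ankle anteroposterior curve peak at those phases too —
  the optical event rules recover the same events.

This placement sacrifices the late-swing knee flexion peak of physiological
gait in exchange for exact event-structure closure; the curves are
kinematically plausible but make no physiological-realism claim.

Commanded values are realised exactly: each kinematic range is normalised
over its measuring window (linear gain), the commanded step length is met
by shifting the knee mid-stance/swing extrema jointly (which preserves the
commanded knee range), and the commanded step width by a constant hip
ab/adduction offset — both solved on the generator's own closed-form
forward geometry.

Noise model
-----------
Per-sensor uniform random headings (magnetometer-free emulation), optional
slow heading drift, white orientation noise, a low-frequency soft-tissue
artefact on sensor (not bone) orientation, and marker positional noise that
propagates to cluster orientation jitter bounded by the cluster's maximum
orientation error.  A fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation as _R

from .calibration import DEFAULT_ASSUMPTIONS
from .rigid_bodies import load_reference_geometries, orientation_error
from .rotations import _ZUP_TO_YUP, yaw_rotation
from .session import CaptureSession, DeviceStream
from .skeleton import Anthropometrics, SkeletonDefinition, build_skeleton

__all__ = [
    "GaitProfile",
    "NoiseModel",
    "GaitTrajectories",
    "joint_trajectories",
    "synthesize_imu",
    "synthesize_opt",
    "simulate_session",
    "simulate_test_retest",
]

GAIT_DEVICES = ("pelvis", "thorax", "thigh_R", "thigh_L",
                "calf_R", "calf_L", "foot_R", "foot_L")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GaitProfile:
    """Commanded gait pattern; defaults follow a healthy young adult walking
    at a natural self-selected pace (speed 121.8 cm/s, step 59 cm, hip
    flexion-extension range 35 deg, single support just under 40 %)."""

    stride_time_s: float = 0.97
    gait_speed_cm_s: float = 121.8
    step_length_cm: float = 59.0
    step_width_cm: float = 12.0
    # kinematic ranges over their measuring windows, degrees
    trunk_tilt_range: float = 10.0
    pelvic_tilt_range: float = 4.8
    hip_flexion_range: float = 35.0
    hip_abduction_range: float = 8.0
    knee_flexion_range: float = 35.0
    ankle_dorsi_range: float = 23.0
    ankle_inversion_range: float = 8.0
    hip_contact_deg: float = 25.0        # hip flexion at initial contact
    # event phases (fractions of the stride cycle)
    phase_contra_toe_off: float = 0.101  # T2
    phase_toe_off: float = 0.603         # T5
    # subject
    height_cm: float = 173.1
    iliac_crest_width_cm: float = 28.0
    elbow_span_cm: float = 90.0
    # capture structure
    lead_in_s: float = 2.0               # neutral standing (calibration segment)
    ramp_s: float = 1.0                  # smooth transition into steady gait
    # optional 180-degree turn (over-ground IMU captures)
    turn_after_strides: Optional[int] = None
    turn_duration_s: float = 2.0

    def __post_init__(self):
        if self.stride_time_s <= 0:
            raise SimulationError("stride time must be positive")
        for name in ("trunk_tilt_range", "pelvic_tilt_range", "hip_flexion_range",
                     "hip_abduction_range", "knee_flexion_range", "ankle_dorsi_range",
                     "ankle_inversion_range"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if not 0 < self.phase_contra_toe_off < 0.5 < self.phase_toe_off < 1:
            raise SimulationError("event phases must satisfy 0 < T2 < 0.5 < T5 < 1")

    @property
    def anthropometrics(self) -> Anthropometrics:
        return Anthropometrics(height=self.height_cm, elbow_span=self.elbow_span_cm,
                               iliac_crest_width=self.iliac_crest_width_cm)


@dataclass(frozen=True)
class NoiseModel:
    """Sensor imperfection model; defaults reflect sub-degree IMU accuracy.

    ``heading_offsets``: each sensor's fusion frame gets an independent
    uniform 0-360 degree heading (magnetometer-free behaviour).
    ``heading_drift_deg_s``: per-sensor yaw drift rate drawn uniformly in
    +-that magnitude.  ``orientation_noise_deg``: white rotational noise SD.
    ``soft_tissue_deg``: RMS of a low-pass-filtered rotational artefact
    applied to the sensor, not the bone.  ``marker_noise_mm``: optical
    marker positional noise SD; cluster orientation jitter is bounded by the
    cluster's maximum orientation error for that positioning error.
    """

    heading_offsets: bool = True
    heading_drift_deg_s: float = 0.0
    orientation_noise_deg: float = 0.3
    soft_tissue_deg: float = 0.3
    soft_tissue_cutoff_s: float = 0.4    # gaussian time constant of the artefact
    marker_noise_mm: float = 0.34
    mounting_incline_deg: float = 30.0   # max random inclination about the assumed axis

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(heading_offsets=False, heading_drift_deg_s=0.0,
                   orientation_noise_deg=0.0, soft_tissue_deg=0.0, marker_noise_mm=0.0,
                   mounting_incline_deg=30.0)

    @classmethod
    def headings_only(cls) -> "NoiseModel":
        return cls(heading_offsets=True, heading_drift_deg_s=0.0,
                   orientation_noise_deg=0.0, soft_tissue_deg=0.0, marker_noise_mm=0.0)


def _pw_cos(phases, values, phi):
    """Periodic piecewise-cosine through extrema (phase, value); C1."""
    ps = np.asarray(phases, dtype=float)
    vs = np.asarray(values, dtype=float)
    phi = np.mod(np.asarray(phi, dtype=float), 1.0)
    pext = np.concatenate([[ps[-1] - 1.0], ps, [ps[0] + 1.0]])
    vext = np.concatenate([[vs[-1]], vs, [vs[0]]])
    idx = np.clip(np.searchsorted(pext, phi, side="right") - 1, 0, len(pext) - 2)
    p0, p1 = pext[idx], pext[idx + 1]
    v0, v1 = vext[idx], vext[idx + 1]
    u = (phi - p0) / (p1 - p0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _to_zup_stack(mats: np.ndarray) -> np.ndarray:
    """Re-express a (n,3,3) rotation stack in the Z-up fusion convention."""
    return np.einsum("ji,njk,kl->nil", _ZUP_TO_YUP, mats, _ZUP_TO_YUP)


def _quats_scalar_first(mats: np.ndarray) -> np.ndarray:
    q = _R.from_matrix(mats).as_quat()          # (x, y, z, w)
    q = q[:, [3, 0, 1, 2]]
    q[q[:, 0] < 0] *= -1.0
    return q


@dataclass
class _CurveSet:
    """Right-leg / axial curve definitions as (phases, values) extrema lists."""

    hip_x: Tuple[np.ndarray, np.ndarray]      # euler x of thigh (flexion is negative x)
    hip_z: Tuple[np.ndarray, np.ndarray]
    knee_x: Tuple[np.ndarray, np.ndarray]
    foot_x: Tuple[np.ndarray, np.ndarray]
    foot_z: Tuple[np.ndarray, np.ndarray]
    pelvis_z: Tuple[np.ndarray, np.ndarray]
    thorax_z: Tuple[np.ndarray, np.ndarray]

    def eval_right(self, phi) -> Dict[str, np.ndarray]:
        z = np.zeros_like(np.asarray(phi, dtype=float))
        e = {}
        e["pelvis"] = np.stack([z, _pw_cos(*self.pelvis_z, phi), z], axis=-1)
        e["thorax"] = np.stack([z, _pw_cos(*self.thorax_z, phi), z], axis=-1)
        e["thigh_R"] = np.stack([_pw_cos(*self.hip_x, phi), _pw_cos(*self.hip_z, phi), z], axis=-1)
        e["calf_R"] = np.stack([_pw_cos(*self.knee_x, phi), z, z], axis=-1)
        e["foot_R"] = np.stack([_pw_cos(*self.foot_x, phi), _pw_cos(*self.foot_z, phi), z], axis=-1)
        # left leg: sagittal (x) curves shift half a cycle; frontal/axial
        # (z, y) curves shift and mirror
        lphi = np.asarray(phi, dtype=float) - 0.5
        e["thigh_L"] = np.stack(
            [_pw_cos(*self.hip_x, lphi), -_pw_cos(*self.hip_z, lphi), z], axis=-1)
        e["calf_L"] = np.stack([_pw_cos(*self.knee_x, lphi), z, z], axis=-1)
        e["foot_L"] = np.stack(
            [_pw_cos(*self.foot_x, lphi), -_pw_cos(*self.foot_z, lphi), z], axis=-1)
        return e


def _compose_abs(eulers: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Absolute bone rotations from relative euler curves (rxzy order)."""
    rel = {b: _R.from_euler("XZY", e, degrees=True).as_matrix() for b, e in eulers.items()}
    out = {"pelvis": rel["pelvis"]}
    out["thorax"] = out["pelvis"] @ rel["thorax"]
    for s in ("R", "L"):
        out[f"thigh_{s}"] = out["pelvis"] @ rel[f"thigh_{s}"]
        out[f"calf_{s}"] = out[f"thigh_{s}"] @ rel[f"calf_{s}"]
        out[f"foot_{s}"] = out[f"calf_{s}"] @ rel[f"foot_{s}"]
    return out


def _ankle_positions(absolute, skeleton: SkeletonDefinition, pelvis_pos):
    """World ankle-centre (foot-origin) positions via the bone chain."""
    out = {}
    for s in ("R", "L"):
        hip = pelvis_pos + np.einsum("...ij,j->...i", absolute["pelvis"],
                                     skeleton.bones[f"thigh_{s}"].offset)
        knee = hip + np.einsum("...ij,j->...i", absolute[f"thigh_{s}"],
                               skeleton.bones[f"calf_{s}"].offset)
        out[s] = knee + np.einsum("...ij,j->...i", absolute[f"calf_{s}"],
                                  skeleton.bones[f"foot_{s}"].offset)
    return out


@dataclass
class GroundTruth:
    events: pd.DataFrame                 # stride, side, T1..T6 (float frames)
    variables: Dict[str, float]          # Table-style label -> true value
    joint_eulers: Dict[str, np.ndarray]  # commanded relative euler series (deg)
    steady_start_frame: int
    calibration_frame: int
    single_support_pct: float
    double_support_pct: float
    t3_phase: float
    turn_interval: Optional[Tuple[int, int]] = None


@dataclass
class GaitTrajectories:
    profile: GaitProfile
    modality: str
    rate: float
    timestamps: np.ndarray
    eulers: Dict[str, np.ndarray]        # relative euler curves per bone (n,3)
    absolute: Dict[str, np.ndarray]      # absolute bone rotations (n,3,3)
    pelvis_translation: np.ndarray       # (n,3) cm
    positions: Dict[str, np.ndarray]     # ankle centres per side (n,3)
    skeleton: SkeletonDefinition
    truth: GroundTruth


def _build_curves(profile: GaitProfile, t3_phase_guess: float = 0.3) -> _CurveSet:
    """Event-locked extrema with gains normalised over the measuring windows."""
    p = profile
    t5 = p.phase_toe_off

    # hip: flexion theta has max at contact (phase 0), min at toe-off;
    # euler x = -theta for the legs in this frame
    f0, f05 = 1.0, float(_pw_cos([0.0, t5], [1.0, 0.0], 0.5))
    spread = p.hip_flexion_range / (f0 - f05)        # theta_max - theta_min
    th_max = p.hip_contact_deg
    th_min = th_max - spread
    hip_x = (np.array([0.0, t5]), np.array([-th_max, -th_min]))

    # knee: extrema at contact, loading response, mid-stance, toe-off.
    # T4..T5 window [0.5, t5] lies on the rising mid-stance->toe-off branch;
    # its range is (k_sw - k_ms)/2 for window start exactly at 0.5 -- the
    # gain is normalised numerically below to stay exact for any t5.
    k_ic, k_lr, k_ms0 = 4.0, 16.0, 6.0

    def knee_curve(delta):
        k_ms = k_ms0 - delta
        k_sw = k_ms + 2.0 * p.knee_flexion_range * _knee_gain_correction(t5)
        return (np.array([0.0, 0.15, 0.40, t5]), np.array([k_ic, k_lr, k_ms, k_sw]))

    def _knee_gain_correction(t5_):
        # window [0.5, t5] of the branch [0.40 -> t5]: fraction of (k_sw-k_ms)
        u0 = (0.5 - 0.40) / (t5_ - 0.40)
        frac = 1.0 - 0.5 * (1.0 - math.cos(math.pi * u0))
        return 0.5 / frac if frac > 0 else 0.5

    # pelvic obliquity (z), two cycles per stride, window T1..T4 spans both extrema
    pz = p.pelvic_tilt_range / 2.0
    pelvis_z = (np.array([0.10, 0.35, 0.60, 0.85]), np.array([pz, -pz, pz, -pz]))
    tz = p.trunk_tilt_range / 2.0
    thorax_z = (np.array([0.10, 0.35, 0.60, 0.85]), np.array([tz, -tz, tz, -tz]))

    # steep-segment curves normalised numerically over their windows
    def normalised(phases, values, lo, hi, commanded):
        grid = np.linspace(lo, hi, 2001)
        v = _pw_cos(phases, values, grid)
        rng = float(v.max() - v.min())
        g = commanded / rng if rng > 0 else 0.0
        return (np.asarray(phases, dtype=float), np.asarray(values, dtype=float) * g)

    hip_z = normalised([0.50, 0.62], [0.5, -0.5], 0.5, t5, p.hip_abduction_range)
    foot_x = normalised([0.50, 0.65], [0.5, -0.5], 0.5, t5, p.ankle_dorsi_range)
    foot_z = normalised([0.05, 0.40], [0.5, -0.5], 0.0, t3_phase_guess,
                        p.ankle_inversion_range)

    return _CurveSet(hip_x=hip_x, hip_z=hip_z, knee_x=knee_curve(0.0),
                     foot_x=foot_x, foot_z=foot_z, pelvis_z=pelvis_z, thorax_z=thorax_z)


def _solve_spatial(curves: _CurveSet, profile: GaitProfile,
                   skeleton: SkeletonDefinition) -> _CurveSet:
    """Meet the commanded step length and width exactly at the contact pose."""

    def ankles_at_contact(cs: _CurveSet):
        e = cs.eval_right(np.array([0.0]))
        absr = _compose_abs(e)
        pos = _ankle_positions(absr, skeleton, np.zeros(3))
        return pos["R"][0], pos["L"][0]

    # knee shift: moves mid-stance and swing extrema together (window range
    # preserved); monotone effect on the contralateral shank angle at contact
    kp, kv = curves.knee_x

    def with_delta(delta):
        v = kv.copy()
        v[2] -= delta
        v[3] -= delta
        return replace(curves, knee_x=(kp, v))

    # constant ab/adduction offset: moves both ankles apart symmetrically
    zp, zv = curves.hip_z

    def with_both(delta, ab):
        c = with_delta(delta)
        return replace(c, hip_z=(zp, zv + ab))

    # the two knobs couple weakly (frontal offsets scale sagittal
    # projections and vice versa): alternate the 1-D solves to convergence
    delta, ab = 0.0, 0.0
    for _ in range(12):
        def step_err2(d):
            r, l = ankles_at_contact(with_both(d, ab))
            return (r[2] - l[2]) - profile.step_length_cm

        delta = brentq(step_err2, -60.0, 80.0, xtol=1e-11)

        def width_err(a):
            # signed right-minus-left separation increases monotonically
            # with a common outward ab/adduction offset
            r, l = ankles_at_contact(with_both(delta, a))
            return (r[0] - l[0]) - profile.step_width_cm

        ab = brentq(width_err, -30.0, 30.0, xtol=1e-11)
        if abs(step_err2(delta)) < 1e-8 and abs(width_err(ab)) < 1e-8:
            break
    return with_both(delta, ab)


VARIABLE_TRUTH_LABELS = {
    "step_length": "Step length [cm]",
    "step_width": "Step width [cm]",
    "single_support": "Single support [%]",
    "double_support": "Double support [%]",
    "gait_speed": "Gait speed [cm/s]",
    "trunk_tilt": "Range of trunk tilt T2 to T5 [deg]",
    "pelvic_tilt": "Range of pelvic tilt T1 to T4 [deg]",
    "hip_flexion": "Range of hip flexion-extension T1 to T4 [deg]",
    "hip_abduction": "Range of hip adduction-abduction T4 to T5 [deg]",
    "knee_flexion": "Range of knee flexion-extension T4 to T5 [deg]",
    "ankle_dorsi": "Range of ankle dorsi-plantar flexion T4 to T5 [deg]",
    "ankle_inversion": "Range of ankle inversion-eversion T1 to T3 [deg]",
}


def _truth_variables(curves: _CurveSet, profile: GaitProfile,
                     skeleton: SkeletonDefinition, modality: str):
    """Exact variable values and the T3 phase from the steady-state cycle."""
    p = profile
    grid = np.linspace(0.0, 1.0, 4801)
    e = curves.eval_right(grid)
    absr = _compose_abs(e)
    pos = _ankle_positions(absr, skeleton, np.zeros(3))

    # contralateral reference curve for T3 (mid-value crossing in (T2, T4))
    if modality == "imu":
        contra = -e["thigh_L"][:, 0]          # left hip flexion-extension
    else:
        contra = pos["L"][:, 2]               # left ankle anteroposterior
    t2, t4 = p.phase_contra_toe_off, 0.5
    i2, i4 = int(round(t2 * 4800)), int(round(t4 * 4800))
    mid = 0.5 * (contra[i2] + contra[i4])
    seg = contra[i2:i4 + 1]
    t3 = grid[i2 + int(np.nonzero(seg >= mid)[0][0])]

    def window_range(series, lo, hi):
        a, b = int(round(lo * 4800)), int(round(hi * 4800))
        return float(series[a:b + 1].max() - series[a:b + 1].min())

    t5 = p.phase_toe_off
    ankR0, ankL0 = pos["R"][0], pos["L"][0]
    vars_ = {
        "step_length": float(abs(ankR0[2] - ankL0[2])),
        "step_width": float(abs(ankR0[0] - ankL0[0])),
        "single_support": 100.0 * (t4 - t2),
        "double_support": 100.0 * (t2 + (t5 - t4)),
        "gait_speed": p.gait_speed_cm_s,
        "trunk_tilt": window_range(e["thorax"][:, 1], t2, t5),
        "pelvic_tilt": window_range(e["pelvis"][:, 1], 0.0, t4),
        "hip_flexion": window_range(e["thigh_R"][:, 0], 0.0, t4),
        "hip_abduction": window_range(e["thigh_R"][:, 1], t4, t5),
        "knee_flexion": window_range(e["calf_R"][:, 0], t4, t5),
        "ankle_dorsi": window_range(e["foot_R"][:, 0], t4, t5),
        "ankle_inversion": window_range(e["foot_R"][:, 1], 0.0, t3),
    }
    return {VARIABLE_TRUTH_LABELS[k]: v for k, v in vars_.items()}, float(t3)


def joint_trajectories(
    profile: GaitProfile,
    n_strides: int = 27,
    rate: float = 60.0,
    modality: str = "imu",
) -> GaitTrajectories:
    """Generate the avatar's bone rotations, root trajectory and ground truth.

    The capture starts with a neutral standing segment (for calibration),
    ramps smoothly into steady gait, and runs ``n_strides`` full strides per
    side.  Ground-truth events are reported in (float) frame units for the
    steady strides only.
    """
    if n_strides < 1:
        raise SimulationError("need at least one stride")
    if rate < 20.0:
        raise SimulationError(f"rate {rate} Hz too low; gait curves would alias")
    p = profile
    skeleton = build_skeleton(p.anthropometrics, mode="imu")

    curves = _build_curves(p)
    curves = _solve_spatial(curves, p, skeleton)
    truth_vars, t3_phase = _truth_variables(curves, p, skeleton, modality)
    # re-normalise the inversion-eversion gain against the modality's T3
    curves = _build_curves(p, t3_phase_guess=t3_phase)
    curves = _solve_spatial(curves, p, skeleton)
    truth_vars, t3_phase = _truth_variables(curves, p, skeleton, modality)

    T = p.stride_time_s
    steady0 = p.lead_in_s + p.ramp_s
    turn = None
    turn_strides = 0
    if p.turn_after_strides is not None:
        turn_strides = int(math.ceil(p.turn_duration_s / T)) + 1
    total_s = steady0 + (n_strides + turn_strides + 1.3) * T
    n = int(round(total_s * rate))
    t = np.arange(n) / rate
    phi = (t - steady0) / T
    env = _smoothstep((t - p.lead_in_s) / p.ramp_s)

    eulers = {b: env[:, None] * e for b, e in curves.eval_right(phi).items()}

    # optional 180-degree turn: pelvis yaw ramps during an excluded interval
    heading = np.zeros(n)
    if p.turn_after_strides is not None:
        t_turn0 = steady0 + p.turn_after_strides * T
        heading = 180.0 * _smoothstep((t - t_turn0) / p.turn_duration_s)
        eulers["pelvis"] = eulers["pelvis"].copy()
        eulers["pelvis"][:, 2] += heading  # euler y column

    absolute = _compose_abs(eulers)

    pelvis_y0 = (skeleton.bones["toes_R"].offset[1].__abs__()
                 + abs(skeleton.bones["foot_R"].offset[1])
                 + abs(skeleton.bones["calf_R"].offset[1])
                 + abs(skeleton.bones["thigh_R"].offset[1]))
    bounce = -1.0 * env * np.cos(4.0 * np.pi * phi)
    sway = 1.5 * env * np.cos(2.0 * np.pi * phi)
    pelvis_t = np.zeros((n, 3))
    pelvis_t[:, 1] = pelvis_y0 + bounce
    if modality == "imu":
        # over-ground: advance along the current heading at the commanded speed
        vz = p.gait_speed_cm_s * env * np.cos(np.deg2rad(heading))
        vx = p.gait_speed_cm_s * env * np.sin(np.deg2rad(heading))
        pelvis_t[:, 2] = np.cumsum(vz) / rate
        pelvis_t[:, 0] = np.cumsum(vx) / rate
    else:
        pelvis_t[:, 0] = sway  # treadmill: stationary with lateral sway

    positions = _ankle_positions(absolute, skeleton, pelvis_t)

    # ground-truth events (float frames), steady strides only
    ev_phases = {"T1": 0.0, "T2": p.phase_contra_toe_off, "T3": t3_phase,
                 "T4": 0.5, "T5": p.phase_toe_off, "T6": 1.0}
    rows = []
    stride = 0
    skip = set()
    if p.turn_after_strides is not None:
        skip = set(range(p.turn_after_strides - 1, p.turn_after_strides + turn_strides + 1))
    for k in range(n_strides + turn_strides):
        for side, off in (("R", 0.0), ("L", 0.5)):
            if k in skip:
                continue
            row = {"stride": stride, "side": side}
            ok = True
            for name, ph in ev_phases.items():
                f = (steady0 + (k + off + ph) * T) * rate
                if f >= n - 1:
                    ok = False
                row[name] = f
            if ok:
                rows.append(row)
                stride += 1
    events = pd.DataFrame(rows)

    truth = GroundTruth(
        events=events,
        variables=truth_vars,
        joint_eulers=eulers,
        steady_start_frame=int(math.ceil(steady0 * rate)),
        calibration_frame=int(round(0.5 * p.lead_in_s * rate)),
        single_support_pct=100.0 * (0.5 - p.phase_contra_toe_off),
        double_support_pct=100.0 * (p.phase_contra_toe_off + p.phase_toe_off - 0.5),
        t3_phase=t3_phase,
        turn_interval=(
            None if p.turn_after_strides is None
            else (int((steady0 + p.turn_after_strides * T) * rate),
                  int((steady0 + p.turn_after_strides * T + p.turn_duration_s) * rate))
        ),
    )
    return GaitTrajectories(
        profile=p, modality=modality, rate=rate, timestamps=t, eulers=eulers,
        absolute=absolute, pelvis_translation=pelvis_t, positions=positions,
        skeleton=skeleton, truth=truth,
    )


def _mount_matrix(axis: str, expected_deg: float, incline_deg: float) -> np.ndarray:
    """Sensor-to-bone mounting with the assumed axis at its expected ground
    direction and a random inclination about that axis."""
    u = yaw_rotation(expected_deg) @ np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, 1.0, 0.0])
    if axis == "Y":
        cols = np.stack([up, u, np.cross(up, u)], axis=1)
    else:
        cols = np.stack([u, up, np.cross(u, up)], axis=1)
    incline = _R.from_rotvec(np.deg2rad(incline_deg) * u).as_matrix()
    return incline @ cols


def _noise_rotvecs(n: int, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    if sd_deg <= 0:
        return np.zeros((n, 3))
    return rng.normal(0.0, np.deg2rad(sd_deg), size=(n, 3))


def _soft_tissue_rotvecs(n: int, rate: float, rms_deg: float, tau_s: float,
                         rng: np.random.Generator) -> np.ndarray:
    if rms_deg <= 0:
        return np.zeros((n, 3))
    raw = rng.normal(0.0, 1.0, size=(n, 3))
    filt = gaussian_filter1d(raw, sigma=tau_s * rate, axis=0, mode="reflect")
    rms = np.sqrt(np.mean(filt**2)) or 1.0
    return np.deg2rad(rms_deg) * filt / rms


def synthesize_imu(
    traj: GaitTrajectories,
    noise: NoiseModel = NoiseModel(),
    rng: Optional[np.random.Generator] = None,
) -> CaptureSession:
    """Emit 8-device IMU quaternion streams (Z-up fusion convention).

    Each sensor stream is expressed in its own fusion frame with a private
    random heading (and optional drift), mounted on its bone per the
    heading-assumption table with a random inclination about the assumed
    axis, and corrupted by white orientation noise plus the soft-tissue
    artefact.  The neutral lead-in segment serves as the calibration pose.
    A pelvis translation channel carries the root trajectory.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = len(traj.timestamps)
    devices: Dict[str, DeviceStream] = {}
    for name in GAIT_DEVICES:
        if name == "pelvis":
            axis, expected = "Y", 0.0
        else:
            a = DEFAULT_ASSUMPTIONS[name]
            axis, expected = a.axis, a.expected
        incline = rng.uniform(-noise.mounting_incline_deg, noise.mounting_incline_deg)
        mount = _mount_matrix(axis, expected, incline)
        eta = rng.uniform(0.0, 360.0) if noise.heading_offsets else 0.0
        drift = rng.uniform(-1.0, 1.0) * noise.heading_drift_deg_s
        yaw_t = -(eta + drift * traj.timestamps)

        sensor_w = traj.absolute[name] @ mount
        wobble = _R.from_rotvec(
            _soft_tissue_rotvecs(n, traj.rate, noise.soft_tissue_deg,
                                 noise.soft_tissue_cutoff_s, rng)
            + _noise_rotvecs(n, noise.orientation_noise_deg, rng)
        ).as_matrix()
        yaws = _R.from_euler("Y", yaw_t[:, None], degrees=True).as_matrix()
        reading = np.einsum("nij,njk,nkl->nil", yaws, sensor_w, wobble)
        stream = DeviceStream(quaternions=_quats_scalar_first(_to_zup_stack(reading)))
        if name == "pelvis":
            stream.translations = traj.pelvis_translation.copy()
        devices[name] = stream

    return CaptureSession(
        modality="imu", rate=traj.rate, devices=devices, timestamps=traj.timestamps,
        environment="overground", meta={"frame_convention": "zup"},
    )


def synthesize_opt(
    traj: GaitTrajectories,
    noise: NoiseModel = NoiseModel(),
    rng: Optional[np.random.Generator] = None,
) -> CaptureSession:
    """Emit 8-cluster optical rigid-transform streams (camera frame, 120 Hz).

    Cluster orientations are the bone orientations under a random (full)
    cluster-to-bone mounting, with orientation jitter bounded by each
    cluster's maximum orientation error; translations are the bone-origin
    positions with marker positional noise.  Treadmill capture: the belt
    speed is recorded in the session.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eo = {g.name: orientation_error(replace(g, ep=noise.marker_noise_mm))
          if noise.marker_noise_mm > 0 else 0.0
          for g in load_reference_geometries()}
    n = len(traj.timestamps)
    chain_pos = _device_positions(traj)
    devices: Dict[str, DeviceStream] = {}
    for name in GAIT_DEVICES:
        mount = _R.random(rng=rng).as_matrix()
        if eo.get(name, 0.0) > 0:
            angles = rng.uniform(0.0, np.deg2rad(eo[name]), size=n)
            axes = rng.normal(size=(n, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            jitter = _R.from_rotvec(angles[:, None] * axes).as_matrix()
        else:
            jitter = np.broadcast_to(np.eye(3), (n, 3, 3))
        reading = np.einsum("nij,jk,nkl->nil", traj.absolute[name], mount, jitter)
        trans = chain_pos[name].copy()
        if noise.marker_noise_mm > 0:
            trans = trans + rng.normal(0.0, noise.marker_noise_mm / 10.0, size=(n, 3))
        devices[name] = DeviceStream(quaternions=_quats_scalar_first(reading), translations=trans)
    return CaptureSession(
        modality="optical", rate=traj.rate, devices=devices, timestamps=traj.timestamps,
        environment="treadmill", belt_speed=traj.profile.gait_speed_cm_s,
        meta={"frame_convention": "yup"},
    )


def _device_positions(traj: GaitTrajectories) -> Dict[str, np.ndarray]:
    sk, absr, root = traj.skeleton, traj.absolute, traj.pelvis_translation
    pos = {"pelvis": root}
    pos["thorax"] = root + np.einsum("nij,j->ni", absr["pelvis"], sk.bones["thorax"].offset)
    for s in ("R", "L"):
        hip = root + np.einsum("nij,j->ni", absr["pelvis"], sk.bones[f"thigh_{s}"].offset)
        knee = hip + np.einsum("nij,j->ni", absr[f"thigh_{s}"], sk.bones[f"calf_{s}"].offset)
        ankle = knee + np.einsum("nij,j->ni", absr[f"calf_{s}"], sk.bones[f"foot_{s}"].offset)
        pos[f"thigh_{s}"] = hip
        pos[f"calf_{s}"] = knee
        pos[f"foot_{s}"] = ankle
    return pos


def simulate_session(
    profile: GaitProfile = GaitProfile(),
    noise: NoiseModel = NoiseModel(),
    n_strides: int = 27,
    modality: str = "imu",
    seed: int = 0,
):
    """Convenience wrapper: trajectories + sensor synthesis in one call.

    Returns ``(session, trajectories)``; the ground truth lives in
    ``trajectories.truth``.
    """
    rate = 60.0 if modality == "imu" else 120.0
    traj = joint_trajectories(profile, n_strides=n_strides, rate=rate, modality=modality)
    rng = np.random.default_rng(seed)
    if modality == "imu":
        session = synthesize_imu(traj, noise, rng)
    else:
        session = synthesize_opt(traj, noise, rng)
    return session, traj


def simulate_test_retest(
    n_subjects: int,
    between_subject_sd,
    within_subject_sd,
    seed: int = 0,
    profile: GaitProfile = GaitProfile(),
    variables=None,
):
    """Test-retest cohort for the reliability statistics.

    Each subject's true value of each variable is Normal(profile truth,
    between_subject_sd); each session observation adds independent
    Normal(0, within_subject_sd) measurement error.  The SD arguments are
    scalars (applied to every variable) or dicts keyed by variable label.
    Returns a long-format :class:`gaitbox.reliability.TestRetestTable`.
    """
    from .reliability import TestRetestTable

    if n_subjects < 2:
        raise SimulationError("need at least 2 subjects")
    traj_vars, _ = _truth_variables(
        _solve_spatial(_build_curves(profile), profile,
                       build_skeleton(profile.anthropometrics, mode="imu")),
        profile, build_skeleton(profile.anthropometrics, mode="imu"), "imu")
    labels = list(variables) if variables is not None else list(traj_vars)

    def sd_of(spec, label):
        v = spec.get(label) if isinstance(spec, dict) else spec
        if v is None or v < 0:
            raise SimulationError(f"invalid SD for {label!r}")
        return float(v)

    rng = np.random.default_rng(seed)
    rows = []
    for label in labels:
        mean = traj_vars.get(label, 0.0)
        sb = sd_of(between_subject_sd, label)
        se = sd_of(within_subject_sd, label)
        if sb <= 0:
            raise SimulationError("between-subject SD must be positive")
        true = rng.normal(mean, sb, size=n_subjects)
        for side in ("R", "L"):
            test = true + rng.normal(0.0, se, size=n_subjects)
            retest = true + rng.normal(0.0, se, size=n_subjects)
            for i in range(n_subjects):
                rows.append({"subject": i, "variable": label, "side": side,
                             "session": "test", "value": test[i]})
                rows.append({"subject": i, "variable": label, "side": side,
                             "session": "retest", "value": retest[i]})
    return TestRetestTable(pd.DataFrame(rows))
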