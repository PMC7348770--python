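"""Anatomical calibration ("Fitbody") and per-frame skeletal tracking.

Magnetometer-free IMUs share no horizontal reference: each sensor's fusion
frame has gravity-aligned vertical but an arbitrary heading.  The calibration
recovers every heading from a single static neutral pose using mounting
assumptions: for each body part one sensor axis is known to lie parallel to
the ground at a known angle from the pelvis sensor's projected Y axis
(0 or 90 degrees, depending on the body part).  The measured ground-plane
angle between the two projections gives a per-sensor heading correction
``alpha``; e.g. a measured 83 degrees where 90 is expected means 7 degrees
must be corrected.

The correction chain, with ``R_a^b`` read "rotation of a with respect to b"
and instant 0 the calibration frame:

* ``R_Gs0^G = yaw(alpha)`` — heading correction (per sensor),
* ``R_s0^G = R_Gs0^G @ R_s0^Gs`` — sensor in the shared frame,
* ``R_s0^b = (R_b0^G)^T @ R_s0^G`` — constant sensor-to-bone rotation,
* ``R_bi^G = R_si^G @ (R_s0^b)^T`` — bone orientation at any instant i,
* ``R_bi^p = (R_pi^G)^T @ R_bi^G`` — bone relative to its parent.

The shared frame G is anchored anatomically: the pelvis sensor sits on the
sacrum with its Y axis pointing along the subject's mediolateral direction,
so the calibration additionally yaws the whole frame to map that projected
axis onto the world +X axis.  This keeps the reported Euler components
(X flexion, Z tilt/ab-adduction, Y axial) anatomically meaningful.  Optical
marker clusters are captured in a common camera frame already, so their
heading correction is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
from scipy.spatial.transform import Rotation as _R

from .rotations import (
    DegenerateProjectionError,
    angle_between_projections,
    assert_rotation,
    project_to_ground,
    wrap_angle,
    yaw_rotation,
)
from .session import CaptureSession
from .skeleton import SkeletonDefinition

__all__ = [
    "HeadingAssumption",
    "DEFAULT_ASSUMPTIONS",
    "CalibrationResult",
    "BonePoseSeries",
    "heading_alpha",
    "heading_rotation",
    "correct_sensor",
    "sensor_to_bone",
    "bone_absolute",
    "bone_relative",
    "calibrate",
    "track",
]

#: Euler column order in all angle arrays (intrinsic rotating-frame x-z-y)
EULER_COLUMNS = ("x", "z", "y")


class CalibrationError(ValueError):
    pass


class CalibrationPoseError(CalibrationError):
    """An assumed ground-parallel axis measured near vertical (mis-mounted device)."""


@dataclass(frozen=True)
class HeadingAssumption:
    """Mounting assumption for one device.

    ``expected`` is the signed ground-plane angle (degrees) from the pelvis
    sensor's projected Y axis to the device's projected ``axis``; the
    magnitudes (0 or 90) follow the body-part table, the signs distinguish
    left from right mountings.
    """

    device: str
    axis: str        # "X" | "Y"
    expected: float  # degrees

    def __post_init__(self):
        if self.axis not in ("X", "Y"):
            raise CalibrationError("assumed axis must be 'X' or 'Y'")
        if abs(self.expected) not in (0.0, 90.0):
            raise CalibrationError("expected ground-plane angle must be 0 or +-90 degrees")


# Body-part assumptions: chest and feet share the pelvis heading (0), head and
# limbs are mounted sideways (90); signs encode which way each side faces.
DEFAULT_ASSUMPTIONS: Dict[str, HeadingAssumption] = {
    a.device: a
    for a in [
        HeadingAssumption("thorax", "Y", 0.0),
        HeadingAssumption("head", "X", -90.0),
        HeadingAssumption("foot_R", "Y", 0.0),
        HeadingAssumption("foot_L", "Y", 0.0),
        HeadingAssumption("thigh_R", "Y", 90.0),
        HeadingAssumption("thigh_L", "Y", -90.0),
        HeadingAssumption("calf_R", "Y", 90.0),
        HeadingAssumption("calf_L", "Y", -90.0),
        HeadingAssumption("upper_arm_R", "Y", 90.0),
        HeadingAssumption("upper_arm_L", "Y", -90.0),
        HeadingAssumption("forearm_R", "X", 90.0),
        HeadingAssumption("forearm_L", "X", -90.0),
        HeadingAssumption("hand_R", "X", 90.0),
        HeadingAssumption("hand_L", "X", -90.0),
    ]
}

_AXIS_VEC = {"X": np.array([1.0, 0.0, 0.0]), "Y": np.array([0.0, 1.0, 0.0])}


def heading_alpha(
    sensor_rotation_at_0: np.ndarray,
    pelvis_rotation_at_0: np.ndarray,
    assumption: HeadingAssumption,
) -> float:
    """Heading correction angle for one sensor, degrees in (-180, 180].

    ``alpha = expected - measured`` where ``measured`` is the ground-plane
    angle from the pelvis sensor's projected Y axis to the sensor's projected
    assumed axis, each read in its own fusion frame.
    """
    rs = assert_rotation(sensor_rotation_at_0, name="sensor rotation")
    rp = assert_rotation(pelvis_rotation_at_0, name="pelvis rotation")
    try:
        a = project_to_ground(rs @ _AXIS_VEC[assumption.axis])
    except DegenerateProjectionError as e:
        raise CalibrationPoseError(
            f"device {assumption.device!r}: assumed {assumption.axis} axis is near vertical "
            "in the calibration pose (device mis-mounted?)"
        ) from e
    try:
        r = project_to_ground(rp @ _AXIS_VEC["Y"])
    except DegenerateProjectionError as e:
        raise CalibrationPoseError("pelvis sensor Y axis is near vertical") from e
    measured = angle_between_projections(r, a)
    return wrap_angle(assumption.expected - measured)


def heading_rotation(alpha_deg: float) -> np.ndarray:
    """Heading correction matrix: rotation about the vertical axis by alpha."""
    return yaw_rotation(alpha_deg)


def correct_sensor(Rs0Gs: np.ndarray, RGs0G: np.ndarray) -> np.ndarray:
    """Sensor rotation in the shared frame: ``Rs0G = RGs0G @ Rs0Gs``."""
    return np.asarray(RGs0G, dtype=float) @ np.asarray(Rs0Gs, dtype=float)


def sensor_to_bone(Rb0G: np.ndarray, Rs0G: np.ndarray) -> np.ndarray:
    """Constant sensor-to-bone rotation: ``Rs0b = Rb0G.T @ Rs0G``."""
    return np.asarray(Rb0G, dtype=float).T @ np.asarray(Rs0G, dtype=float)


def bone_absolute(RsiG: np.ndarray, Rs0b: np.ndarray) -> np.ndarray:
    """Bone orientation at instant i: ``RbiG = RsiG @ Rs0b.T``."""
    return np.asarray(RsiG, dtype=float) @ np.asarray(Rs0b, dtype=float).T


def bone_relative(RpiG: np.ndarray, RbiG: np.ndarray) -> np.ndarray:
    """Bone relative to its parent: ``Rbip = RpiG.T @ RbiG``."""
    return np.asarray(RpiG, dtype=float).T @ np.asarray(RbiG, dtype=float)


@dataclass
class DeviceCalibration:
    alpha: float               # heading correction, degrees (0 in optical mode)
    RGs0G: np.ndarray          # full heading correction incl. anatomical anchor
    Rs0b: np.ndarray           # constant sensor-to-bone rotation
    Rb0G: np.ndarray           # neutral-pose bone orientation


@dataclass
class CalibrationResult:
    modality: str
    frame0: int
    anchor_alpha: float                       # shared anatomical-anchor yaw, degrees
    devices: Dict[str, DeviceCalibration]
    average_window_s: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "frame0": self.frame0,
            "anchor_alpha_deg": self.anchor_alpha,
            "average_window_s": self.average_window_s,
            "devices": {
                name: {
                    "alpha_deg": d.alpha,
                    "RGs0G": [float(x) for x in d.RGs0G.ravel()],
                    "Rs0b": [float(x) for x in d.Rs0b.ravel()],
                    "Rb0G": [float(x) for x in d.Rb0G.ravel()],
                }
                for name, d in self.devices.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        devices = {
            name: DeviceCalibration(
                alpha=float(e["alpha_deg"]),
                RGs0G=np.asarray(e["RGs0G"], dtype=float).reshape(3, 3),
                Rs0b=np.asarray(e["Rs0b"], dtype=float).reshape(3, 3),
                Rb0G=np.asarray(e["Rb0G"], dtype=float).reshape(3, 3),
            )
            for name, e in d["devices"].items()
        }
        return cls(
            modality=d["modality"], frame0=int(d["frame0"]),
            anchor_alpha=float(d["anchor_alpha_deg"]), devices=devices,
            average_window_s=d.get("average_window_s"),
        )


def _device_rotations(session: CaptureSession, name: str) -> np.ndarray:
    """(n, 3, 3) device orientations in the Y-up world convention."""
    mats = session.devices[name].rotations()
    if session.meta.get("frame_convention", "yup") == "zup":
        from .rotations import _ZUP_TO_YUP as M
        mats = np.einsum("ij,njk,lk->nil", M, mats, M)
    return mats


def _rotation_at(session, name, frame0, window_s):
    mats = _device_rotations(session, name)
    if window_s is None:
        return mats[frame0]
    n = max(1, int(round(window_s * session.rate)))
    chunk = mats[frame0:frame0 + n]
    return _R.from_matrix(chunk).mean().as_matrix()


def neutral_bone_orientation(bone: str) -> np.ndarray:
    """Neutral-pose bone orientation ``Rb0G``.

    In the calibration pose (standing, legs vertical, feet pointing forward)
    every bone's local frame is aligned with the world frame, so the neutral
    orientation is the identity for all bones.
    """
    return np.eye(3)


def calibrate(
    session: CaptureSession,
    skeleton: SkeletonDefinition,
    frame0: int = 0,
    assumptions: Optional[Mapping[str, HeadingAssumption]] = None,
    average_window_s: Optional[float] = None,
    expected_devices=None,
) -> CalibrationResult:
    """Run the anatomical calibration at ``frame0`` of a neutral-pose capture.

    IMU mode applies the magnetometer-free heading correction (per-device
    ``alpha`` from the mounting assumptions plus the shared anatomical
    anchor); optical mode uses the camera frame directly (alpha = 0).
    """
    if not 0 <= frame0 < session.n_frames:
        raise CalibrationError(f"frame0={frame0} outside session of {session.n_frames} frames")
    devices = list(expected_devices) if expected_devices is not None else list(session.devices)
    session.require_devices(devices, frame=frame0)
    unknown = [d for d in devices if d not in skeleton.bones]
    if unknown:
        raise CalibrationError(f"device(s) with no matching bone: {', '.join(unknown)}")
    assumptions = dict(DEFAULT_ASSUMPTIONS if assumptions is None else assumptions)

    out: Dict[str, DeviceCalibration] = {}
    anchor = 0.0
    if session.modality == "imu":
        if "pelvis" not in devices:
            raise CalibrationError("IMU calibration requires the pelvis sensor (defines the shared frame)")
        rp0 = _rotation_at(session, "pelvis", frame0, average_window_s)
        # anatomical anchor: yaw the shared frame so the pelvis sensor's
        # projected Y axis lands on the world +X (mediolateral) axis
        try:
            r = project_to_ground(rp0 @ _AXIS_VEC["Y"])
        except DegenerateProjectionError as e:
            raise CalibrationPoseError("pelvis sensor Y axis is near vertical") from e
        anchor = wrap_angle(-angle_between_projections(np.array([1.0, 0.0]), r))
        for name in devices:
            rs0_gs = _rotation_at(session, name, frame0, average_window_s)
            if name == "pelvis":
                alpha = 0.0
            else:
                if name not in assumptions:
                    raise CalibrationError(f"no heading assumption for device {name!r}")
                alpha = heading_alpha(rs0_gs, rp0, assumptions[name])
            RGs0G = heading_rotation(anchor + alpha)
            rs0_g = correct_sensor(rs0_gs, RGs0G)
            rb0 = neutral_bone_orientation(name)
            out[name] = DeviceCalibration(alpha=alpha, RGs0G=RGs0G,
                                          Rs0b=sensor_to_bone(rb0, rs0_g), Rb0G=rb0)
    else:
        for name in devices:
            rs0_g = _rotation_at(session, name, frame0, average_window_s)
            rb0 = neutral_bone_orientation(name)
            out[name] = DeviceCalibration(alpha=0.0, RGs0G=np.eye(3),
                                          Rs0b=sensor_to_bone(rb0, rs0_g), Rb0G=rb0)
    return CalibrationResult(
        modality=session.modality, frame0=frame0, anchor_alpha=anchor,
        devices=out, average_window_s=average_window_s,
    )


@dataclass
class BonePoseSeries:
    """Per-frame bone poses: absolute/relative rotations, joint angles, positions.

    ``euler`` columns follow :data:`EULER_COLUMNS`: (x, z, y) intrinsic
    rotating-frame order, degrees.  Positions are joint-centre (bone-origin)
    positions in cm in the world frame.
    """

    rate: float
    timestamps: np.ndarray
    absolute: Dict[str, np.ndarray]   # (n,3,3)
    relative: Dict[str, np.ndarray]   # (n,3,3); pelvis: == absolute
    euler: Dict[str, np.ndarray]      # (n,3) degrees, columns (x, z, y)
    position: Dict[str, np.ndarray]   # (n,3) cm
    environment: str = "overground"
    belt_speed: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def angle(self, bone: str, component: str) -> np.ndarray:
        """One Euler component series, degrees; component in {'x','z','y'}."""
        return self.euler[bone][:, EULER_COLUMNS.index(component)]


def track(
    session: CaptureSession,
    calibration: CalibrationResult,
    skeleton: SkeletonDefinition,
) -> BonePoseSeries:
    """Apply a calibration to a capture, producing the bone-pose series.

    IMU mode drives joint-centre positions by forward kinematics from the
    root pose (the pelvis translation channel when the session provides one,
    else a fixed root); optical mode reads each bone-origin position from its
    cluster's rigid-transform translation.
    """
    if calibration.modality != session.modality:
        raise CalibrationError(
            f"calibration is for {calibration.modality!r} but session is {session.modality!r}"
        )
    session.fill_gaps()
    names = [n for n in calibration.devices if n in session.devices]
    n = session.n_frames

    absolute: Dict[str, np.ndarray] = {}
    for name in names:
        cal = calibration.devices[name]
        mats = _device_rotations(session, name)
        # RsiG = RGs0G @ RsiGs ; RbiG = RsiG @ Rs0b^T     (per frame)
        rs = np.einsum("ij,njk->nik", cal.RGs0G, mats)
        absolute[name] = np.einsum("nij,kj->nik", rs, cal.Rs0b)

    relative: Dict[str, np.ndarray] = {}
    euler: Dict[str, np.ndarray] = {}
    for name in names:
        parent = skeleton.parent_of(name)
        while parent is not None and parent not in absolute:
            parent = skeleton.parent_of(parent)  # skip uninstrumented links
        if parent is None:
            rel = absolute[name]
        else:
            rel = np.einsum("nji,njk->nik", absolute[parent], absolute[name])
        relative[name] = rel
        ang = _R.from_matrix(rel).as_euler("XZY", degrees=True)
        euler[name] = ang

    position: Dict[str, np.ndarray] = {}
    if session.modality == "optical":
        for name in names:
            t = session.devices[name].translations
            if t is None:
                raise CalibrationError(f"optical device {name!r} has no translation channel")
            position[name] = np.asarray(t, dtype=float)
    else:
        pelvis_t = session.devices.get("pelvis")
        root = (
            np.asarray(pelvis_t.translations, dtype=float)
            if pelvis_t is not None and pelvis_t.translations is not None
            else np.zeros((n, 3))
        )
        position = _fk_positions(skeleton, absolute, root, names)

    return BonePoseSeries(
        rate=session.rate, timestamps=session.timestamps,
        absolute=absolute, relative=relative, euler=euler, position=position,
        environment=session.environment, belt_speed=session.belt_speed,
        meta={"frame0": calibration.frame0},
    )


def _fk_positions(skeleton, absolute, root, names):
    """Vectorised per-frame forward kinematics over the instrumented chain."""
    position: Dict[str, np.ndarray] = {}
    eff: Dict[str, np.ndarray] = {}
    n = root.shape[0]
    for bone in skeleton.ordered():
        if bone.parent is None:
            position[bone.name] = np.broadcast_to(root, (n, 3)).copy() if root.ndim == 1 else root.copy()
        elif bone.parent in position:
            position[bone.name] = position[bone.parent] + np.einsum(
                "nij,j->ni", eff[bone.parent], bone.offset
            )
        else:
            continue
        if bone.name in absolute:
            eff[bone.name] = absolute[bone.name]
        elif bone.parent in eff:
            eff[bone.name] = eff[bone.parent]
        else:
            eff[bone.name] = np.broadcast_to(np.eye(3), (n, 3, 3))
    return {k: v for k, v in position.items() if k in names}
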