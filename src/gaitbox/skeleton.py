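"""Bone hierarchy, anthropometric scaling and forward kinematics.

The human model is a 20-bone skeleton rooted at the pelvis; 15 bones can be
instrumented with a device (an IMU or an optical marker cluster).  Every bone
local frame is aligned with the world frame in the neutral standing pose
(neutral rotation = identity); the geometry of each bone lives in its offset
vector, i.e. the position of the bone origin (its proximal joint centre)
expressed in the parent frame.  Lengths are centimetres.

In IMU mode the skeleton is scaled linearly from the subject's height using
fixed published segment-proportion ratios; hip-joint spacing comes from the
iliac-crest width and shoulder spacing from the elbow span.  In optical mode
joint centres are placed from pointer-measured anatomical landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "Anthropometrics",
    "Bone",
    "SkeletonDefinition",
    "build_skeleton",
    "forward_kinematics",
    "GAIT_BONES",
    "INSTRUMENTED_BONES",
]


class ConfigurationError(ValueError):
    pass


class IncompleteChainError(KeyError):
    """A bone in the kinematic chain has no rotation supplied."""


# Segment lengths as fractions of standing height (classical segment-proportion
# table used for scaling link models from stature).
_H = {
    "pelvis_height": 0.065,   # pelvis centre above the hip-joint line
    "lumbar": 0.12,           # pelvis centre to thorax origin
    "thorax": 0.17,           # thorax origin to neck root
    "neck": 0.03,             # neck root to head origin
    "head": 0.085,            # head origin to vertex
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.108,
    "thigh": 0.245,           # hip centre to knee centre
    "calf": 0.246,            # knee centre to ankle centre
    "foot_length": 0.152,
    "ankle_height": 0.039,
    "hip_centre_from_crest": 0.77,  # hip-joint spacing / iliac-crest width
    "shoulder_from_elbow_span": 0.40,  # shoulder spacing / elbow span
}


@dataclass(frozen=True)
class Anthropometrics:
    """Subject dimensions; lengths in cm.

    ``landmarks`` (optical mode) maps landmark names to world positions in the
    neutral pose, measured with an instrumented pointer: both acromions,
    greater trochanters, external malleoli and iliac crests.
    """

    height: float
    elbow_span: Optional[float] = None
    iliac_crest_width: Optional[float] = None
    landmarks: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.height > 0):
            raise ConfigurationError("height must be positive")
        for name, v in (("elbow_span", self.elbow_span), ("iliac_crest_width", self.iliac_crest_width)):
            if v is not None and not (v > 0):
                raise ConfigurationError(f"{name} must be positive")

    @property
    def leg_length(self) -> float:
        """Hip centre to ankle centre, cm."""
        return (_H["thigh"] + _H["calf"]) * self.height


@dataclass(frozen=True)
class Bone:
    name: str
    parent: Optional[str]          # None only for the pelvis root
    offset: np.ndarray             # origin in the parent frame, cm
    length: float                  # cm, used for reporting only
    instrumented: bool = True
    side: Optional[str] = None     # "R" / "L" / None


_OPTICAL_LANDMARKS = (
    "acromion_R", "acromion_L",
    "trochanter_R", "trochanter_L",
    "malleolus_R", "malleolus_L",
    "iliac_crest_R", "iliac_crest_L",
)

#: the eight bones needed for gait analysis
GAIT_BONES = ("pelvis", "thorax", "thigh_R", "thigh_L", "calf_R", "calf_L", "foot_R", "foot_L")

#: the fifteen instrumentable bones of the full-body model
INSTRUMENTED_BONES = GAIT_BONES + (
    "head", "upper_arm_R", "upper_arm_L", "forearm_R", "forearm_L", "hand_R", "hand_L",
)


@dataclass
class SkeletonDefinition:
    """Ordered bone list; acyclic, rooted at the pelvis."""

    bones: Dict[str, Bone]
    mode: str  # "imu" | "optical"

    def __post_init__(self):
        roots = [b for b in self.bones.values() if b.parent is None]
        if len(roots) != 1 or roots[0].name != "pelvis":
            raise ConfigurationError("skeleton must have the pelvis as its single root")
        for b in self.bones.values():
            if b.parent is not None and b.parent not in self.bones:
                raise ConfigurationError(f"bone {b.name!r} has unknown parent {b.parent!r}")
        # cycle check by walking to the root from every bone
        for b in self.bones.values():
            seen, cur = set(), b
            while cur.parent is not None:
                if cur.name in seen:
                    raise ConfigurationError("bone hierarchy contains a cycle")
                seen.add(cur.name)
                cur = self.bones[cur.parent]

    def parent_of(self, name: str) -> Optional[str]:
        return self.bones[name].parent

    def ordered(self) -> Iterable[Bone]:
        """Bones in parent-before-child order."""
        out, done = [], set()

        def visit(b: Bone):
            if b.name in done:
                return
            if b.parent is not None:
                visit(self.bones[b.parent])
            done.add(b.name)
            out.append(b)

        for b in self.bones.values():
            visit(b)
        return out

    @property
    def instrumented(self):
        return [b.name for b in self.bones.values() if b.instrumented]

    @property
    def stature(self) -> float:
        """Neutral-pose floor-to-vertex height in cm (foot sole to head top)."""
        b = self.bones
        ankle_height = abs(b["toes_R"].offset[1])
        up = b["thorax"].offset[1] + b["neck"].offset[1] + b["head"].offset[1] + b["head"].length
        down = abs(b["thigh_R"].offset[1]) + abs(b["calf_R"].offset[1]) + abs(b["foot_R"].offset[1])
        return float(ankle_height + down + up)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "bones": [
                {
                    "name": b.name,
                    "parent": b.parent,
                    "offset_cm": [float(x) for x in b.offset],
                    "length_cm": float(b.length),
                    "instrumented": b.instrumented,
                    "side": b.side,
                }
                for b in self.ordered()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonDefinition":
        bones = {
            e["name"]: Bone(
                name=e["name"], parent=e["parent"], offset=np.asarray(e["offset_cm"], dtype=float),
                length=float(e["length_cm"]), instrumented=bool(e["instrumented"]), side=e.get("side"),
            )
            for e in d["bones"]
        }
        return cls(bones=bones, mode=d["mode"])


def _imu_joint_centres(a: Anthropometrics) -> dict:
    h = a.height
    crest = a.iliac_crest_width if a.iliac_crest_width is not None else 0.16 * h
    span = a.elbow_span if a.elbow_span is not None else 0.52 * h
    return {
        "half_hip": 0.5 * _H["hip_centre_from_crest"] * crest,
        "half_shoulder": 0.5 * _H["shoulder_from_elbow_span"] * span,
        "thigh": _H["thigh"] * h,
        "calf": _H["calf"] * h,
        "foot": _H["foot_length"] * h,
        "ankle_height": _H["ankle_height"] * h,
        "pelvis_drop": _H["pelvis_height"] * h,
        "lumbar": _H["lumbar"] * h,
        "thorax": _H["thorax"] * h,
        "neck": _H["neck"] * h,
        "head": _H["head"] * h,
        "upper_arm": _H["upper_arm"] * h,
        "forearm": _H["forearm"] * h,
        "hand": _H["hand"] * h,
    }


def _optical_joint_centres(a: Anthropometrics) -> dict:
    missing = [k for k in _OPTICAL_LANDMARKS if k not in a.landmarks]
    if missing:
        raise ConfigurationError(f"optical mode requires landmarks: {', '.join(missing)}")
    lm = {k: np.asarray(v, dtype=float) for k, v in a.landmarks.items()}
    d = _imu_joint_centres(a)  # height-scaled fallbacks for segments without landmarks
    hip_R = lm["trochanter_R"]
    hip_L = lm["trochanter_L"]
    knee_frac = _H["thigh"] / (_H["thigh"] + _H["calf"])
    for side in ("R", "L"):
        hip, mall = lm[f"trochanter_{side}"], lm[f"malleolus_{side}"]
        leg = np.linalg.norm(hip - mall)
        d[f"thigh_{side}"] = knee_frac * leg
        d[f"calf_{side}"] = (1 - knee_frac) * leg
    d["half_hip"] = 0.5 * np.linalg.norm(hip_R - hip_L)
    d["half_shoulder"] = 0.5 * np.linalg.norm(lm["acromion_R"] - lm["acromion_L"])
    d["crest_width"] = np.linalg.norm(lm["iliac_crest_R"] - lm["iliac_crest_L"])
    return d


def build_skeleton(a: Anthropometrics, mode: str = "imu") -> SkeletonDefinition:
    """Build a scaled skeleton for ``mode`` ("imu" or "optical").

    IMU mode scales every segment linearly from the subject's height; optical
    mode places the lower-limb joint centres from pointer-measured landmarks.
    """
    if mode not in ("imu", "optical"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    d = _imu_joint_centres(a) if mode == "imu" else _optical_joint_centres(a)

    def seg(side, key):
        return d.get(f"{key}_{side}", d.get(key))

    bones: Dict[str, Bone] = {}

    def add(name, parent, offset, length, instrumented=True, side=None):
        bones[name] = Bone(name, parent, np.asarray(offset, dtype=float), float(length),
                           instrumented, side)

    add("pelvis", None, [0.0, 0.0, 0.0], d["pelvis_drop"])
    add("thorax", "pelvis", [0.0, d["lumbar"], 0.0], d["thorax"])
    add("neck", "thorax", [0.0, d["thorax"], 0.0], d["neck"], instrumented=False)
    add("head", "neck", [0.0, d["neck"], 0.0], d["head"])
    for s, sign in (("R", 1.0), ("L", -1.0)):
        add(f"clavicle_{s}", "thorax", [sign * 0.5 * d["half_shoulder"], d["thorax"], 0.0],
            0.5 * d["half_shoulder"], instrumented=False, side=s)
        add(f"upper_arm_{s}", f"clavicle_{s}", [sign * 0.5 * d["half_shoulder"], 0.0, 0.0],
            d["upper_arm"], side=s)
        add(f"forearm_{s}", f"upper_arm_{s}", [0.0, -d["upper_arm"], 0.0], d["forearm"], side=s)
        add(f"hand_{s}", f"forearm_{s}", [0.0, -d["forearm"], 0.0], d["hand"], side=s)
        add(f"thigh_{s}", "pelvis", [sign * d["half_hip"], -d["pelvis_drop"], 0.0],
            seg(s, "thigh"), side=s)
        add(f"calf_{s}", f"thigh_{s}", [0.0, -seg(s, "thigh"), 0.0], seg(s, "calf"), side=s)
        add(f"foot_{s}", f"calf_{s}", [0.0, -seg(s, "calf"), 0.0], d["foot"], side=s)
        add(f"toes_{s}", f"foot_{s}", [0.0, -d["ankle_height"], d["foot"]], 0.3 * d["foot"],
            instrumented=False, side=s)
    return SkeletonDefinition(bones=bones, mode=mode)


def forward_kinematics(
    skeleton: SkeletonDefinition,
    rotations: Mapping[str, np.ndarray],
    root_position: np.ndarray = (0.0, 0.0, 0.0),
    bones: Optional[Iterable[str]] = None,
) -> Dict[str, np.ndarray]:
    """Joint-centre (bone-origin) positions from absolute bone rotations.

    Each bone origin is placed at ``parent origin + R_parent @ offset`` where
    ``R_parent`` is the parent's absolute rotation in the world frame; the
    root origin is ``root_position``.  Only the requested ``bones`` (plus
    their ancestors) are computed; non-instrumented bones inherit the
    parent's rotation.
    """
    wanted = set(bones) if bones is not None else set(skeleton.bones)
    positions: Dict[str, np.ndarray] = {}
    eff_rot: Dict[str, np.ndarray] = {}
    root = np.asarray(root_position, dtype=float)

    for bone in skeleton.ordered():
        if bone.name not in wanted and not any(
            _is_ancestor(skeleton, bone.name, w) for w in wanted
        ):
            continue
        if bone.parent is None:
            positions[bone.name] = root.copy()
        else:
            p_rot = eff_rot[bone.parent]
            positions[bone.name] = positions[bone.parent] + p_rot @ bone.offset
        if bone.name in rotations:
            eff_rot[bone.name] = np.asarray(rotations[bone.name], dtype=float)
        elif bone.parent is not None:
            eff_rot[bone.name] = eff_rot[bone.parent]
        elif bone.instrumented:
            raise IncompleteChainError(f"no rotation supplied for bone {bone.name!r}")
        else:
            eff_rot[bone.name] = np.eye(3)
        if bone.name in wanted and bone.instrumented and bone.name not in rotations:
            raise IncompleteChainError(f"no rotation supplied for bone {bone.name!r}")
    return {k: v for k, v in positions.items() if k in wanted}


def _is_ancestor(sk: SkeletonDefinition, anc: str, name: str) -> bool:
    cur = sk.bones[name].parent
    while cur is not None:
        if cur == anc:
            return True
        cur = sk.bones[cur].parent
    return False
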