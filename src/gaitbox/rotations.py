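"""Rotation algebra shared by both capture modalities.

Conventions used throughout the package:

* World frame: X mediolateral (subject's right is +X), Y vertical (up),
  Z anteroposterior (direction of progression is +Z). Right-handed.
* Rotations are 3x3 orthonormal matrices with determinant +1.
* Quaternions are scalar-first ``(w, x, y, z)`` unit quaternions.
* Euler angles use the intrinsic ("rotating frame") x-z-y order and are
  reported in degrees: the X component is flexion-extension, the Z component
  tilt / ab-adduction, and the Y component axial (internal-external) rotation
  of a bone whose local frame is aligned with the world frame in the neutral
  pose.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as _R

__all__ = [
    "VERTICAL_AXIS",
    "GROUND_AXES",
    "quat_to_rotation",
    "rotation_to_quat",
    "matrix_from_euler_rxzy",
    "euler_rxzy",
    "yaw_rotation",
    "project_to_ground",
    "angle_between_projections",
    "assert_rotation",
    "is_rotation",
    "random_rotation",
    "from_zup",
]

#: index of the vertical (up) axis in the world frame
VERTICAL_AXIS = 1
#: indices of the two ground-plane axes, ordered (X mediolateral, Z anteroposterior)
GROUND_AXES = (0, 2)

_GIMBAL_DEG = 89.99


class InvalidRotationError(ValueError):
    """Raised when a matrix or quaternion does not describe a rotation."""


def is_rotation(m: np.ndarray, tol: float = 1e-9) -> bool:
    """True if ``m`` is a proper rotation matrix within ``tol``."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.all(np.isfinite(m)):
        return False
    if not np.allclose(m.T @ m, np.eye(3), atol=tol):
        return False
    return bool(np.isclose(np.linalg.det(m), 1.0, atol=tol))


def assert_rotation(m: np.ndarray, tol: float = 1e-6, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if not is_rotation(m, tol=tol):
        raise InvalidRotationError(f"{name} is not a proper rotation matrix")
    return m


def quat_to_rotation(q) -> np.ndarray:
    """Convert a scalar-first unit quaternion ``(w, x, y, z)`` to a matrix.

    The quaternion is renormalised when its norm deviates from one by less
    than 1e-3; a larger deviation (or a non-finite / near-zero quaternion)
    is treated as corrupt input. ``q`` and ``-q`` map to the same rotation.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,) or not np.all(np.isfinite(q)):
        raise InvalidRotationError("quaternion must be 4 finite numbers (w, x, y, z)")
    n = np.linalg.norm(q)
    if n < 1e-6:
        raise InvalidRotationError("near-zero-norm quaternion")
    if abs(n - 1.0) > 1e-3:
        raise InvalidRotationError(f"quaternion norm {n:.6f} too far from 1")
    w, x, y, z = q / n
    # scipy uses scalar-last ordering
    return _R.from_quat([x, y, z, w]).as_matrix()


def rotation_to_quat(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_to_rotation`; returns ``(w, x, y, z)`` with w >= 0."""
    x, y, z, w = _R.from_matrix(np.asarray(m, dtype=float)).as_quat()
    q = np.array([w, x, y, z])
    return -q if w < 0 else q


def matrix_from_euler_rxzy(theta_x: float, theta_z: float, theta_y: float) -> np.ndarray:
    """Compose a rotation from intrinsic x-z-y Euler angles in degrees."""
    angles = np.array([theta_x, theta_z, theta_y], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("Euler angles must be finite")
    return _R.from_euler("XZY", angles, degrees=True).as_matrix()


def euler_rxzy(m: np.ndarray, tol: float = 1e-6):
    """Decompose a rotation into intrinsic x-z-y Euler angles in degrees.

    Returns ``(theta_x, theta_z, theta_y, gimbal)`` with
    ``theta_x, theta_y in (-180, 180]`` and ``theta_z in [-90, 90]``.
    Within 0.01 degrees of the gimbal singularity (|theta_z| = 90) the
    decomposition is degenerate; the y angle is tied to 0 and ``gimbal``
    is True.
    """
    import warnings as _warnings

    m = assert_rotation(m, tol=tol)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # scipy announces the gimbal case
        tx, tz, ty = _R.from_matrix(m).as_euler("XZY", degrees=True)
    gimbal = bool(abs(tz) > _GIMBAL_DEG)
    if gimbal:
        # singular decomposition: x and y rotations merge; the tie is broken
        # by folding everything into x and reporting y = 0
        ty = 0.0
        tz = 90.0 if tz > 0 else -90.0
    return float(tx), float(tz), float(ty), gimbal


def yaw_rotation(alpha_deg: float) -> np.ndarray:
    """Rotation about the vertical (Y) axis by ``alpha_deg`` degrees.

    Layout::

        ( cos a   0   sin a )
        (   0     1     0   )
        (-sin a   0   cos a )
    """
    if not np.isfinite(alpha_deg):
        raise ValueError("heading angle must be finite")
    a = np.deg2rad(alpha_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


class DegenerateProjectionError(ValueError):
    """A vector too close to vertical has no meaningful ground projection."""


def project_to_ground(v: np.ndarray) -> np.ndarray:
    """Project a 3-vector onto the ground plane, returning (x, z) coordinates.

    Raises :class:`DegenerateProjectionError` when the vector is within one
    degree of the vertical axis.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("expected a finite 3-vector")
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no projection")
    horiz = np.array([v[GROUND_AXES[0]], v[GROUND_AXES[1]]])
    # angle from the ground plane
    elevation = np.rad2deg(np.arcsin(np.clip(abs(v[VERTICAL_AXIS]) / n, -1, 1)))
    if elevation > 89.0:
        raise DegenerateProjectionError(
            f"vector within 1 degree of vertical (elevation {elevation:.2f})"
        )
    return horiz


def angle_between_projections(a: np.ndarray, b: np.ndarray) -> float:
    """Signed angle in degrees from ground-plane vector ``a`` to ``b``.

    Positive counter-clockwise when viewed from above (+Y looking down),
    result in (-180, 180].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (2,) or b.shape != (2,):
        raise ValueError("expected 2-vectors in ground-plane coordinates")
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise ValueError("zero vector has no direction")
    # ground coordinates are (x, z); viewed from above with +Y toward the
    # viewer, the frame (x, z) is left-handed, so the ccw angle flips sign.
    cross = a[0] * b[1] - a[1] * b[0]
    dot = a[0] * b[0] + a[1] * b[1]
    ang = -np.rad2deg(np.arctan2(cross, dot))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


# Fixed axis permutation between an IMU fusion frame (Z up, Fig.-7 style) and
# the package world frame (Y up). Applied once at ingestion; cyclic, det +1:
# world x <- fusion y, world y <- fusion z, world z <- fusion x.
_ZUP_TO_YUP = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])


def from_zup(m: np.ndarray) -> np.ndarray:
    """Re-express a rotation given in a Z-up frame in the Y-up world frame."""
    return _ZUP_TO_YUP @ np.asarray(m, dtype=float) @ _ZUP_TO_YUP.T


def to_zup(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`from_zup` (used by the simulator when emitting streams)."""
    return _ZUP_TO_YUP.T @ np.asarray(m, dtype=float) @ _ZUP_TO_YUP


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (used by the simulator and tests)."""
    return _R.random(rng=rng).as_matrix()
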