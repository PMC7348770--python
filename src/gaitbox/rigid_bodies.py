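"""Optical marker-cluster (rigid-body) geometry checks.

Each rigid body is a cluster of three reflective markers with fixed mutual
distances.  Two quantities matter when designing a cluster set:

* the maximum orientation error ``Eo = 2 asin(Ep / Dmin) * 180/pi`` in
  degrees, where ``Ep`` is the camera system's mean marker positioning
  error and ``Dmin`` the smallest marker-to-marker distance — the worst-case
  angular error of the rigid transform fitted to the cluster;
* distinguishability: the tracking software identifies clusters by their
  unique distance triples, so no two clusters may share (near-)identical
  marker-to-marker distances.

A reference cluster set for a 15-device full-body configuration ships with
the package (``data/rigid_body_geometry.json``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Tuple

__all__ = [
    "RigidBodyGeometry",
    "orientation_error",
    "check_uniqueness",
    "load_reference_geometries",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RigidBodyGeometry:
    """Three-marker cluster: distances in mm, positioning error in mm."""

    name: str
    d12: float
    d13: float
    d23: float
    ep: float = 0.34
    side: Optional[str] = None

    def __post_init__(self):
        d = sorted((self.d12, self.d13, self.d23))
        if d[0] <= 0:
            raise GeometryError(f"{self.name}: distances must be positive")
        if d[0] + d[1] <= d[2]:
            raise GeometryError(f"{self.name}: distances violate the triangle inequality")

    @property
    def dmin(self) -> float:
        return min(self.d12, self.d13, self.d23)

    @property
    def distances(self) -> Tuple[float, float, float]:
        return (self.d12, self.d13, self.d23)


def orientation_error(geom: RigidBodyGeometry) -> float:
    """Maximum orientation error Eo in degrees: 2 asin(Ep/Dmin) * 180/pi."""
    if geom.ep >= geom.dmin:
        raise GeometryError(
            f"{geom.name}: positioning error {geom.ep} mm >= smallest marker "
            f"distance {geom.dmin} mm"
        )
    return 2.0 * math.asin(geom.ep / geom.dmin) * 180.0 / math.pi


def check_uniqueness(geoms: List[RigidBodyGeometry], tol_mm: float = 5.0):
    """Pairs of clusters whose sorted distance triples agree within ``tol_mm``.

    An empty list means every cluster is distinguishable by the tracking
    software at that tolerance.
    """
    if len(geoms) < 2:
        raise GeometryError("uniqueness check needs at least two clusters")
    conflicts = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            a = sorted(geoms[i].distances)
            b = sorted(geoms[j].distances)
            if all(abs(x - y) <= tol_mm for x, y in zip(a, b)):
                conflicts.append((geoms[i].name, geoms[j].name))
    return conflicts


def load_reference_geometries(path=None) -> List[RigidBodyGeometry]:
    """The packaged 15-cluster reference geometry set."""
    if path is None:
        text = resources.files("gaitbox.data").joinpath("rigid_body_geometry.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    ep = float(doc.get("positioning_error_mm", 0.34))
    return [
        RigidBodyGeometry(
            name=e["name"], side=e.get("side"),
            d12=float(e["d12_mm"]), d13=float(e["d13_mm"]), d23=float(e["d23_mm"]),
            ep=float(e.get("ep_mm", ep)),
        )
        for e in doc["rigid_bodies"]
    ]
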