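"""Capture sessions and their on-disk format.

A :class:`CaptureSession` holds the per-frame streams of every body-worn
device for one capture: unit quaternions for IMUs (60 Hz by default) or
rigid transforms (rotation + translation) for optical marker clusters
(120 Hz by default), plus optional translation channels (e.g. the pelvis
root trajectory).  Streams are synchronous and frame-indexed; short dropouts
are interpolated at ingestion, longer ones are an error.

The file format is a schema-versioned CSV: ``#``-prefixed header lines
(modality, rate, units, device list) followed by one row per frame with a
timestamp and per-device columns (``dev.qw..dev.qz`` for orientations —
optical rotations are stored as quaternions too, losslessly — and
``dev.tx..dev.tz`` for translations).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _R, Slerp

from .rotations import quat_to_rotation

__all__ = ["CaptureSession", "read_capture", "write_capture", "CaptureFormatError"]

SCHEMA_VERSION = "1.0"
MAX_GAP_S = 0.1


class CaptureFormatError(ValueError):
    pass


class FrameGapError(ValueError):
    """A stream dropout longer than the interpolation limit."""


@dataclass
class DeviceStream:
    """Frame-indexed stream of one device."""

    quaternions: Optional[np.ndarray] = None   # (n, 4) scalar-first
    translations: Optional[np.ndarray] = None  # (n, 3) cm, world frame

    def rotation_at(self, i: int) -> np.ndarray:
        if self.quaternions is None:
            raise CaptureFormatError("device has no orientation channel")
        return quat_to_rotation(self.quaternions[i])

    def rotations(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices for the whole stream."""
        q = self.quaternions
        if q is None:
            raise CaptureFormatError("device has no orientation channel")
        n = np.linalg.norm(q, axis=1, keepdims=True)
        qn = q / n
        return _R.from_quat(qn[:, [1, 2, 3, 0]]).as_matrix()


@dataclass
class CaptureSession:
    """Synchronous multi-device capture."""

    modality: str                      # "imu" | "optical"
    rate: float                        # Hz
    devices: Dict[str, DeviceStream]
    timestamps: np.ndarray             # (n,) seconds
    environment: str = "overground"    # "overground" | "treadmill"
    belt_speed: Optional[float] = None  # cm/s, treadmill mode
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in ("imu", "optical"):
            raise CaptureFormatError(f"unknown modality {self.modality!r}")
        t = np.asarray(self.timestamps, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise CaptureFormatError("session needs at least two frames")
        if np.any(np.diff(t) <= 0):
            raise CaptureFormatError("timestamps must be strictly increasing")
        med = float(np.median(np.diff(t)))
        if abs(med - 1.0 / self.rate) > 0.01 / self.rate:
            raise CaptureFormatError(
                f"declared rate {self.rate} Hz does not match median frame spacing {1.0/med:.2f} Hz"
            )
        self.timestamps = t

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def fill_gaps(self) -> "CaptureSession":
        """Interpolate missing quaternion frames (NaN rows) up to 0.1 s.

        Slerp on quaternions, linear on translations; a longer dropout
        raises :class:`FrameGapError`.
        """
        dt = 1.0 / self.rate
        max_gap = int(round(MAX_GAP_S / dt))
        for name, stream in self.devices.items():
            for attr in ("quaternions", "translations"):
                arr = getattr(stream, attr)
                if arr is None:
                    continue
                bad = np.any(~np.isfinite(arr), axis=1)
                if not bad.any():
                    continue
                runs = _runs(bad)
                for a, b in runs:
                    if b - a > max_gap or a == 0 or b == len(arr):
                        raise FrameGapError(
                            f"device {name!r}: gap of {b - a} frames exceeds {MAX_GAP_S} s"
                        )
                good = ~bad
                idx = np.arange(len(arr))
                if attr == "translations":
                    for c in range(arr.shape[1]):
                        arr[bad, c] = np.interp(idx[bad], idx[good], arr[good, c])
                else:
                    qs = arr[good]
                    rot = _R.from_quat(
                        (qs / np.linalg.norm(qs, axis=1, keepdims=True))[:, [1, 2, 3, 0]]
                    )
                    sl = Slerp(idx[good], rot)
                    q = sl(idx[bad]).as_quat()
                    arr[bad] = q[:, [3, 0, 1, 2]]
        return self

    def require_devices(self, names, frame: int = 0) -> None:
        missing = [
            n for n in names
            if n not in self.devices
            or (self.devices[n].quaternions is None and self.devices[n].translations is None)
            or (self.devices[n].quaternions is not None
                and not np.all(np.isfinite(self.devices[n].quaternions[frame])))
        ]
        if missing:
            raise CaptureFormatError(
                f"missing device stream(s) at frame {frame}: {', '.join(missing)}"
            )


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs."""
    out, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def write_capture(session: CaptureSession, path) -> None:
    cols: Dict[str, np.ndarray] = {"time_s": session.timestamps}
    devlist: List[str] = []
    for name, stream in session.devices.items():
        devlist.append(name)
        if stream.quaternions is not None:
            for j, c in enumerate("wxyz"):
                cols[f"{name}.q{c}"] = stream.quaternions[:, j]
        if stream.translations is not None:
            for j, c in enumerate("xyz"):
                cols[f"{name}.t{c}"] = stream.translations[:, j]
    df = pd.DataFrame(cols)
    header = [
        f"# gaitbox-capture v{SCHEMA_VERSION}",
        f"# modality: {session.modality}",
        f"# rate_hz: {session.rate}",
        f"# environment: {session.environment}",
        f"# belt_speed_cm_s: {'' if session.belt_speed is None else session.belt_speed}",
        f"# frame_convention: {session.meta.get('frame_convention', 'yup')}",
        f"# devices: {','.join(devlist)}",
        "# units: time s, translation cm, quaternion w x y z (unit)",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_capture(path) -> CaptureSession:
    """Read and validate a capture file; short gaps are interpolated."""
    header: Dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                elif body.startswith("gaitbox-capture"):
                    header["schema"] = body.split("v", 1)[-1]
            else:
                lines.append(line)
    if "schema" not in header:
        raise CaptureFormatError(f"{path}: not a gaitbox capture file")
    major = header["schema"].split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise CaptureFormatError(f"{path}: unsupported schema major version {header['schema']}")
    try:
        df = pd.read_csv(io.StringIO("".join(lines)))
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise CaptureFormatError(f"{path}: {e}") from e
    if "time_s" not in df.columns:
        raise CaptureFormatError(f"{path}: missing time_s column")
    devices: Dict[str, DeviceStream] = {}
    for name in header.get("devices", "").split(","):
        name = name.strip()
        if not name:
            continue
        qcols = [f"{name}.q{c}" for c in "wxyz"]
        tcols = [f"{name}.t{c}" for c in "xyz"]
        quat = df[qcols].to_numpy(dtype=float) if all(c in df.columns for c in qcols) else None
        trans = df[tcols].to_numpy(dtype=float) if all(c in df.columns for c in tcols) else None
        if quat is None and trans is None:
            raise CaptureFormatError(f"{path}: device {name!r} declared but has no columns")
        devices[name] = DeviceStream(quaternions=quat, translations=trans)
    belt = header.get("belt_speed_cm_s", "")
    session = CaptureSession(
        modality=header.get("modality", "imu"),
        rate=float(header.get("rate_hz", "60")),
        devices=devices,
        timestamps=df["time_s"].to_numpy(dtype=float),
        environment=header.get("environment", "overground"),
        belt_speed=float(belt) if belt else None,
        meta={"frame_convention": header.get("frame_convention", "yup")},
    )
    return session.fill_gaps()


def optical_rotation_columns(session: CaptureSession):  # pragma: no cover - helper
    """Optical sessions store orientations as quaternions too (lossless)."""
    return {n: s.rotations() for n, s in session.devices.items()}
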