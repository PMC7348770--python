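"""Gait-event detection from kinematic curves.

Six events per stride and side (initial contact T1, contralateral toe-off
T2, mid-single-support reference T3, contralateral initial contact T4,
toe-off T5, next initial contact T6) are located from extrema of smoothed
kinematic curves — no force platforms or instrumented treadmill needed.

IMU configuration: the hip flexion-extension curve of each leg, which only
depends on the pelvis and thigh sensors (short error chain).  Initial
contact is the flexion maximum, toe-off the extension minimum; the
contralateral curve supplies T2 and T4 (half a cycle out of phase).

Optical configuration: the anteroposterior displacement curve of each ankle
joint centre on a treadmill, where each cluster is tracked independently.
Anterior maximum = contact, posterior minimum = toe-off; same pairing with
the contralateral foot.

T3 has no closed textual definition in the sources this design follows; it
is defined here as the contralateral curve's crossing of the midpoint
between its T2 minimum and T4 maximum (approximately mid single support)
and is isolated in :func:`_locate_t3` so the choice is easy to revisit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import BonePoseSeries

__all__ = [
    "EventCurve",
    "GaitEventTable",
    "StraightSection",
    "smooth",
    "find_extrema",
    "select_straight_sections",
    "detect_events_imu",
    "detect_events_opt",
    "normalize_stride",
]

EVENT_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6")

#: minimum peak-to-peak range (deg or cm) below which no events are searched
FLAT_CURVE_RANGE = 2.0
DEFAULT_WINDOW_S = 0.2
DEFAULT_MIN_SEPARATION_S = 0.4


class EventDetectionError(ValueError):
    pass


class FlatCurveError(EventDetectionError):
    """The gait pattern shows no usable flexion-extension range."""


@dataclass
class EventCurve:
    """A frame-indexed kinematic curve used for event detection."""

    values: np.ndarray
    rate: float
    kind: str = "hip_flexion"   # "hip_flexion" (deg) | "ankle_ap" (cm)
    side: str = "R"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise EventDetectionError("curve must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise EventDetectionError("curve contains non-finite values")
        if not self.rate > 0:
            raise EventDetectionError("rate must be positive")


@dataclass(frozen=True)
class StraightSection:
    start: int
    stop: int  # exclusive

    def __post_init__(self):
        if not (0 <= self.start < self.stop):
            raise EventDetectionError("section must satisfy 0 <= start < stop")


@dataclass
class GaitEventTable:
    """Per-stride event frames; one row per stride and side."""

    frame: pd.DataFrame  # columns: stride, side, section, T1..T6, valid
    rate: float

    def valid_strides(self, side: Optional[str] = None) -> pd.DataFrame:
        df = self.frame[self.frame["valid"]]
        return df if side is None else df[df["side"] == side]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def smooth(
    curve: EventCurve,
    window_s: float = DEFAULT_WINDOW_S,
    shape: str = "hann",
) -> EventCurve:
    """Sliding-window smoothing by convolution with reflect padding.

    ``shape`` is ``"hann"`` (default) or ``"flat"`` (moving average).  The
    output has the same length as the input, and a constant input is
    returned unchanged.
    """
    if shape not in ("hann", "flat"):
        raise EventDetectionError(f"unknown window shape {shape!r}")
    x = curve.values
    n = int(round(window_s * curve.rate))
    if n <= 1:
        return EventCurve(x.copy(), curve.rate, curve.kind, curve.side)
    if n % 2 == 0:
        n += 1
    if len(x) < n:
        raise EventDetectionError(f"curve of {len(x)} samples shorter than window of {n}")
    w = np.ones(n) if shape == "flat" else np.hanning(n + 2)[1:-1]
    w = w / w.sum()
    pad = n // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    y = np.convolve(xp, w, mode="valid")
    return EventCurve(y, curve.rate, curve.kind, curve.side)


def find_extrema(
    curve: EventCurve,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> Tuple[np.ndarray, np.ndarray]:
    """Alternating local maxima and minima of a (smoothed) curve.

    Returns ``(maxima, minima)`` frame indices.  Same-type extrema closer
    than the minimum separation are suppressed keeping the more extreme one
    (double-peak guard; genuine max-min pairs may be arbitrarily close);
    the final sequence strictly alternates max/min, collapsing same-type
    runs to the more extreme member.  Ties resolve to the earliest frame;
    plateaus to their earliest frame.  A monotone curve yields empty arrays.
    """
    x = curve.values
    n = len(x)
    if n < 3:
        return np.array([], dtype=int), np.array([], dtype=int)

    # local extrema by neighbour comparison, plateau-aware (earliest frame)
    cand: List[Tuple[int, int]] = []  # (index, +1 max / -1 min)
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        left, right = x[i - 1], x[min(j + 1, n - 1)]
        if x[i] > left and x[i] > right:
            cand.append((i, +1))
        elif x[i] < left and x[i] < right:
            cand.append((i, -1))
        i = j + 1
    if not cand:
        return np.array([], dtype=int), np.array([], dtype=int)

    min_sep = int(round(min_separation_s * curve.rate))

    def thin(idxs: List[int], sign: float) -> List[int]:
        """Greedy same-type suppression: keep the more extreme, ties earliest."""
        order = sorted(idxs, key=lambda i: (-sign * x[i], i))
        kept: List[int] = []
        for i in order:
            if all(abs(i - j) >= min_sep for j in kept):
                kept.append(i)
        return sorted(kept)

    maxima = thin([i for i, t in cand if t > 0], +1.0)
    minima = thin([i for i, t in cand if t < 0], -1.0)

    # enforce strict alternation on the combined sequence
    def better(a, b):
        ia, t = a
        ib, _ = b
        if t > 0:
            return a if (x[ia], -ia) >= (x[ib], -ib) else b
        return a if (x[ia], ia) <= (x[ib], ib) else b

    merged = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    alt: List[Tuple[int, int]] = []
    for c in merged:
        if alt and alt[-1][1] == c[1]:
            alt[-1] = better(alt[-1], c)
        else:
            alt.append(c)
    return (np.array([i for i, t in alt if t > 0], dtype=int),
            np.array([i for i, t in alt if t < 0], dtype=int))


def select_straight_sections(
    series: BonePoseSeries,
    manual: Optional[Sequence[Tuple[int, int]]] = None,
    yaw_tolerance_deg: float = 20.0,
    window_s: float = 2.0,
) -> List[StraightSection]:
    """Straight-walking sections of an over-ground capture.

    ``manual`` frame ranges are validated and clipped; with ``manual=None``
    sections are found automatically by keeping stretches where the pelvis
    yaw varies less than ``yaw_tolerance_deg`` over a sliding
    ``window_s``-second window (a heuristic that excludes turns).
    On a treadmill the whole capture is one section.
    """
    n = series.n_frames
    if series.environment == "treadmill" or (manual is not None and len(manual) == 0):
        return [StraightSection(0, n)]
    if manual is not None:
        secs = sorted((int(a), int(b)) for a, b in manual)
        out = []
        for a, b in secs:
            a, b = max(a, 0), min(b, n)
            if a >= b:
                raise EventDetectionError(f"empty section ({a}, {b})")
            if out and a < out[-1].stop:
                raise EventDetectionError("manual sections overlap")
            out.append(StraightSection(a, b))
        return out
    yaw = np.unwrap(np.deg2rad(series.angle("pelvis", "y")))
    yaw = np.rad2deg(yaw)
    w = max(2, int(round(window_s * series.rate)))
    straight = np.zeros(n, dtype=bool)
    half = w // 2
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        straight[i] = (yaw[a:b].max() - yaw[a:b].min()) < yaw_tolerance_deg
    out = []
    start = None
    for i, v in enumerate(straight):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= w:
                out.append(StraightSection(start, i))
            start = None
    if start is not None and n - start >= w:
        out.append(StraightSection(start, n))
    return out


def _check_flat(curve: EventCurve) -> None:
    rng = float(curve.values.max() - curve.values.min())
    if rng < FLAT_CURVE_RANGE:
        raise FlatCurveError(
            f"curve range {rng:.2f} below {FLAT_CURVE_RANGE}: the gait pattern "
            "must show a minimum of flexion and extension"
        )


def _locate_t3(contra: np.ndarray, t2: int, t4: int) -> int:
    """Mid-single-support reference: contralateral mid-value crossing in (T2, T4).

    The contralateral curve rises from its T2 minimum to its T4 maximum;
    T3 is the first frame at or above the midpoint of the two.
    """
    mid = 0.5 * (contra[t2] + contra[t4])
    seg = contra[t2:t4 + 1]
    above = np.nonzero(seg >= mid)[0]
    if len(above) == 0:  # pragma: no cover - monotone segment always crosses
        return (t2 + t4) // 2
    return int(t2 + above[0])


def _peak_preserving(values: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    """Lightly smoothed copy of a curve for final event placement.

    A third of the detection window: wide enough to keep per-frame noise
    from dominating the extremum location, narrow enough that the peak drag
    of heavy smoothing on asymmetric curves stays well under one frame.
    """
    return smooth(EventCurve(values, rate), window_s=window_s / 3.0).values


def _refine_extremum(fine: np.ndarray, idx: int, halfwidth: int, kind: int) -> int:
    """Re-locate an extremum on the peak-preserving curve near ``idx``.

    The heavy smoothing that suppresses false extrema also drags the peak of
    an asymmetric curve by a frame or two; the final event is placed at the
    local extremum of the peak-preserving copy within ``halfwidth`` frames.
    """
    a = max(0, idx - halfwidth)
    b = min(len(fine), idx + halfwidth + 1)
    seg = fine[a:b]
    off = int(np.argmax(seg) if kind > 0 else np.argmin(seg))
    return a + off


def _detect_events(
    ipsiR: EventCurve,
    ipsiL: EventCurve,
    sections: Sequence[StraightSection],
    min_separation_s: float,
    window_s: float,
) -> GaitEventTable:
    if len(ipsiR.values) != len(ipsiL.values) or ipsiR.rate != ipsiL.rate:
        raise EventDetectionError("left and right curves must share length and rate")
    sm = {s: smooth(c, window_s=window_s) for s, c in (("R", ipsiR), ("L", ipsiL))}
    fine = {s: _peak_preserving(c.values, c.rate, window_s)
            for s, c in (("R", ipsiR), ("L", ipsiL))}
    halfwidth = max(2, int(round(window_s * ipsiR.rate / 2.0)))
    for c in sm.values():
        _check_flat(c)
    ext = {}
    for s, c in sm.items():
        maxima, minima = find_extrema(c, min_separation_s)
        ext[s] = (
            np.array(sorted(_refine_extremum(fine[s], i, halfwidth, +1) for i in maxima), dtype=int),
            np.array(sorted(_refine_extremum(fine[s], i, halfwidth, -1) for i in minima), dtype=int),
        )

    rows = []
    stride_id = 0
    for sec_id, sec in enumerate(sections):
        for side in ("R", "L"):
            other = "L" if side == "R" else "R"
            maxima = [i for i in ext[side][0] if sec.start <= i < sec.stop]
            co_max = ext[other][0]
            co_min = ext[other][1]
            ip_min = ext[side][1]
            contra = fine[other]
            for t1, t6 in zip(maxima[:-1], maxima[1:]):
                row = {"stride": stride_id, "side": side, "section": sec_id,
                       "T1": t1, "T6": t6, "valid": True}
                stride_id += 1
                t4s = [i for i in co_max if t1 < i < t6]
                t4 = t4s[0] if len(t4s) == 1 else None
                t2 = next((i for i in co_min if t1 < i < (t4 or t6)), None) if t4 else None
                t5 = next((i for i in ip_min if t4 < i < t6), None) if t4 else None
                if None in (t2, t4, t5):
                    row.update({"T2": -1, "T3": -1, "T4": -1, "T5": -1, "valid": False})
                else:
                    t3 = _locate_t3(contra, t2, t4)
                    row.update({"T2": t2, "T3": t3, "T4": t4, "T5": t5})
                    if not (t1 < t2 <= t3 < t4 < t5 < t6):
                        row["valid"] = False
                rows.append(row)
    if not rows:
        raise EventDetectionError("no strides found in the given sections")
    df = pd.DataFrame(rows, columns=["stride", "side", "section", *EVENT_NAMES, "valid"])
    return GaitEventTable(frame=df, rate=ipsiR.rate)


def detect_events_imu(
    hipR: EventCurve,
    hipL: EventCurve,
    sections: Optional[Sequence[StraightSection]] = None,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    window_s: float = DEFAULT_WINDOW_S,
) -> GaitEventTable:
    """Detect T1..T6 from the two hip flexion-extension curves (IMU mode).

    Per side: T1/T6 at ipsilateral flexion maxima, T5 at the ipsilateral
    extension minimum after T4; T2/T4 at the contralateral extension
    minimum / flexion maximum; T3 at the contralateral mid-value crossing.
    Strides violating T1 < T2 <= T3 < T4 < T5 < T6 are flagged invalid.
    """
    if sections is None:
        sections = [StraightSection(0, len(hipR.values))]
    return _detect_events(hipR, hipL, sections, min_separation_s, window_s)


def detect_events_opt(
    ankleR: EventCurve,
    ankleL: EventCurve,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    window_s: float = DEFAULT_WINDOW_S,
) -> GaitEventTable:
    """Detect T1..T6 from the two ankle anteroposterior displacement curves.

    Treadmill (continuous) captures: the whole session is one section.
    Event-to-extremum mapping mirrors the IMU rules with anterior maxima
    playing the role of flexion maxima.
    """
    sections = [StraightSection(0, len(ankleR.values))]
    return _detect_events(ankleR, ankleL, sections, min_separation_s, window_s)


def normalize_stride(values: np.ndarray, t1: int, t6: int, n_points: int = 101) -> np.ndarray:
    """Resample one stride (frames ``t1..t6`` inclusive) to 0-100 % of the cycle.

    Linear interpolation; the endpoint samples are preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    if not (0 <= t1 < t6 < len(values)) or t6 - t1 < 2:
        raise EventDetectionError("stride must span at least 3 frames inside the series")
    src = np.arange(t1, t6 + 1)
    dst = np.linspace(t1, t6, n_points)
    return np.interp(dst, src, values[t1:t6 + 1])
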