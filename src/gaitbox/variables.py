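"""Spatio-temporal and kinematic gait variables.

Twelve variables are computed per stride and side, then averaged over the
stride set (25 strides in the reference protocol; a warning is issued below
23, where stride statistics are considered stable):

* step length / width: ankle joint-centre separation at initial contact,
  anteroposterior / mediolateral component (cm);
* single support: T2..T4 as a percentage of the stride time; double
  support: (T1..T2) + (T4..T5) as a percentage;
* gait speed: stride length over stride time; on a treadmill the belt speed
  is added to the (near-zero) displacement of the ankle in the room frame;
* seven kinematic ranges (max - min of a joint-angle component between two
  events): trunk tilt T2-T5, pelvic tilt T1-T4, hip flexion-extension T1-T4,
  hip ab/adduction T4-T5, knee flexion-extension T4-T5, ankle dorsi/plantar
  flexion T4-T5, ankle inversion-eversion T1-T3.

Angle and position curves are denoised with a peak-preserving
Savitzky-Golay filter (cubic, 0.15 s window) before ranges and positions
are read off: max-min range estimation shares extremum search's
sensitivity to noise spikes, but a moving-average window of the event
detector's size would clip the genuine peaks that the ranges measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from scipy.signal import savgol_filter

from .calibration import BonePoseSeries
from .events import GaitEventTable

__all__ = [
    "StrideGeometry",
    "GaitVariableTable",
    "VARIABLE_SPECS",
    "step_length",
    "step_width",
    "support_percentages",
    "gait_speed",
    "rom_between_events",
    "compute_all",
]

MIN_STABLE_STRIDES = 23

AX_ML, AX_VERT, AX_AP = 0, 1, 2  # world-frame component indices


class VariableError(ValueError):
    pass


@dataclass
class StrideGeometry:
    """Ankle joint-centre geometry of one stride (world frame, cm)."""

    ankle_ipsi_t1: np.ndarray
    ankle_contra_t1: Optional[np.ndarray]
    ankle_ipsi_t6: np.ndarray
    duration: float                      # seconds
    environment: str = "overground"
    belt_speed: Optional[float] = None   # cm/s

    def __post_init__(self):
        if not self.duration > 0:
            raise VariableError("stride duration must be positive")


def step_length(geom: StrideGeometry) -> float:
    """Anteroposterior ankle-to-ankle distance at initial contact, cm."""
    if geom.ankle_contra_t1 is None:
        raise VariableError("contralateral ankle position missing at T1")
    return float(abs(geom.ankle_ipsi_t1[AX_AP] - geom.ankle_contra_t1[AX_AP]))


def step_width(geom: StrideGeometry) -> float:
    """Mediolateral ankle-to-ankle distance at initial contact, cm."""
    if geom.ankle_contra_t1 is None:
        raise VariableError("contralateral ankle position missing at T1")
    return float(abs(geom.ankle_ipsi_t1[AX_ML] - geom.ankle_contra_t1[AX_ML]))


def support_percentages(t1: int, t2: int, t4: int, t5: int, t6: int):
    """(single %, double %) of the stride time.

    single = 100 (T4-T2)/(T6-T1); double = 100 ((T2-T1)+(T5-T4))/(T6-T1).
    """
    stride = t6 - t1
    if stride <= 0:
        raise VariableError("degenerate stride (T6 <= T1)")
    single = 100.0 * (t4 - t2) / stride
    double = 100.0 * ((t2 - t1) + (t5 - t4)) / stride
    return float(single), float(double)


def gait_speed(geom: StrideGeometry) -> float:
    """Stride length / stride time, cm/s.

    Over ground: the anteroposterior displacement of the ankle between its
    own T1 and T6.  Treadmill: the belt carries the subject, so the belt
    speed is added to the displacement measured in the room frame; the belt
    speed must be configured.
    """
    dz = abs(geom.ankle_ipsi_t6[AX_AP] - geom.ankle_ipsi_t1[AX_AP])
    if geom.environment == "treadmill":
        if geom.belt_speed is None:
            raise VariableError("treadmill mode requires a configured belt speed")
        return float((dz + geom.belt_speed * geom.duration) / geom.duration)
    return float(dz / geom.duration)


def rom_between_events(angles: np.ndarray, event_a: int, event_b: int) -> float:
    """Range (max - min) of an angle series on [event_a, event_b] inclusive."""
    if not (0 <= event_a <= event_b < len(angles)):
        raise VariableError(f"event window [{event_a}, {event_b}] outside series")
    window = np.asarray(angles[event_a:event_b + 1], dtype=float)
    if window.size == 0:
        raise VariableError("empty event window")
    return float(window.max() - window.min())


# (label, category, bone pattern, euler component, start event, end event);
# bone "{S}" expands to the stride side.
VARIABLE_SPECS = [
    ("Step length [cm]", "step", None, None, None, None),
    ("Step width [cm]", "step", None, None, None, None),
    ("Single support [%]", "support", None, None, None, None),
    ("Double support [%]", "support", None, None, None, None),
    ("Gait speed [cm/s]", "speed", None, None, None, None),
    ("Range of trunk tilt T2 to T5 [deg]", "kinematic", "thorax", "z", "T2", "T5"),
    ("Range of pelvic tilt T1 to T4 [deg]", "kinematic", "pelvis", "z", "T1", "T4"),
    ("Range of hip flexion-extension T1 to T4 [deg]", "kinematic", "thigh_{S}", "x", "T1", "T4"),
    ("Range of hip adduction-abduction T4 to T5 [deg]", "kinematic", "thigh_{S}", "z", "T4", "T5"),
    ("Range of knee flexion-extension T4 to T5 [deg]", "kinematic", "calf_{S}", "x", "T4", "T5"),
    ("Range of ankle dorsi-plantar flexion T4 to T5 [deg]", "kinematic", "foot_{S}", "x", "T4", "T5"),
    ("Range of ankle inversion-eversion T1 to T3 [deg]", "kinematic", "foot_{S}", "z", "T1", "T3"),
]

KINEMATIC_SPECS = [s for s in VARIABLE_SPECS if s[1] == "kinematic"]


@dataclass
class GaitVariableTable:
    """Per-stride variable rows plus per-side means and SDs."""

    strides: pd.DataFrame   # one row per valid stride
    summary: pd.DataFrame   # side x variable mean/sd/n

    def mean(self, variable: str, side: str) -> float:
        row = self.summary[(self.summary["variable"] == variable) & (self.summary["side"] == side)]
        return float(row["mean"].iloc[0])


DEFAULT_DENOISE_WINDOW_S = 0.15


def _denoise(values: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    """Peak-preserving Savitzky-Golay denoising (cubic local fits)."""
    n = int(round(window_s * rate))
    n += 1 - n % 2  # odd
    if n < 5 or len(values) <= n:
        return np.asarray(values, dtype=float)
    return savgol_filter(values, window_length=n, polyorder=3, mode="interp")


def _smoothed_angle(series: BonePoseSeries, bone: str, comp: str, window_s: float) -> np.ndarray:
    return _denoise(series.angle(bone, comp), series.rate, window_s)


def _smoothed_positions(series: BonePoseSeries, bone: str, window_s: float) -> np.ndarray:
    cols = [_denoise(series.position[bone][:, j], series.rate, window_s) for j in range(3)]
    return np.stack(cols, axis=1)


def compute_all(
    series: BonePoseSeries,
    events: GaitEventTable,
    window_s: float = DEFAULT_DENOISE_WINDOW_S,
) -> GaitVariableTable:
    """Compute all twelve variables for every valid stride, plus summaries.

    Invalid strides are skipped (logged via warnings), never imputed; with
    fewer than 23 valid strides on a side the summary carries a stability
    warning.
    """
    valid = events.frame[events.frame["valid"]]
    if len(valid) == 0:
        raise VariableError("no valid strides in the event table")

    angle_cache: Dict[tuple, np.ndarray] = {}

    def angle(bone, comp):
        if (bone, comp) not in angle_cache:
            angle_cache[(bone, comp)] = _smoothed_angle(series, bone, comp, window_s)
        return angle_cache[(bone, comp)]

    pos = {s: _smoothed_positions(series, f"foot_{s}", window_s) for s in ("R", "L")}

    rows = []
    for _, ev in valid.iterrows():
        side = ev["side"]
        other = "L" if side == "R" else "R"
        t = {k: int(ev[k]) for k in ("T1", "T2", "T3", "T4", "T5", "T6")}
        geom = StrideGeometry(
            ankle_ipsi_t1=pos[side][t["T1"]],
            ankle_contra_t1=pos[other][t["T1"]],
            ankle_ipsi_t6=pos[side][t["T6"]],
            duration=(t["T6"] - t["T1"]) / series.rate,
            environment=series.environment,
            belt_speed=series.belt_speed,
        )
        single, double = support_percentages(t["T1"], t["T2"], t["T4"], t["T5"], t["T6"])
        row = {
            "stride": int(ev["stride"]), "side": side,
            "Step length [cm]": step_length(geom),
            "Step width [cm]": step_width(geom),
            "Single support [%]": single,
            "Double support [%]": double,
            "Gait speed [cm/s]": gait_speed(geom),
        }
        for label, _, bone, comp, ea, eb in KINEMATIC_SPECS:
            series_angles = angle(bone.format(S=side), comp)
            row[label] = rom_between_events(series_angles, t[ea], t[eb])
        rows.append(row)
    strides = pd.DataFrame(rows)

    summary_rows = []
    for side in ("R", "L"):
        sub = strides[strides["side"] == side]
        if len(sub) == 0:
            continue
        if len(sub) < MIN_STABLE_STRIDES:
            warnings.warn(
                f"only {len(sub)} valid strides on side {side}; stride statistics "
                f"are considered stable from {MIN_STABLE_STRIDES}",
                stacklevel=2,
            )
        for label, category, *_ in VARIABLE_SPECS:
            vals = sub[label].to_numpy(dtype=float)
            summary_rows.append({
                "variable": label, "category": category, "side": side,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            })
    return GaitVariableTable(strides=strides, summary=pd.DataFrame(summary_rows))
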