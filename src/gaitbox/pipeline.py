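"""End-to-end analysis pipeline: capture -> calibration -> tracking ->
events -> variables (-> reliability), with file artefacts.

The pipeline is configuration-driven so a whole session can be processed
with one call (or one CLI invocation).  Every stage logs the numerical
parameters it used, making runs self-documenting.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from .calibration import BonePoseSeries, CalibrationResult, calibrate, track
from .events import (
    EventCurve,
    GaitEventTable,
    detect_events_imu,
    detect_events_opt,
    select_straight_sections,
)
from .session import CaptureSession, read_capture
from .skeleton import Anthropometrics, build_skeleton
from .variables import compute_all

__all__ = ["hip_flexion_curve", "ankle_ap_curve", "detect_events", "run_pipeline"]

log = logging.getLogger("gaitbox")


def hip_flexion_curve(series: BonePoseSeries, side: str) -> EventCurve:
    """Hip flexion-extension curve of one leg, degrees (flexion positive).

    The thigh's X Euler component measures flexion-extension; with the world
    X axis pointing to the subject's right, forward flexion of a downward
    segment is a negative X rotation, so the anatomical flexion curve is the
    negated component.
    """
    return EventCurve(-series.angle(f"thigh_{side}", "x"), series.rate,
                      kind="hip_flexion", side=side)


def ankle_ap_curve(series: BonePoseSeries, side: str) -> EventCurve:
    """Anteroposterior (Z) displacement curve of one ankle joint centre, cm."""
    return EventCurve(series.position[f"foot_{side}"][:, 2], series.rate,
                      kind="ankle_ap", side=side)


def detect_events(series: BonePoseSeries, modality: str,
                  sections=None) -> GaitEventTable:
    """Modality dispatch for event detection on a tracked series."""
    if modality == "imu":
        secs = select_straight_sections(series, manual=sections)
        return detect_events_imu(hip_flexion_curve(series, "R"),
                                 hip_flexion_curve(series, "L"), secs)
    return detect_events_opt(ankle_ap_curve(series, "R"), ankle_ap_curve(series, "L"))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run the full analysis described by ``config``; returns the artefacts.

    Config keys: ``capture`` (path) or ``session`` (in-memory
    :class:`CaptureSession`); ``modality``; ``height_cm`` (+ optional
    ``elbow_span_cm``, ``iliac_crest_width_cm``); ``frame0``; optional
    ``sections`` ([[a, b], ...] frames); ``belt_speed_cm_s`` for treadmill
    captures.  With ``out_dir`` set, calibration JSON, events CSV and
    variables CSV are written there.
    """
    artefacts = {}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as e:
            raise PipelineError(name, e) from e
        artefacts[name] = result
        return result

    def load():
        if "session" in config:
            return config["session"]
        return read_capture(config["capture"])

    session: CaptureSession = stage("load", load)
    modality = config.get("modality", session.modality)
    if modality != session.modality:
        raise PipelineError("load", ValueError(
            f"config modality {modality!r} != capture modality {session.modality!r}"))
    if session.environment == "treadmill" and session.belt_speed is None:
        belt = config.get("belt_speed_cm_s")
        if belt is None:
            raise PipelineError("load", ValueError(
                "treadmill capture needs belt_speed_cm_s in the config"))
        session.belt_speed = float(belt)

    anth = Anthropometrics(
        height=float(config["height_cm"]),
        elbow_span=config.get("elbow_span_cm"),
        iliac_crest_width=config.get("iliac_crest_width_cm"),
    )
    skeleton = stage("skeleton", lambda: build_skeleton(anth, mode="imu"))
    frame0 = int(config.get("frame0", 0))
    log.info("calibrating at frame0=%d (modality %s)", frame0, modality)
    calibration: CalibrationResult = stage(
        "calibrate", lambda: calibrate(session, skeleton, frame0=frame0))
    series = stage("track", lambda: track(session, calibration, skeleton))
    sections = config.get("sections")
    events = stage("events", lambda: detect_events(series, modality, sections))
    min_t1 = config.get("first_analysed_frame")
    if min_t1 is not None:
        events.frame.loc[events.frame["T1"] < int(min_t1), "valid"] = False
    variables = stage("variables", lambda: compute_all(series, events))

    reliability = None
    if "reliability_table" in config:
        from .reliability import TestRetestTable, reliability_report, summarize

        def rel():
            table = TestRetestTable.read_csv(config["reliability_table"])
            report = reliability_report(
                table, icc_model=config.get("icc_model", "2,1"))
            return report, summarize(report)

        reliability = stage("reliability", rel)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "calibration.json", "w") as fh:
            json.dump(calibration.to_dict(), fh, indent=1)
        events.to_csv(out / "events.csv")
        variables.strides.to_csv(out / "variables_strides.csv", index=False)
        variables.summary.to_csv(out / "variables_summary.csv", index=False)
        if reliability is not None:
            report, summary = reliability
            report.to_csv(out / "reliability.csv")
            with open(out / "reliability_summary.json", "w") as fh:
                json.dump({k: v for k, v in summary.items() if not isinstance(v, dict)},
                          fh, indent=1)
        log.info("artefacts written to %s", out)
    return artefacts
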