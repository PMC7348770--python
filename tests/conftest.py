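"""Shared fixtures: simulated captures run once per session."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from gaitbox.calibration import calibrate, track
from gaitbox.pipeline import detect_events
from gaitbox.simulate import GaitProfile, NoiseModel, simulate_session
from gaitbox.variables import compute_all


@dataclass
class PipelineRun:
    session: object
    traj: object
    calibration: object
    series: object
    events: object
    variables: object

    @property
    def truth(self):
        return self.traj.truth


def run_pipeline_on_sim(profile, noise, modality, n_strides, seed):
    session, traj = simulate_session(profile, noise, n_strides=n_strides,
                                     modality=modality, seed=seed)
    cal = calibrate(session, traj.skeleton, frame0=traj.truth.calibration_frame)
    series = track(session, cal, traj.skeleton)
    if modality == "imu":
        events = detect_events(series, "imu",
                               sections=[(traj.truth.steady_start_frame, series.n_frames)])
    else:
        events = detect_events(series, "optical")
        events.frame.loc[events.frame["T1"] < traj.truth.steady_start_frame, "valid"] = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variables = compute_all(series, events)
    return PipelineRun(session, traj, cal, series, events, variables)


def event_errors(truth_events, event_table):
    """Detected-minus-true frames for every truth stride, NaN when unmatched."""
    errs = []
    for _, tr in truth_events.iterrows():
        det = event_table.frame[
            (event_table.frame["side"] == tr["side"])
            & (np.abs(event_table.frame["T1"] - tr["T1"]) < 25)
            & event_table.frame["valid"]
        ]
        if len(det) == 0:
            errs.append(np.nan)
            continue
        d = det.iloc[0]
        errs.extend(d[k] - tr[k] for k in ("T1", "T2", "T3", "T4", "T5", "T6"))
    return np.asarray(errs, dtype=float)


@pytest.fixture(scope="session")
def imu_clean():
    """Random per-sensor headings, otherwise noise-free (closure checks)."""
    return run_pipeline_on_sim(GaitProfile(), NoiseModel.headings_only(), "imu", 6, seed=3)


@pytest.fixture(scope="session")
def imu_noisy():
    """Default noise, 27 strides (the reference protocol's 25 plus margin)."""
    return run_pipeline_on_sim(GaitProfile(), NoiseModel(), "imu", 27, seed=7)


@pytest.fixture(scope="session")
def opt_clean():
    return run_pipeline_on_sim(GaitProfile(), NoiseModel.none(), "optical", 6, seed=3)


@pytest.fixture(scope="session")
def opt_noisy():
    return run_pipeline_on_sim(GaitProfile(), NoiseModel(), "optical", 27, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)
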