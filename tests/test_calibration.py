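"""Heading correction, sensor-to-bone linking and tracking."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as R

from gaitbox.calibration import (
    CalibrationError,
    CalibrationPoseError,
    DEFAULT_ASSUMPTIONS,
    HeadingAssumption,
    bone_absolute,
    bone_relative,
    calibrate,
    correct_sensor,
    heading_alpha,
    heading_rotation,
    sensor_to_bone,
    track,
)
from gaitbox.rotations import random_rotation, yaw_rotation, to_zup
from gaitbox.session import CaptureFormatError
from gaitbox.simulate import GaitProfile, NoiseModel, simulate_session, _mount_matrix

from conftest import run_pipeline_on_sim


class TestHeadingAlpha:
    def test_worked_example_seven_degrees(self):
        # thigh sensor measured at 83 degrees where 90 is expected
        assumption = HeadingAssumption("thigh_R", "Y", 90.0)
        pelvis = _mount_matrix("Y", 0.0, 0.0)
        sensor = yaw_rotation(83.0 - 90.0) @ _mount_matrix("Y", 90.0, 0.0)
        assert np.isclose(heading_alpha(sensor, pelvis, assumption), 7.0, atol=1e-9)

    def test_zero_when_measured_equals_expected(self):
        assumption = HeadingAssumption("calf_L", "Y", -90.0)
        pelvis = _mount_matrix("Y", 0.0, 12.0)
        sensor = _mount_matrix("Y", -90.0, -25.0)
        assert np.isclose(heading_alpha(sensor, pelvis, assumption), 0.0, atol=1e-9)

    def test_recovers_injected_yaw_offset(self, rng):
        for _ in range(25):
            beta = rng.uniform(-179, 179)
            expected = float(rng.choice([0.0, 90.0, -90.0]))
            assumption = HeadingAssumption("dev", "Y" if rng.random() < 0.5 else "X", expected)
            pelvis = _mount_matrix("Y", 0.0, rng.uniform(-30, 30))
            sensor = yaw_rotation(-beta) @ _mount_matrix(
                assumption.axis, expected, rng.uniform(-30, 30))
            assert np.isclose(heading_alpha(sensor, pelvis, assumption), beta, atol=1e-8)

    def test_vertical_axis_is_pose_error(self):
        assumption = HeadingAssumption("foot_R", "Y", 0.0)
        # identity orientation points the sensor's Y axis straight up
        with pytest.raises(CalibrationPoseError):
            heading_alpha(np.eye(3), _mount_matrix("Y", 0.0, 0.0), assumption)


class TestCorrectionChain:
    def test_identity_correction(self, rng):
        m = random_rotation(rng)
        assert np.allclose(correct_sensor(m, np.eye(3)), m)

    def test_matrix_product_order(self, rng):
        a, b = random_rotation(rng), random_rotation(rng)
        assert np.allclose(correct_sensor(a, b), np.asarray(b) @ np.asarray(a))

    def test_single_axis_composition(self):
        got = correct_sensor(yaw_rotation(30.0), yaw_rotation(25.0))
        assert np.allclose(got, yaw_rotation(55.0), atol=1e-12)

    def test_sensor_to_bone_identity_cases(self, rng):
        m = random_rotation(rng)
        assert np.allclose(sensor_to_bone(m, m), np.eye(3), atol=1e-12)
        assert np.allclose(sensor_to_bone(np.eye(3), m), m)

    def test_closure_bone_absolute_at_instant_zero(self, rng):
        # applying the device-to-bone link back at instant 0 returns the
        # neutral bone orientation
        rb0, rs0 = random_rotation(rng), random_rotation(rng)
        rs0b = sensor_to_bone(rb0, rs0)
        assert np.allclose(bone_absolute(rs0, rs0b), rb0, atol=1e-9)

    def test_bone_absolute_perturbation(self, rng):
        rb0, rs0 = random_rotation(rng), random_rotation(rng)
        rs0b = sensor_to_bone(rb0, rs0)
        delta = random_rotation(rng)
        assert np.allclose(bone_absolute(delta @ rs0, rs0b), delta @ rb0, atol=1e-9)

    def test_bone_relative_recomposition(self, rng):
        parent, child = random_rotation(rng), random_rotation(rng)
        rel = bone_relative(parent, child)
        assert np.allclose(parent @ rel, child, atol=1e-12)
        assert np.allclose(bone_relative(np.eye(3), child), child)
        assert np.allclose(bone_relative(child, child), np.eye(3), atol=1e-12)


class TestCalibrateAndTrack:
    def test_calibration_frame_has_zero_angles(self, imu_clean):
        f0 = imu_clean.calibration.frame0
        for bone, ang in imu_clean.series.euler.items():
            assert np.allclose(ang[f0], 0.0, atol=1e-6), bone

    def test_magnetometer_free_tracking_matches_truth(self, imu_clean):
        # private random headings corrected via the mounting assumptions
        for bone, ang in imu_clean.series.euler.items():
            assert np.abs(ang - imu_clean.traj.eulers[bone]).max() < 1e-6

    def test_optical_tracking_matches_truth(self, opt_clean):
        for bone, ang in opt_clean.series.euler.items():
            assert np.abs(ang - opt_clean.traj.eulers[bone]).max() < 1e-6
        assert np.abs(
            opt_clean.series.position["foot_R"] - opt_clean.traj.positions["R"]
        ).max() < 1e-6

    def test_optical_alpha_zero(self, opt_clean):
        assert all(d.alpha == 0.0 for d in opt_clean.calibration.devices.values())

    def test_heading_invariance_under_common_yaw(self):
        session, traj = simulate_session(GaitProfile(), NoiseModel.headings_only(),
                                         n_strides=3, modality="imu", seed=2)
        yawed = copy.deepcopy(session)
        Yz = to_zup(yaw_rotation(37.0))
        for stream in yawed.devices.values():
            mats = R.from_quat(stream.quaternions[:, [1, 2, 3, 0]]).as_matrix()
            mats = np.einsum("ij,njk->nik", Yz, mats)
            stream.quaternions = R.from_matrix(mats).as_quat()[:, [3, 0, 1, 2]]
        results = []
        for s in (session, yawed):
            cal = calibrate(s, traj.skeleton, frame0=traj.truth.calibration_frame)
            results.append(track(s, cal, traj.skeleton))
        for bone in results[0].euler:
            assert np.allclose(results[0].euler[bone], results[1].euler[bone], atol=1e-9)

    def test_sensor_to_bone_time_invariant(self, imu_clean):
        # re-deriving the device-to-bone link at later frames of a rigidly
        # attached noise-free capture returns the same matrix
        from gaitbox.calibration import _device_rotations, sensor_to_bone
        session, traj, cal = imu_clean.session, imu_clean.traj, imu_clean.calibration
        name = "thigh_R"
        mats = _device_rotations(session, name)
        dev = cal.devices[name]
        for frame in (cal.frame0, cal.frame0 + 10):
            # bone truth at that frame (relative chain composed to absolute)
            rb = traj.absolute[name][frame]
            rs = dev.RGs0G @ mats[frame]
            assert np.allclose(sensor_to_bone(rb, rs), dev.Rs0b, atol=1e-9)

    def test_missing_device_errors_with_name(self, imu_clean):
        session = copy.deepcopy(imu_clean.session)
        del session.devices["calf_L"]
        with pytest.raises(CaptureFormatError, match="calf_L"):
            calibrate(session, imu_clean.traj.skeleton, frame0=0,
                      expected_devices=list(imu_clean.session.devices))

    def test_modality_mismatch_rejected(self, imu_clean, opt_clean):
        with pytest.raises(CalibrationError):
            track(opt_clean.session, imu_clean.calibration, imu_clean.traj.skeleton)

    def test_serialisation_round_trip(self, imu_clean):
        from gaitbox.calibration import CalibrationResult
        d = imu_clean.calibration.to_dict()
        back = CalibrationResult.from_dict(d)
        for name, dev in imu_clean.calibration.devices.items():
            assert np.allclose(dev.Rs0b, back.devices[name].Rs0b)
            assert np.isclose(dev.alpha, back.devices[name].alpha)

    def test_heading_rotation_is_heading_matrix(self):
        assert np.allclose(heading_rotation(7.0), yaw_rotation(7.0))

    def test_drift_grows_tracking_error(self):
        errs = {}
        for rate in (0.0, 0.5):
            nm = NoiseModel(heading_offsets=True, heading_drift_deg_s=rate,
                            orientation_noise_deg=0.0, soft_tissue_deg=0.0,
                            marker_noise_mm=0.0)
            run = run_pipeline_on_sim(GaitProfile(), nm, "imu", 30, seed=9)
            e = np.abs(run.series.euler["thigh_R"][:, 0]
                       - run.traj.eulers["thigh_R"][:, 0])
            n = len(e)
            errs[rate] = (e[: n // 3].mean(), e[2 * n // 3:].mean())
        assert errs[0.0][1] < 1e-9
        early, late = errs[0.5]
        assert late > 3 * early > 0  # error grows roughly linearly with time
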