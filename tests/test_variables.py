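"""Spatio-temporal and kinematic gait variables."""

import numpy as np
import pytest

from gaitbox.variables import (
    StrideGeometry,
    VariableError,
    compute_all,
    gait_speed,
    rom_between_events,
    step_length,
    step_width,
    support_percentages,
)

from conftest import run_pipeline_on_sim
from gaitbox.simulate import GaitProfile, NoiseModel


def geom(ipsi_t1, contra_t1, ipsi_t6, duration=1.0, **kw):
    return StrideGeometry(np.asarray(ipsi_t1, float),
                          None if contra_t1 is None else np.asarray(contra_t1, float),
                          np.asarray(ipsi_t6, float), duration, **kw)


class TestStepMeasures:
    def test_coincident_ankles_zero(self):
        g = geom([0, 0, 0], [0, 0, 0], [0, 0, 100])
        assert step_length(g) == 0.0 and step_width(g) == 0.0

    def test_components(self):
        g = geom([3, 0, 40], [-9, 0, -19], [0, 0, 100])
        assert step_length(g) == 59.0
        assert step_width(g) == 12.0

    def test_translation_invariance(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        off = rng.normal(size=3) * 50
        g1 = geom(a, b, a)
        g2 = geom(a + off, b + off, a + off)
        assert np.isclose(step_length(g1), step_length(g2))
        assert np.isclose(step_width(g1), step_width(g2))

    def test_missing_contralateral(self):
        with pytest.raises(VariableError, match="contralateral"):
            step_length(geom([0, 0, 0], None, [0, 0, 1]))


class TestSupports:
    def test_formulas(self):
        single, double = support_percentages(0, 6, 30, 36, 60)
        assert np.isclose(single, 100 * 24 / 60)
        assert np.isclose(double, 100 * 12 / 60)

    def test_no_double_support(self):
        _, double = support_percentages(0, 0, 30, 30, 60)
        assert double == 0.0

    def test_time_dilation_invariance(self):
        a = support_percentages(0, 6, 30, 36, 60)
        b = support_percentages(0, 12, 60, 72, 120)
        assert np.allclose(a, b)


class TestGaitSpeed:
    def test_stationary_overground_zero(self):
        g = geom([0, 0, 5], [0, 0, 0], [0, 0, 5])
        assert gait_speed(g) == 0.0

    def test_treadmill_zero_displacement_is_belt_speed(self):
        g = geom([0, 0, 5], None, [0, 0, 5], duration=0.8,
                 environment="treadmill", belt_speed=114.2)
        assert np.isclose(gait_speed(g), 114.2)

    def test_treadmill_without_belt_speed_errors(self):
        g = geom([0, 0, 0], None, [0, 0, 0], environment="treadmill")
        with pytest.raises(VariableError, match="belt"):
            gait_speed(g)

    def test_overground_displacement(self):
        g = geom([0, 0, 10], None, [0, 0, 128], duration=1.0)
        assert np.isclose(gait_speed(g), 118.0)


class TestRom:
    def test_constant_zero(self):
        assert rom_between_events(np.full(50, 4.2), 3, 40) == 0.0

    def test_monotone_ramp(self):
        assert np.isclose(rom_between_events(np.linspace(-5, 30, 71), 0, 70), 35.0)

    def test_offset_invariance(self, rng):
        v = rng.normal(size=80)
        assert np.isclose(rom_between_events(v, 5, 60),
                          rom_between_events(v + 13.7, 5, 60))

    def test_bad_window(self):
        with pytest.raises(VariableError):
            rom_between_events(np.zeros(10), 5, 20)


class TestComputeAll:
    def test_optical_recovery_within_tolerances(self, opt_noisy):
        # treadmill configuration, default noise, 27 strides
        tol = {
            "Step length [cm]": 1.0, "Step width [cm]": 1.0,
            "Single support [%]": 1.0, "Double support [%]": 1.0,
            "Gait speed [cm/s]": 2.0,
        }
        for label, truth in opt_noisy.truth.variables.items():
            est = 0.5 * (opt_noisy.variables.mean(label, "R")
                         + opt_noisy.variables.mean(label, "L"))
            t = tol.get(label, 0.5)   # kinematic ranges: half a degree
            assert abs(est - truth) <= t, f"{label}: {est} vs {truth}"

    def test_imu_recovery_within_frame_resolution_bounds(self, imu_noisy):
        # 60 Hz events quantise steep curve segments; documented looser
        # bounds (cf. the wider reliability margins of the IMU configuration)
        tol = {
            "Step length [cm]": 3.5, "Step width [cm]": 1.0,
            "Single support [%]": 2.5, "Double support [%]": 4.5,
            "Gait speed [cm/s]": 2.0,
            "Range of hip adduction-abduction T4 to T5 [deg]": 2.5,
            "Range of knee flexion-extension T4 to T5 [deg]": 7.0,
            "Range of ankle dorsi-plantar flexion T4 to T5 [deg]": 5.5,
        }
        for label, truth in imu_noisy.truth.variables.items():
            est = 0.5 * (imu_noisy.variables.mean(label, "R")
                         + imu_noisy.variables.mean(label, "L"))
            t = tol.get(label, 1.0)
            assert abs(est - truth) <= t, f"{label}: {est} vs {truth}"

    def test_support_identity_sums_to_100(self, imu_noisy, opt_noisy):
        for run in (imu_noisy, opt_noisy):
            s = run.variables.summary
            singles = {side: run.variables.mean("Single support [%]", side)
                       for side in ("R", "L")}
            doubles = np.mean([run.variables.mean("Double support [%]", s) for s in ("R", "L")])
            total = singles["R"] + singles["L"] + doubles
            assert abs(total - 100.0) <= 0.5

    def test_mirrored_gait_swaps_columns(self, opt_clean):
        # relabel the tracked sides and recompute: R and L columns swap
        import copy
        from gaitbox.pipeline import detect_events

        series = copy.deepcopy(opt_clean.series)
        for d in (series.euler, series.absolute, series.relative, series.position):
            for base in ("thigh", "calf", "foot"):
                d[f"{base}_R"], d[f"{base}_L"] = d[f"{base}_L"], d[f"{base}_R"]
        ev = detect_events(series, "optical")
        ev.frame.loc[ev.frame["T1"] < opt_clean.truth.steady_start_frame, "valid"] = False
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gv = compute_all(series, ev)
        for label in opt_clean.truth.variables:
            for side, other in (("R", "L"), ("L", "R")):
                assert np.isclose(gv.mean(label, side),
                                  opt_clean.variables.mean(label, other), atol=1e-9)

    def test_stride_averaging_reduces_variance(self):
        # the SD of the 25-stride mean across captures is ~ stride SD / 5
        label = "Step length [cm]"
        means, stride_sds = [], []
        for seed in range(6):
            run = run_pipeline_on_sim(GaitProfile(), NoiseModel(), "optical", 25, seed=100 + seed)
            sub = run.variables.strides
            vals = sub[sub["side"] == "R"][label].to_numpy()
            means.append(vals.mean())
            stride_sds.append(vals.std(ddof=1))
        sd_of_means = np.std(means, ddof=1)
        predicted = np.mean(stride_sds) / np.sqrt(25)
        assert sd_of_means < 1.5 * np.mean(stride_sds)  # far below per-stride spread
        assert sd_of_means < 4 * predicted               # loose: 6 captures only

    def test_no_valid_strides_errors(self, opt_clean):
        import copy
        ev = copy.deepcopy(opt_clean.events)
        ev.frame["valid"] = False
        with pytest.raises(VariableError):
            compute_all(opt_clean.series, ev)

    def test_few_strides_warns(self, opt_clean):
        import copy
        ev = copy.deepcopy(opt_clean.events)
        keep = ev.frame.index[:4]
        ev.frame.loc[~ev.frame.index.isin(keep), "valid"] = False
        with pytest.warns(UserWarning, match="strides"):
            compute_all(opt_clean.series, ev)
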