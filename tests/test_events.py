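"""Curve smoothing, extremum search and gait-event detection."""

import numpy as np
import pytest

from gaitbox.events import (
    EventCurve,
    EventDetectionError,
    FlatCurveError,
    StraightSection,
    detect_events_imu,
    detect_events_opt,
    find_extrema,
    normalize_stride,
    select_straight_sections,
    smooth,
)
from gaitbox.simulate import GaitProfile, NoiseModel

from conftest import event_errors, run_pipeline_on_sim


def curve(values, rate=60.0, side="R"):
    return EventCurve(np.asarray(values, dtype=float), rate, side=side)


class TestSmooth:
    def test_constant_curve_unchanged(self):
        c = curve(np.full(100, 3.7))
        for shape in ("hann", "flat"):
            assert np.allclose(smooth(c, shape=shape).values, 3.7)

    def test_single_sample_window_is_identity(self):
        c = curve(np.random.default_rng(0).normal(size=50))
        out = smooth(c, window_s=1.0 / 60.0)
        assert np.array_equal(out.values, c.values)

    def test_preserves_length(self):
        c = curve(np.sin(np.linspace(0, 20, 300)))
        assert len(smooth(c).values) == 300

    def test_reduces_noise_on_sinusoid(self, rng):
        t = np.arange(600) / 60.0
        clean = 20 * np.sin(2 * np.pi * 1.0 * t)
        noisy = clean + rng.normal(0, 2.0, size=len(t))
        out = smooth(curve(noisy)).values
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((out - clean) ** 2))
        assert rms_after < 0.6 * rms_before

    def test_too_short_curve_errors(self):
        with pytest.raises(EventDetectionError, match="shorter"):
            smooth(curve(np.zeros(5)), window_s=0.2)

    def test_unknown_shape_rejected(self):
        with pytest.raises(EventDetectionError):
            smooth(curve(np.zeros(100)), shape="boxcar")


def brute_force_extrema(x):
    maxima = [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    minima = [i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]
    return maxima, minima


class TestFindExtrema:
    def test_sine_wave_counts_and_phases(self):
        t = np.arange(600) / 60.0          # 10 s at 60 Hz
        c = curve(10 * np.sin(2 * np.pi * 1.0 * t))
        maxima, minima = find_extrema(c, min_separation_s=0.4)
        assert len(maxima) == 10 and len(minima) == 10
        # analytic maxima at t = 0.25 + k
        expected = (0.25 + np.arange(10)) * 60
        assert np.all(np.abs(maxima - expected) <= 1)

    def test_monotone_ramp_is_empty(self):
        maxima, minima = find_extrema(curve(np.linspace(0, 5, 200)), 0.4)
        assert len(maxima) == 0 and len(minima) == 0

    def test_matches_brute_force_after_smoothing(self, rng):
        t = np.arange(900) / 60.0
        raw = 15 * np.sin(2 * np.pi * 0.8 * t) + 4 * np.sin(2 * np.pi * 1.6 * t + 1.0)
        sm = smooth(curve(raw + rng.normal(0, 0.3, len(t))))
        maxima, minima = find_extrema(sm, min_separation_s=0.25)
        bm, bn = brute_force_extrema(sm.values)
        # every reported extremum is a genuine local extremum of the curve
        assert set(maxima) <= set(bm) and set(minima) <= set(bn)
        # and the big ones are all found
        big = [i for i in bm if sm.values[i] > 10]
        assert set(big) <= set(maxima)

    def test_alternation(self, rng):
        t = np.arange(1200) / 60.0
        x = np.sin(2 * np.pi * 0.9 * t) + 0.4 * np.sin(2 * np.pi * 2.3 * t)
        maxima, minima = find_extrema(curve(x), 0.3)
        merged = sorted([(i, 1) for i in maxima] + [(i, -1) for i in minima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_double_peak_suppressed(self):
        # two maxima 0.2 s apart; the larger must win
        t = np.arange(300) / 60.0
        x = np.exp(-((t - 2.0) ** 2) / 0.01) + 0.8 * np.exp(-((t - 2.2) ** 2) / 0.01)
        maxima, _ = find_extrema(curve(x), min_separation_s=0.4)
        assert len(maxima) == 1 and abs(maxima[0] - 120) <= 1


class TestStraightSections:
    def test_manual_full_range(self, imu_clean):
        secs = select_straight_sections(imu_clean.series, manual=[(0, 10_000)])
        assert len(secs) == 1 and secs[0].start == 0

    def test_overlapping_manual_ranges_rejected(self, imu_clean):
        with pytest.raises(EventDetectionError, match="overlap"):
            select_straight_sections(imu_clean.series, manual=[(0, 100), (50, 200)])

    def test_treadmill_is_single_section(self, opt_clean):
        secs = select_straight_sections(opt_clean.series, manual=None)
        assert secs == [StraightSection(0, opt_clean.series.n_frames)]

    def test_empty_manual_list_is_full_session(self, imu_clean):
        secs = select_straight_sections(imu_clean.series, manual=[])
        assert secs == [StraightSection(0, imu_clean.series.n_frames)]

    def test_auto_sections_exclude_turn(self):
        run = run_pipeline_on_sim(GaitProfile(turn_after_strides=5),
                                  NoiseModel.headings_only(), "imu", 10, seed=5)
        secs = select_straight_sections(run.series, manual=None)
        assert len(secs) == 2
        turn = run.truth.turn_interval
        assert secs[0].stop <= turn[0] + run.series.rate  # section ends near turn start
        assert secs[1].start >= turn[0]


class TestDetectEvents:
    def test_flat_curves_error(self):
        flat = curve(np.zeros(600))
        with pytest.raises(FlatCurveError):
            detect_events_imu(flat, curve(np.zeros(600), side="L"))

    def test_imu_noise_free_events_within_1_5_frames(self, imu_clean):
        errs = event_errors(imu_clean.truth.events, imu_clean.events)
        assert not np.any(np.isnan(errs))
        assert np.abs(errs).max() <= 1.5

    def test_opt_noise_free_events_within_1_5_frames(self, opt_clean):
        errs = event_errors(opt_clean.truth.events, opt_clean.events)
        assert not np.any(np.isnan(errs))
        assert np.abs(errs).max() <= 1.5

    def test_noisy_events_within_2_frames_95pct(self, imu_noisy, opt_noisy):
        for run in (imu_noisy, opt_noisy):
            errs = event_errors(run.truth.events, run.events)
            found = errs[~np.isnan(errs)]
            assert len(found) >= 0.95 * len(errs)
            assert np.mean(np.abs(found) <= 2.0) >= 0.95

    def test_event_ordering_invariant(self, imu_noisy, opt_noisy):
        for run in (imu_noisy, opt_noisy):
            v = run.events.frame[run.events.frame["valid"]]
            assert ((v["T1"] < v["T2"]) & (v["T2"] <= v["T3"]) & (v["T3"] < v["T4"])
                    & (v["T4"] < v["T5"]) & (v["T5"] < v["T6"])).all()

    def test_left_right_swap_symmetry(self, imu_clean):
        from gaitbox.pipeline import hip_flexion_curve
        r = hip_flexion_curve(imu_clean.series, "R")
        l = hip_flexion_curve(imu_clean.series, "L")
        a = detect_events_imu(r, l).frame
        b = detect_events_imu(l, r).frame
        swapped = b.copy()
        swapped["side"] = swapped["side"].map({"R": "L", "L": "R"})
        for side in ("R", "L"):
            cols = ["T1", "T2", "T3", "T4", "T5", "T6", "valid"]
            x = a[a["side"] == side].sort_values("T1")[cols].reset_index(drop=True)
            y = swapped[swapped["side"] == side].sort_values("T1")[cols].reset_index(drop=True)
            assert x.equals(y)

    def test_time_shift_equivariance(self, imu_clean):
        from gaitbox.pipeline import hip_flexion_curve
        k = 30
        r = hip_flexion_curve(imu_clean.series, "R")
        l = hip_flexion_curve(imu_clean.series, "L")
        shifted_r = EventCurve(r.values[k:], r.rate, side="R")
        shifted_l = EventCurve(l.values[k:], l.rate, side="L")
        a = detect_events_imu(r, l).frame
        b = detect_events_imu(shifted_r, shifted_l).frame
        cols = ["T1", "T2", "T3", "T4", "T5", "T6"]
        a_valid = a[a["valid"] & (a[cols].min(axis=1) > k + 60)]
        for _, row in a_valid.iterrows():
            match = b[(b["side"] == row["side"]) & (b["T1"] == row["T1"] - k) & b["valid"]]
            assert len(match) == 1
            assert all(match.iloc[0][c] == row[c] - k for c in cols)

    def test_opt_swapped_curves_swap_sides(self, opt_clean):
        from gaitbox.pipeline import ankle_ap_curve
        r = ankle_ap_curve(opt_clean.series, "R")
        l = ankle_ap_curve(opt_clean.series, "L")
        a = detect_events_opt(r, l).frame
        b = detect_events_opt(l, r).frame
        ra = a[a["side"] == "R"].sort_values("T1")["T1"].tolist()
        lb = b[b["side"] == "L"].sort_values("T1")["T1"].tolist()
        assert ra == lb


class TestNormalizeStride:
    def test_linear_ramp(self):
        v = np.arange(100, dtype=float)
        out = normalize_stride(v, 10, 60)
        assert len(out) == 101
        assert np.allclose(out, np.linspace(10, 60, 101))

    def test_endpoints_preserved(self, rng):
        v = rng.normal(size=200)
        out = normalize_stride(v, 17, 133)
        assert out[0] == v[17] and out[-1] == v[133]

    def test_sinusoid_peak_phase(self):
        rate = 60.0
        t = np.arange(120)
        v = np.sin(2 * np.pi * (t - 10) / 100)   # one cycle over frames 10..110
        out = normalize_stride(v, 10, 110)
        # analytic maximum at 25 % of the cycle
        assert abs(np.argmax(out) - 25) <= 1

    def test_too_short_stride_rejected(self):
        with pytest.raises(EventDetectionError):
            normalize_stride(np.zeros(10), 4, 5)
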