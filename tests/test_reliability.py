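"""ICC / SEM / MDC statistics and their recovery from simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from gaitbox.reliability import (
    ReliabilityError,
    UndefinedICCError,
    icc,
    mdc95,
    mdc_group,
    mdces95,
    pooled_sd,
    reliability_report,
    round_half_up,
    sem,
    summarize,
)
from gaitbox.simulate import simulate_test_retest


class TestPooledSd:
    def test_equal_inputs(self):
        assert pooled_sd(0.9, 0.9) == pytest.approx(0.9)
        assert pooled_sd(0.9, 0.9, "mean") == pytest.approx(0.9)

    def test_zero(self):
        assert pooled_sd(0.0, 0.0) == 0.0

    def test_rms_hand_value(self):
        assert pooled_sd(4.6, 4.8) == pytest.approx(4.701, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ReliabilityError):
            pooled_sd(-0.1, 1.0)


class TestICC:
    def test_perfect_agreement(self, rng):
        x = rng.normal(10, 3, size=30)
        assert icc(x, x.copy()) == 1.0

    def test_zero_between_subject_variance_undefined(self):
        x = np.full(10, 5.0)
        with pytest.raises(UndefinedICCError):
            icc(x, x + 0.0)

    def test_small_table_matches_anova_oracle(self):
        # brute-force variance components on a 4-subject table
        test = np.array([9.0, 10.0, 12.0, 15.0])
        retest = np.array([10.0, 11.0, 11.0, 14.0])
        data = np.stack([test, retest], axis=1)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((data - data.mean(axis=1, keepdims=True)
                 - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(test, retest) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(50, 8, size=25)
        y = x + rng.normal(0, 3, size=25) + 0.5
        df = pd.DataFrame({
            "subject": np.tile(np.arange(25), 2),
            "rater": np.repeat(["a", "b"], 25),
            "value": np.concatenate([x, y]),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="value")
        # ICC(A,1): two-way random absolute agreement; ICC(C,1): consistency
        icc2 = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        icc3 = float(res.loc[res["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc(x, y, model="2,1") == pytest.approx(icc2, abs=1e-9)
        assert icc(x, y, model="3,1") == pytest.approx(icc3, abs=1e-9)

    def test_generative_recovery(self):
        # error/true variance ratio 0.1 -> ICC(2,1) ~ 1/1.1 = 0.909
        rng = np.random.default_rng(42)
        n = 500
        true = rng.normal(0, 1.0, n)
        x = true + rng.normal(0, np.sqrt(0.1), n)
        y = true + rng.normal(0, np.sqrt(0.1), n)
        assert icc(x, y) == pytest.approx(1 / 1.1, abs=0.02)


class TestMDC:
    def test_printed_reference_row(self):
        # single-support right side of the optical configuration
        assert round_half_up(mdc95(0.9, 0.9, 0.89), 1) == 0.8

    def test_perfect_icc_gives_zero(self):
        assert mdc95(2.4, 3.1, 1.0) == 0.0

    def test_hand_value_unrounded_inputs(self):
        # 1.96 sqrt(2) * pooled(4.6, 4.8) * sqrt(0.07) = 3.45
        assert mdc95(4.6, 4.8, 0.93) == pytest.approx(3.448, abs=2e-3)

    def test_monotone_in_one_minus_icc(self):
        vals = [mdc95(2.0, 2.0, i) for i in (0.99, 0.9, 0.8, 0.5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_icc_above_one_rejected(self):
        with pytest.raises(ReliabilityError):
            mdc95(1.0, 1.0, 1.2)

    def test_scale_equivariance(self, rng):
        sd1, sd2, i = 3.1, 2.7, 0.88
        c = 7.3
        assert mdc95(c * sd1, c * sd2, i) == pytest.approx(c * mdc95(sd1, sd2, i))
        assert sem(c * sd1, c * sd2, i) == pytest.approx(c * sem(sd1, sd2, i))
        assert mdces95(mdc95(c * sd1, c * sd2, i), c * sd1) == pytest.approx(
            mdces95(mdc95(sd1, sd2, i), sd1))

    def test_mdces_examples(self):
        assert mdces95(0.0, 4.6) == 0.0
        assert mdces95(4.6, 4.6) == 1.0
        assert mdces95(3.45, 4.6) == pytest.approx(0.75)
        with pytest.raises(ReliabilityError):
            mdces95(1.0, 0.0)

    def test_group_mdc(self):
        assert mdc_group(4.0, 1) == 4.0
        assert mdc_group(4.0, 4) == 2.0
        assert mdc_group(5.0, 25) == 1.0
        vals = [mdc_group(4.0, n) for n in (1, 2, 5, 10, 33)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ReliabilityError):
            mdc_group(4.0, 0)


class TestReportAndSummary:
    def test_degenerate_cohort(self):
        table = simulate_test_retest(30, between_subject_sd=4.0,
                                     within_subject_sd=0.0, seed=1,
                                     variables=["Step length [cm]"])
        rep = reliability_report(table)
        assert (rep.frame["icc"] == 1.0).all()
        assert (rep.frame["mdc95"] == 0.0).all()

    def test_sem_recovery(self):
        table = simulate_test_retest(200, between_subject_sd=4.5,
                                     within_subject_sd=1.2, seed=11)
        rep = reliability_report(table)
        assert rep.frame["sem"].mean() == pytest.approx(1.2, rel=0.10)

    def test_mdc_scale_with_reference_like_cohort(self):
        # 33 subjects with SD ratios like the step-length reference rows
        table = simulate_test_retest(33, between_subject_sd=4.6,
                                     within_subject_sd=1.2, seed=5,
                                     variables=["Step length [cm]"])
        rep = reliability_report(table)
        assert 2.0 <= rep.frame["mdc95"].mean() <= 5.0

    def test_single_variable_summary_is_itself(self):
        df = pd.DataFrame([{"variable": "v", "side": "R", "category": "step",
                            "icc": 0.9, "mdc95": 3.0, "mdces95": 0.7}])
        s = summarize(df)
        assert s["mdc95_step"] == 3.0
        assert s["mean_icc"] == 0.9
        assert s["mdc95_side_averaged"]["v"] == 3.0

    def test_side_averaged_mdc(self):
        df = pd.DataFrame([
            {"variable": "v", "side": "R", "category": "step", "icc": 0.9, "mdc95": 3.0},
            {"variable": "v", "side": "L", "category": "step", "icc": 0.9, "mdc95": 5.0},
        ])
        assert summarize(df)["mdc95_side_averaged"]["v"] == 4.0

    def test_invalid_sds_rejected(self):
        from gaitbox.simulate import SimulationError
        with pytest.raises(SimulationError):
            simulate_test_retest(10, between_subject_sd=-1.0, within_subject_sd=0.5)

    def test_determinism_under_seed(self):
        a = simulate_test_retest(20, 4.0, 1.0, seed=3).frame
        b = simulate_test_retest(20, 4.0, 1.0, seed=3).frame
        assert a.equals(b)
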