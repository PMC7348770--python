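"""Test-retest reproducibility statistics: ICC, SEM, MDC95.

Given per-subject test and retest values of each gait variable (each value
already a 25-stride average), reproducibility is summarised per variable as

* ``ICC``: intraclass correlation, two-way random effects, absolute
  agreement, single measurement — ICC(2,1) — the standard model for
  same-rater test-retest designs; ICC(3,1) is available behind a flag;
* ``SEM = SD_pooled * sqrt(1 - ICC)`` with ``SD_pooled`` the RMS average of
  the test and retest standard deviations (an arithmetic-mean pooling is
  available; the two coincide for equal SDs);
* ``MDC95 = 1.96 * sqrt(2) * SEM``: the smallest within-subject change not
  attributable to measurement error at 95 % confidence;
* ``MDCes95 = MDC95 / SD_test``: the effect-size form (number of baseline
  standard deviations the design can detect);
* ``MDC95_group = MDC95 / sqrt(n)``: the group-level threshold for a sample
  of n subjects.

Internally full precision is kept; display rounding is half-up to the
conventional printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "load_reference_reliability",
    "pooled_sd",
    "icc",
    "sem",
    "mdc95",
    "mdces95",
    "mdc_group",
    "TestRetestTable",
    "ReliabilityReport",
    "reliability_report",
    "summarize",
    "round_half_up",
]


class ReliabilityError(ValueError):
    pass


class UndefinedICCError(ReliabilityError):
    """No between-subject variance: the ICC is not identifiable."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pooled_sd(sd_test: float, sd_retest: float, method: str = "rms") -> float:
    """Pooled average of the test and retest standard deviations.

    ``method="rms"`` (default) pools variances: sqrt((s1^2 + s2^2)/2);
    ``method="mean"`` is the arithmetic mean.  Equal SDs give the same
    result under both readings.
    """
    if sd_test < 0 or sd_retest < 0:
        raise ReliabilityError("standard deviations must be non-negative")
    if method == "rms":
        return math.sqrt((sd_test**2 + sd_retest**2) / 2.0)
    if method == "mean":
        return (sd_test + sd_retest) / 2.0
    raise ReliabilityError(f"unknown pooling method {method!r}")


def icc(test: np.ndarray, retest: np.ndarray, model: str = "2,1") -> float:
    """Intraclass correlation of paired test/retest values.

    ``model="2,1"`` (default): two-way random effects, absolute agreement,
    single measurement.  ``model="3,1"``: two-way mixed, consistency.
    Computed from the two-way ANOVA mean squares; the result is clipped to
    [-1, 1].  Zero between-subject variance raises
    :class:`UndefinedICCError`.
    """
    x = np.asarray(test, dtype=float)
    y = np.asarray(retest, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ReliabilityError("test and retest must be equal-length vectors")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 2:
        raise ReliabilityError("ICC needs at least 2 complete subject pairs")
    k = 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    # retest == test leaves only catastrophic-cancellation residue here;
    # snap it to zero so perfect agreement yields ICC = 1 exactly
    if ss_err < 1e-12 * max(ss_total, 1.0):
        ss_err = 0.0
    if ss_cols < 1e-12 * max(ss_total, 1.0):
        ss_cols = 0.0
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or np.isclose(msr, 0.0):
        raise UndefinedICCError("zero between-subject variance; ICC undefined")
    if model == "2,1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "3,1":
        denom = msr + (k - 1) * mse
    else:
        raise ReliabilityError(f"unknown ICC model {model!r}")
    if denom == 0:
        raise UndefinedICCError("degenerate ANOVA decomposition; ICC undefined")
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def sem(sd_test: float, sd_retest: float, icc_value: float, pooling: str = "rms") -> float:
    """Standard error of measurement: SD_pooled * sqrt(1 - ICC)."""
    if icc_value > 1.0:
        raise ReliabilityError("ICC cannot exceed 1")
    return pooled_sd(sd_test, sd_retest, pooling) * math.sqrt(max(0.0, 1.0 - icc_value))


def mdc95(sd_test: float, sd_retest: float, icc_value: float, pooling: str = "rms") -> float:
    """Minimal detectable change at 95 % confidence: 1.96 sqrt(2) SEM."""
    return 1.96 * math.sqrt(2.0) * sem(sd_test, sd_retest, icc_value, pooling)


def mdces95(mdc95_value: float, sd_test: float) -> float:
    """Effect-size form of the MDC95: MDC95 / SD_test (dimensionless)."""
    if sd_test <= 0:
        raise ReliabilityError("MDCes95 undefined for non-positive test SD")
    return float(mdc95_value) / float(sd_test)


def mdc_group(mdc95_value: float, n: int) -> float:
    """Group-level MDC for n subjects: MDC95 / sqrt(n)."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ReliabilityError("group size must be an integer >= 1")
    return float(mdc95_value) / math.sqrt(n)


@dataclass
class TestRetestTable:
    """Long-format test/retest values: subject, variable, side, session, value."""

    frame: pd.DataFrame

    REQUIRED = ("subject", "variable", "side", "session", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ReliabilityError(f"missing column(s): {', '.join(missing)}")
        bad = set(self.frame["session"].unique()) - {"test", "retest"}
        if bad:
            raise ReliabilityError(f"session must be 'test' or 'retest', got {bad}")

    def pairs(self, variable: str, side: str):
        """(test, retest) aligned arrays for one variable/side."""
        sub = self.frame[(self.frame["variable"] == variable) & (self.frame["side"] == side)]
        wide = sub.pivot_table(index="subject", columns="session", values="value")
        if "test" not in wide or "retest" not in wide:
            raise ReliabilityError(f"incomplete sessions for {variable!r}/{side}")
        wide = wide.dropna()
        if len(wide) < 2:
            raise ReliabilityError(f"fewer than 2 complete pairs for {variable!r}/{side}")
        return wide["test"].to_numpy(), wide["retest"].to_numpy()

    @classmethod
    def read_csv(cls, path) -> "TestRetestTable":
        return cls(pd.read_csv(path))


@dataclass
class ReliabilityReport:
    """Per-variable reproducibility rows (Table-style layout)."""

    frame: pd.DataFrame  # variable, side, category, test_mean, test_sd, retest_mean,
    #                      retest_sd, dif_mean, dif_sd, icc, sem, mdc95, mdces95

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def reliability_report(
    table: TestRetestTable,
    icc_model: str = "2,1",
    pooling: str = "rms",
    categories: Optional[dict] = None,
) -> ReliabilityReport:
    """Full reproducibility report over every variable/side in the table."""
    rows = []
    combos = table.frame[["variable", "side"]].drop_duplicates().itertuples(index=False)
    for variable, side in combos:
        t, r = table.pairs(variable, side)
        icc_v = icc(t, r, model=icc_model)
        sd_t, sd_r = float(np.std(t, ddof=1)), float(np.std(r, ddof=1))
        m = mdc95(sd_t, sd_r, icc_v, pooling)
        rows.append({
            "variable": variable, "side": side,
            "category": (categories or {}).get(variable, _category_of(variable)),
            "test_mean": float(np.mean(t)), "test_sd": sd_t,
            "retest_mean": float(np.mean(r)), "retest_sd": sd_r,
            "dif_mean": float(np.mean(r - t)), "dif_sd": float(np.std(r - t, ddof=1)),
            "icc": icc_v, "sem": sem(sd_t, sd_r, icc_v, pooling),
            "mdc95": m, "mdces95": mdces95(m, sd_t) if sd_t > 0 else np.nan,
        })
    return ReliabilityReport(frame=pd.DataFrame(rows))


def _category_of(variable: str) -> str:
    v = variable.lower()
    if "step" in v:
        return "step"
    if "support" in v:
        return "support"
    if "speed" in v:
        return "speed"
    return "kinematic"


def load_reference_reliability(config: Optional[str] = None) -> pd.DataFrame:
    """Packaged test-retest summary rows of the two capture configurations.

    A 33-subject healthy-adult reference study: per variable and side, the
    test/retest means and SDs, ICC, MDCes95 and MDC95 for the IMU
    (over-ground) and optical (treadmill) configurations.  ``config``
    filters to ``"imu"`` or ``"optical"``.
    """
    from importlib import resources

    with resources.files("gaitbox.data").joinpath("reference_reliability.csv").open() as fh:
        df = pd.read_csv(fh)
    if config is not None:
        df = df[df["config"] == config].reset_index(drop=True)
        if len(df) == 0:
            raise ReliabilityError(f"unknown configuration {config!r}")
    return df


def summarize(report) -> dict:
    """Category summaries of a reliability report.

    Accepts a :class:`ReliabilityReport` or a DataFrame with at least
    ``variable, side, category, icc, mdc95`` columns.  Returns unweighted
    means of MDC95 per category (step measures, support percentages, gait
    speed, kinematic ranges), the mean ICC and mean MDCes95 over all rows,
    and the right-left averaged MDC95 per variable.
    """
    df = report.frame if isinstance(report, ReliabilityReport) else report
    need = {"variable", "side", "category", "icc", "mdc95"}
    if not need <= set(df.columns):
        raise ReliabilityError(f"summary needs columns {sorted(need)}")
    out = {}
    for cat in ("step", "support", "speed", "kinematic"):
        vals = df.loc[df["category"] == cat, "mdc95"]
        if len(vals):
            out[f"mdc95_{cat}"] = float(vals.mean())
    out["mean_icc"] = float(df["icc"].mean())
    if "mdces95" in df.columns:
        out["mean_mdces95"] = float(df["mdces95"].mean())
    out["mdc95_side_averaged"] = (
        df.groupby("variable", sort=False)["mdc95"].mean().to_dict()
    )
    return out
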