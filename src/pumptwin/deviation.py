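"""Infusion-deviation statistics for gravimetric pump-accuracy runs.

Implements the continuous-weighing accuracy metrics used in
IEC 60601-2-24-style bench tests of infusion pumps:

* single-infusion deviation  |theoretical - actual| / theoretical * 100,
* mean / max / min deviation over repeated infusions of one set dose,
* cumulative ("total") deviation of a constant basal-rate run, and
* the paired t-test used to compare the mean deviations of two pump
  variants dose-by-dose.

Delivered doses are assumed to already be the mean of repeated weighings;
no balance-drift or evaporation correction is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InfusionRecord",
    "DeviationReport",
    "BasalRunReport",
    "PairedTTestResult",
    "single_deviation",
    "mean_deviation",
    "deviation_report",
    "basal_run_report",
    "paired_t_test",
    "t_test_from_summary",
    "read_infusion_log",
    "write_infusion_log",
]


@dataclass(frozen=True)
class InfusionRecord:
    """One commanded-vs-delivered infusion event.

    ``delivered_dose`` is the mean of the repeated weighings performed
    after the event (6 weighings in the bench protocol this mirrors).
    """

    index: int
    commanded_dose: float  # U
    delivered_dose: float  # U
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if self.commanded_dose <= 0:
            raise ValueError(f"commanded_dose must be > 0, got {self.commanded_dose}")
        if self.delivered_dose < 0:
            raise ValueError(f"delivered_dose must be >= 0, got {self.delivered_dose}")


@dataclass(frozen=True)
class DeviationReport:
    """Per-record and aggregate deviations, in percent of commanded dose."""

    per_record_deviation: tuple[float, ...]
    max_deviation: float
    min_deviation: float
    mean_deviation: float

    def rounded(self, ndigits: int = 2) -> "DeviationReport":
        """Display copy with percents rounded half-away-from-zero."""
        r = lambda x: _round_half_away(x, ndigits)
        return DeviationReport(
            per_record_deviation=tuple(r(d) for d in self.per_record_deviation),
            max_deviation=r(self.max_deviation),
            min_deviation=r(self.min_deviation),
            mean_deviation=r(self.mean_deviation),
        )


@dataclass(frozen=True)
class BasalRunReport:
    """Cumulative accounting of a constant basal-rate run."""

    rate: float  # U/h
    read_times: tuple[float, ...]  # h
    cumulative_actual: tuple[float, ...]  # U
    cumulative_theoretical: tuple[float, ...]  # U, rate * t exactly
    total_deviation: tuple[float, ...]  # percent per read

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.read_times,
                "cumulative_actual_U": self.cumulative_actual,
                "cumulative_theoretical_U": self.cumulative_theoretical,
                "total_deviation_pct": self.total_deviation,
            }
        )


@dataclass(frozen=True)
class PairedTTestResult:
    """Classical paired t-test summary (two-sided)."""

    n_pairs: int
    mean_difference: float
    sd_difference: float
    se_mean: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    ci95_low: float
    ci95_high: float


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed bench reports)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def single_deviation(theoretical: float, actual: float, *, signed: bool = False) -> float:
    """Deviation of one infusion, percent of the theoretical (set) dose.

    The default is the absolute-value convention, under which over- and
    under-delivery both count positive; ``signed=True`` keeps the sign
    (positive = under-delivery).
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical dose must be > 0, got {theoretical}")
    dev = (theoretical - actual) / theoretical * 100.0
    return dev if signed else abs(dev)


def mean_deviation(deviations: Sequence[float]) -> float:
    """Arithmetic mean of single-infusion deviations (percent)."""
    if len(deviations) == 0:
        raise ValueError("mean_deviation requires a nonempty list")
    return float(np.mean(deviations))


def deviation_report(records: Sequence[InfusionRecord], *, signed: bool = False) -> DeviationReport:
    """Aggregate single-infusion deviations into max/min/mean percents."""
    if len(records) == 0:
        raise ValueError("deviation_report requires at least one record")
    devs = tuple(
        single_deviation(r.commanded_dose, r.delivered_dose, signed=signed) for r in records
    )
    return DeviationReport(
        per_record_deviation=devs,
        max_deviation=max(devs),
        min_deviation=min(devs),
        mean_deviation=mean_deviation(devs),
    )


def basal_run_report(rate: float, reads: Sequence[tuple[float, float]]) -> BasalRunReport:
    """Total (cumulative) deviation at each read of a constant-rate run.

    ``reads`` is a sequence of (time_h, cumulative_actual_U) pairs with
    strictly increasing positive times; the theoretical cumulative dose at
    time t is exactly rate * t.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if len(reads) == 0:
        raise ValueError("basal_run_report requires at least one read")
    times = [t for t, _ in reads]
    actual = [a for _, a in reads]
    if any(t <= 0 for t in times):
        raise ValueError("read times must be > 0")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("read times must be strictly increasing")
    if any(a2 < a1 for a1, a2 in zip(actual, actual[1:])):
        raise ValueError("cumulative_actual must be nondecreasing")
    theo = [rate * t for t in times]
    dev = [abs(th - a) / th * 100.0 for th, a in zip(theo, actual)]
    return BasalRunReport(
        rate=rate,
        read_times=tuple(times),
        cumulative_actual=tuple(actual),
        cumulative_theoretical=tuple(theo),
        total_deviation=tuple(dev),
    )


def _from_summary(n: int, mean_diff: float, sd_diff: float) -> PairedTTestResult:
    if n < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    df = n - 1
    se = sd_diff / math.sqrt(n)
    if se == 0.0:
        if mean_diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            # degenerate: identical differences with nonzero mean
            t_stat, p = math.copysign(math.inf, mean_diff), 0.0
        ci_lo = ci_hi = mean_diff
    else:
        t_stat = mean_diff / se
        p = 2.0 * stats.t.sf(abs(t_stat), df)
        half = stats.t.ppf(0.975, df) * se
        ci_lo, ci_hi = mean_diff - half, mean_diff + half
    return PairedTTestResult(
        n_pairs=n,
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        se_mean=se,
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        ci95_low=ci_lo,
        ci95_high=ci_hi,
    )


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTTestResult:
    """Two-sided paired t-test on the element-wise differences a - b."""
    if len(a) != len(b):
        raise ValueError("paired_t_test requires equal-length samples")
    if len(a) < 2:
        raise ValueError("paired_t_test requires at least 2 pairs")
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return _from_summary(len(diffs), float(np.mean(diffs)), float(np.std(diffs, ddof=1)))


def t_test_from_summary(n: int, mean_diff: float, sd_diff: float) -> PairedTTestResult:
    """Paired t-test from summary statistics of the differences alone."""
    return _from_summary(n, float(mean_diff), float(sd_diff))


def read_infusion_log(path) -> list[InfusionRecord]:
    """Read an infusion log CSV: index, commanded_dose_U, delivered_dose_U[, timestamp]."""
    df = pd.read_csv(path)
    required = {"index", "commanded_dose_U", "delivered_dose_U"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"infusion log missing columns: {sorted(missing)}")
    has_ts = "timestamp" in df.columns
    return [
        InfusionRecord(
            index=int(row["index"]),
            commanded_dose=float(row["commanded_dose_U"]),
            delivered_dose=float(row["delivered_dose_U"]),
            timestamp=float(row["timestamp"]) if has_ts else None,
        )
        for _, row in df.iterrows()
    ]


def write_infusion_log(records: Sequence[InfusionRecord], path) -> None:
    df = pd.DataFrame(
        {
            "index": [r.index for r in records],
            "commanded_dose_U": [r.commanded_dose for r in records],
            "delivered_dose_U": [r.delivered_dose for r in records],
        }
    )
    if any(r.timestamp is not None for r in records):
        df["timestamp"] = [r.timestamp for r in records]
    df.to_csv(path, index=False)
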