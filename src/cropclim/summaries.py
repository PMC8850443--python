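"""Distribution summaries, IQR outlier rules and grouped impact tables."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSummary",
    "OutlierRule",
    "distribution_summary",
    "outlier_mask",
    "sensitivity_report",
    "grouped_impact_table",
    "period_bin",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Moment and quantile summary of one set of values.

    ``skewness`` / ``kurtosis`` are NaN-flagged when undefined (n < 3 resp. 4,
    or zero spread); ``kurtosis_convention`` records whether 'excess'
    (normal -> 0) or 'raw' (normal -> 3) is reported.
    """

    n: int
    min: float
    max: float
    mean: float
    q1: float
    median: float
    q3: float
    sd: float
    skewness: float
    kurtosis: float
    kurtosis_convention: str = "excess"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "kurtosis_convention": self.kurtosis_convention,
        }


@dataclass(frozen=True)
class OutlierRule:
    """1.5 x IQR fence rule.

    ``anchor='median'`` flags values outside ``median +- multiplier*IQR`` (the
    whisker definition used in the source box plots); ``anchor='quartiles'``
    uses classical Tukey fences ``[q1 - m*IQR, q3 + m*IQR]``.
    """

    anchor: str = "median"
    multiplier: float = 1.5
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.anchor not in ("median", "quartiles"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")

    def fences(self, values: np.ndarray) -> tuple[float, float]:
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=self.quantile_method)
        iqr = q3 - q1
        if self.anchor == "median":
            return med - self.multiplier * iqr, med + self.multiplier * iqr
        return q1 - self.multiplier * iqr, q3 + self.multiplier * iqr


def distribution_summary(values: Sequence[float], kurtosis_convention: str = "excess") -> DistributionSummary:
    """Summary statistics with bias-corrected sample skewness and kurtosis.

    Quantiles use linear interpolation of order statistics.  Empty input is an
    error; undefined higher moments come back as NaN, never silently as zero.
    """
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if kurtosis_convention not in ("excess", "raw"):
        raise ValueError(f"unknown kurtosis convention {kurtosis_convention!r}")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    # errstate: central moments can underflow for near-constant data, in which
    # case scipy returns NaN, which is exactly the undefined flag used here
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*catastrophic cancellation.*")
        if arr.size >= 3 and sd > 0:
            skew = float(stats.skew(arr, bias=False))
        else:
            skew = math.nan
        if arr.size >= 4 and sd > 0:
            kurt = float(stats.kurtosis(arr, fisher=True, bias=False))
            if kurtosis_convention == "raw":
                kurt += 3.0
        else:
            kurt = math.nan
    return DistributionSummary(
        n=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        kurtosis_convention=kurtosis_convention,
    )


def outlier_mask(values: Sequence[float], rule: OutlierRule = OutlierRule()) -> tuple[np.ndarray, int]:
    """Boolean mask of values outside the rule's fences, plus the flagged count.

    Values exactly on a fence are kept.  Requires at least four values so the
    quartiles are meaningful.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least four values for an IQR rule")
    lo, hi = rule.fences(arr)
    mask = (arr < lo) | (arr > hi)
    return mask, int(mask.sum())


def sensitivity_report(values: Sequence[float], rule: OutlierRule = OutlierRule()) -> dict:
    """Effect of dropping rule-flagged values on the mean and median."""
    arr = np.asarray(values, dtype=float)
    mask, n_removed = outlier_mask(arr, rule)
    kept = arr[~mask]
    report = {
        "rule_anchor": rule.anchor,
        "multiplier": rule.multiplier,
        "n_total": int(arr.size),
        "n_removed": n_removed,
        "pct_removed": 100.0 * n_removed / arr.size,
        "mean_before": float(arr.mean()),
        "median_before": float(np.median(arr)),
        "mean_after": float(kept.mean()) if kept.size else math.nan,
        "median_after": float(np.median(kept)) if kept.size else math.nan,
    }
    report["delta_mean"] = report["mean_after"] - report["mean_before"]
    report["delta_median"] = report["median_after"] - report["median_before"]
    return report


def grouped_impact_table(
    frame,
    group_keys: Sequence[str],
    metrics: Sequence[str],
    kurtosis_convention: str = "excess",
):
    """One DistributionSummary row per group x metric.

    ``frame`` is a harmonized DataFrame (see ``impacts.harmonized_frame``).
    NaN metric values (undefined per-degree ratios, missing impacts) are
    excluded; per metric, the group ``n`` columns therefore sum to the number
    of non-flagged records.
    """
    import pandas as pd

    for key in group_keys:
        if key not in frame.columns:
            raise KeyError(f"unknown group key {key!r}")
    for metric in metrics:
        if metric not in frame.columns:
            raise KeyError(f"unknown metric {metric!r}")

    rows = []
    grouped = frame.groupby(list(group_keys), dropna=False, sort=True, observed=True)
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            summary = distribution_summary(vals, kurtosis_convention)
            row = dict(zip(group_keys, key))
            row["metric"] = metric
            row.update(summary.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def period_bin(future_mid: int, mc_window: tuple[int, int] = (2040, 2069), ec_start: int = 2070) -> str:
    """Mid-century / end-century / near-future bin for a projection midpoint."""
    if future_mid >= ec_start:
        return "EC"
    if mc_window[0] <= future_mid <= mc_window[1]:
        return "MC"
    return "NF"
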