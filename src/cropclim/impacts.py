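"""Effect-size computations: relative yield impact, counterfactual variant,
baseline-period rescaling and per-decade / per-degree normalizations."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .corpus import CounterfactualYields, SimulationRecord

__all__ = [
    "ImpactConfig",
    "relative_yield_impact",
    "counterfactual_yield_impact",
    "baseline_correct",
    "per_decade_impact",
    "per_degree_impact",
    "harmonize_records",
    "harmonized_frame",
]


@dataclass(frozen=True)
class ImpactConfig:
    """Knobs for the harmonization step.

    ``per_degree_basis`` selects the warming variable used as the per-degree
    denominator (global by default); the chosen basis is stamped on every
    harmonized output so downstream tables are self-describing.
    """

    ref_mid_year: int = 2005
    counterfactual_mode: str = "corrected"  # "corrected" | "literal"
    per_degree_basis: str = "dTg_2005"  # "dTg_2005" | "dTl_2005"
    min_degree_denominator: float = 0.1
    min_year_gap: int = 1

    def __post_init__(self) -> None:
        if self.min_degree_denominator <= 0 or self.min_year_gap <= 0:
            raise ValueError("thresholds must be positive")
        if self.counterfactual_mode not in ("corrected", "literal"):
            raise ValueError(f"unknown counterfactual mode {self.counterfactual_mode!r}")
        if self.per_degree_basis not in ("dTg_2005", "dTl_2005"):
            raise ValueError(f"unknown per-degree basis {self.per_degree_basis!r}")


def relative_yield_impact(Yf: float, Yb: float) -> float:
    """Percent yield change of a future relative to a baseline yield.

    Returns ``(Yf/Yb - 1) * 100``; always >= -100 for non-negative yields.
    """
    if Yb <= 0:
        raise ValueError(f"baseline yield must be positive, got {Yb}")
    if Yf < 0:
        raise ValueError(f"future yield must be non-negative, got {Yf}")
    # (Yf - Yb)/Yb form keeps the zero-trend counterfactual bit-identical
    return (Yf - Yb) / Yb * 100.0


def counterfactual_yield_impact(y: CounterfactualYields, mode: str = "corrected") -> float:
    """Yield impact from paired climate-change / no-climate-change runs.

    ``corrected`` (default) returns the trend-difference relative to the
    climate-change baseline, so identical trends cancel to zero.  ``literal``
    applies an additional ``- 1`` inside the bracket before scaling, retained
    for auditing only: it scores identical trends as -100%.
    """
    if y.Yb_cc <= 0:
        raise ValueError("Yb_cc must be positive")
    trend_diff = (y.Yf_cc - y.Yb_cc) - (y.Yf_ncc - y.Yb_ncc)
    if mode == "corrected":
        return trend_diff / y.Yb_cc * 100.0
    if mode == "literal":
        return (trend_diff / y.Yb_cc - 1.0) * 100.0
    raise ValueError(f"unknown mode {mode!r}")


def baseline_correct(
    value: float,
    future_mid: int,
    base_mid: int,
    ref_mid: int = 2005,
    min_year_gap: int = 1,
) -> float:
    """Rescale a change to the reference baseline midpoint by linear interpolation.

    The value is divided by the study's own year gap (future minus baseline
    midpoint) and multiplied by the gap from the reference midpoint.  Identity
    when ``base_mid == ref_mid``; homogeneous of degree one in ``value``.
    """
    gap = future_mid - base_mid
    if gap < min_year_gap:
        raise ValueError(f"study year gap {gap} below minimum {min_year_gap}")
    return value * (future_mid - ref_mid) / gap


def per_decade_impact(
    YI_2005: float, future_mid: int, ref_mid: int = 2005, min_year_gap: int = 1
) -> float:
    """Harmonized impact expressed per decade since the reference midpoint."""
    gap = future_mid - ref_mid
    if gap < min_year_gap:
        raise ValueError(f"year gap {gap} below minimum {min_year_gap}")
    return YI_2005 / gap * 10.0


def per_degree_impact(
    YI_2005: float, warming: float | None, min_degree_denominator: float = 0.1
) -> float:
    """Harmonized impact per degree of warming.

    Warming magnitudes below ``min_degree_denominator`` (or missing) make the
    ratio meaningless; NaN is returned as an undefined flag and such values
    are excluded from summaries rather than treated as zero.
    """
    if warming is None or math.isnan(warming) or abs(warming) < min_degree_denominator:
        return math.nan
    return YI_2005 / warming


def harmonize_records(
    records: Sequence[SimulationRecord],
    config: ImpactConfig = ImpactConfig(),
    preindustrial_offset: float = 0.8,
) -> list[SimulationRecord]:
    """Fill derived effect-size fields on copies of the input records.

    Computes YI_raw from yields when absent, rescales YI / dTl / dPr to the
    reference baseline midpoint, and fills dTg_pi from dTg_2005 (or vice
    versa) using the configured preindustrial offset.
    """
    out = []
    for rec in records:
        rec = rec.copy()
        if rec.YI_raw is None and rec.Yb is not None and rec.Yf is not None:
            rec.YI_raw = relative_yield_impact(rec.Yf, rec.Yb)
        can_correct = rec.future_mid is not None and rec.base_mid is not None
        if can_correct:
            args = (rec.future_mid, rec.base_mid, config.ref_mid_year, config.min_year_gap)
            if rec.YI_2005 is None and rec.YI_raw is not None:
                rec.YI_2005 = baseline_correct(rec.YI_raw, *args)
            if rec.dTl_2005 is None and rec.dTl is not None:
                rec.dTl_2005 = baseline_correct(rec.dTl, *args)
            if rec.dPr_2005 is None and rec.dPr is not None:
                rec.dPr_2005 = baseline_correct(rec.dPr, *args)
        if rec.dTg_pi is None and rec.dTg_2005 is not None:
            rec.dTg_pi = rec.dTg_2005 + preindustrial_offset
        elif rec.dTg_2005 is None and rec.dTg_pi is not None:
            rec.dTg_2005 = rec.dTg_pi - preindustrial_offset
        out.append(rec)
    return out


def harmonized_frame(records: Sequence[SimulationRecord], config: ImpactConfig = ImpactConfig()):
    """Harmonize and tabulate records with per-decade / per-degree columns.

    The returned DataFrame carries a ``per_degree_basis`` column recording
    which warming variable divided each impact.
    """
    import pandas as pd

    from .corpus import records_to_frame

    harmonized = harmonize_records(records, config)
    frame = records_to_frame(harmonized)

    per_decade, per_degree = [], []
    for rec in harmonized:
        if rec.YI_2005 is None or rec.future_mid is None:
            per_decade.append(math.nan)
        elif rec.future_mid - config.ref_mid_year < config.min_year_gap:
            per_decade.append(math.nan)
        else:
            per_decade.append(per_decade_impact(rec.YI_2005, rec.future_mid, config.ref_mid_year))
        warming = getattr(rec, config.per_degree_basis)
        if rec.YI_2005 is None:
            per_degree.append(math.nan)
        else:
            per_degree.append(
                per_degree_impact(rec.YI_2005, warming, config.min_degree_denominator)
            )
    frame["per_decade"] = pd.Series(per_decade, dtype=float)
    frame["per_degree"] = pd.Series(per_degree, dtype=float)
    frame["per_degree_basis"] = config.per_degree_basis
    return frame
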