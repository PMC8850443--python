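"""Matched with/without-adaptation pairing and adaptation potential."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .corpus import SimulationRecord

__all__ = [
    "PAIR_KEY_FIELDS",
    "AdaptationPair",
    "PairingReport",
    "find_adaptation_pairs",
    "adaptation_potential",
    "best_planting_time",
]

#: Fields that must agree between the two sides of a pair.  CO2 treatment is
#: part of the key so CO2-on and CO2-off runs never pair with each other.
PAIR_KEY_FIELDS = ("study_id", "site_label", "crop", "scenario", "future_mid", "co2_included")


@dataclass(frozen=True)
class AdaptationPair:
    key: tuple
    with_record: SimulationRecord
    without_record: SimulationRecord

    @property
    def options(self) -> set[str]:
        return set(self.with_record.adaptation_options)

    @property
    def potential(self) -> float:
        return adaptation_potential(self)


@dataclass
class PairingReport:
    pairs: list[AdaptationPair]
    unmatched: list[SimulationRecord]  # adaptation runs with no counterpart
    ambiguous: list[tuple]  # keys with >1 no-adaptation record


def _pair_key(rec: SimulationRecord) -> tuple:
    return tuple(getattr(rec, f) for f in PAIR_KEY_FIELDS)


def find_adaptation_pairs(
    records: Sequence[SimulationRecord],
    key_fields: Sequence[str] = PAIR_KEY_FIELDS,
) -> PairingReport:
    """Match every adaptation run to the unique no-adaptation run of its group.

    Groups holding exactly one no-adaptation record produce one pair per
    adaptation record.  Groups with several no-adaptation records are
    ambiguous and reported rather than paired; adaptation records with no
    counterpart are listed as unmatched.
    """

    def key_of(rec: SimulationRecord) -> tuple:
        return tuple(getattr(rec, f) for f in key_fields)

    withs: dict[tuple, list[SimulationRecord]] = {}
    withouts: dict[tuple, list[SimulationRecord]] = {}
    for rec in records:
        (withs if rec.adaptation else withouts).setdefault(key_of(rec), []).append(rec)

    pairs: list[AdaptationPair] = []
    unmatched: list[SimulationRecord] = []
    ambiguous: list[tuple] = []
    for key, adapted in withs.items():
        counterparts = withouts.get(key, [])
        if len(counterparts) == 1:
            pairs.extend(AdaptationPair(key, w, counterparts[0]) for w in adapted)
        elif len(counterparts) > 1:
            ambiguous.append(key)
        else:
            unmatched.extend(adapted)
    return PairingReport(pairs, unmatched, ambiguous)


def adaptation_potential(pair: AdaptationPair) -> float:
    """Percentage-point gain of adapting: with-impact minus without-impact."""
    yi_with = pair.with_record.YI_2005
    yi_without = pair.without_record.YI_2005
    if yi_with is None or yi_without is None:
        raise ValueError("both records need a harmonized YI_2005")
    return yi_with - yi_without


def best_planting_time(
    records: Sequence[SimulationRecord],
    group_key: Callable[[SimulationRecord], tuple] = _pair_key,
    variant_label: Callable[[SimulationRecord], str] = lambda r: r.remark,
) -> list[SimulationRecord]:
    """Keep, per group, the planting-time variant with the highest future yield.

    Ties break deterministically toward the earliest variant label.  Records
    without a future yield never win over records that have one.
    """
    groups: dict[tuple, list[SimulationRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        k = group_key(rec)
        if k not in groups:
            order.append(k)
        groups.setdefault(k, []).append(rec)

    best = []
    for k in order:
        members = sorted(
            groups[k],
            key=lambda r: (-(r.Yf if r.Yf is not None else float("-inf")), variant_label(r)),
        )
        best.append(members[0])
    return best
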