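"""Explicit well-level enumeration of combinations with the redundancy filter.

This module is the brute-force oracle for the closed forms in
:mod:`rotoscreen.combinatorics`: it enumerates every r-subset of occupied
wells, discards the *redundant* ones — combinations holding two or more
dilutions of the same drug, which carry no new pharmacological information —
and counts what is left.

The closed-form dilution-reduced count and this set-theoretic filter
provably coincide for r = 2 (any number of radii) and for n_rad = r, but
for n_rad > r >= 3 the closed form counts a smaller set than "distinct
drugs, free dilutions" (e.g. 96 vs 108 at r = 3, n_rad = 4) while still
exceeding the one-well-per-ring count.  Both numbers are reported side by
side wherever they are compared; the discrepancy is a stable property of
the published formula, never silently reconciled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

from . import combinatorics as comb
from .geometry import InstrumentConfig, Well, WellMap, make_dilution_layout

__all__ = [
    "Combination",
    "CombinationClass",
    "EnumerationBoundError",
    "enumerate_combinations",
    "is_redundant",
    "filter_meaningful",
    "count_meaningful",
    "classify",
    "OracleReport",
    "oracle_report",
]

#: Default hard bound on the number of subsets an oracle call may visit.
DEFAULT_MAX_CELLS = 1_000_000


class EnumerationBoundError(RuntimeError):
    """Raised when an enumeration would exceed its configured size bound."""


class CombinationClass(str, Enum):
    CIRCUMFERENTIAL = "circumferential"
    RADIAL_MIXED = "radial/mixed"


@dataclass(frozen=True)
class Combination:
    """An unordered set of r distinct wells, stored in canonical order.

    Equality and hashing use the (ring, radius)-sorted well tuple; the
    droplet dispensing order is a scheduling concern, not part of the
    combination's identity.
    """

    wells: tuple[Well, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.wells, key=lambda w: (w.ring, w.radius)))
        if len(set((w.ring, w.radius) for w in ordered)) != len(ordered):
            raise ValueError("a combination cannot repeat a well")
        object.__setattr__(self, "wells", ordered)

    @property
    def r(self) -> int:
        return len(self.wells)

    @property
    def drug_set(self) -> frozenset[tuple[int, int]]:
        """(drug id, dilution level) pairs of the member drug wells."""
        return frozenset((w.drug, w.dilution) for w in self.wells if w.is_drug)

    @property
    def drugs(self) -> frozenset[int]:
        return frozenset(w.drug for w in self.wells if w.is_drug)

    @property
    def rings(self) -> frozenset[int]:
        return frozenset(w.ring for w in self.wells)


def enumerate_combinations(wellmap: WellMap, r: int) -> Iterator[Combination]:
    """Yield every r-subset of occupied wells, in lexicographic order.

    Order is by the canonical (ring, radius) well ordering, so identical
    well maps produce identical streams.  Total yield is C(#occupied, r).
    """
    occupied = wellmap.occupied_wells()
    if r > len(occupied):
        raise ValueError(
            f"cannot draw r={r} droplets from {len(occupied)} occupied wells"
        )
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    for subset in itertools.combinations(occupied, r):
        yield Combination(wells=subset)


def is_redundant(combo: Combination) -> bool:
    """True iff some drug appears in the combination at two or more wells.

    In the canonical dilution layout those wells necessarily hold different
    dilution levels of that drug, which is the redundancy the dilution
    reduction removes.  Cell/organoid wells never trigger redundancy.
    """
    drug_ids = [w.drug for w in combo.wells if w.is_drug]
    return len(drug_ids) != len(set(drug_ids))


def filter_meaningful(wellmap: WellMap, r: int) -> Iterator[Combination]:
    """The meaningful (non-redundant) subsequence of `enumerate_combinations`."""
    return (c for c in enumerate_combinations(wellmap, r) if not is_redundant(c))


def count_meaningful(wellmap: WellMap, r: int) -> tuple[int, int | None, bool | None]:
    """Count meaningful combinations by enumeration, beside the closed form.

    Returns ``(enumerated, closed_form, agree)``.  The closed form applies
    only to the canonical dilution layout under the n_ring = n_dil = r
    restriction; otherwise the last two entries are None.
    """
    enumerated = sum(1 for _ in filter_meaningful(wellmap, r))
    cfg = wellmap.config
    closed: int | None = None
    if (
        wellmap.is_canonical_dilution_layout()
        and cfg.n_rings == cfg.n_dilutions == r
        and cfg.n_radii >= r
    ):
        closed = comb.meaningful_combinations(r, cfg.n_radii)
    return enumerated, closed, (None if closed is None else enumerated == closed)


def classify(combo: Combination) -> CombinationClass:
    """Circumferential iff all member wells lie on a single ring."""
    if len(combo.rings) == 1:
        return CombinationClass.CIRCUMFERENTIAL
    return CombinationClass.RADIAL_MIXED


@dataclass(frozen=True)
class OracleReport:
    """Brute-force versus closed-form counts for one dilution design."""

    r: int
    n_rad: int
    enumerated_total: int
    enumerated_meaningful: int
    enumerated_circumferential: int
    closed_total: int
    closed_meaningful: int
    closed_circumferential: int

    @property
    def total_agrees(self) -> bool:
        return self.enumerated_total == self.closed_total

    @property
    def meaningful_agrees(self) -> bool:
        return self.enumerated_meaningful == self.closed_meaningful

    @property
    def circumferential_agrees(self) -> bool:
        return self.enumerated_circumferential == self.closed_circumferential


def oracle_report(
    r: int, n_rad: int, max_cells: int = DEFAULT_MAX_CELLS
) -> OracleReport:
    """Enumerate the (r x n_rad) dilution design and compare with closed forms.

    Refuses (with the size estimate in the message) when the subset count
    C(r * n_rad, r) exceeds ``max_cells``, so the oracle cannot be invoked
    at full commercial scale by accident.
    """
    if n_rad < r:
        raise ValueError(f"need n_rad >= r, got n_rad={n_rad} < r={r}")
    size = comb.binom(r * n_rad, r)
    if size > max_cells:
        raise EnumerationBoundError(
            f"enumeration of C({r * n_rad}, {r}) = {size} subsets exceeds "
            f"the bound of {max_cells}"
        )
    config = InstrumentConfig(n_rings=r, n_radii=n_rad, combo_order=r, n_dilutions=r)
    wellmap = make_dilution_layout(config)
    total = 0
    meaningful = 0
    circumferential = 0
    for combo in enumerate_combinations(wellmap, r):
        total += 1
        if not is_redundant(combo):
            meaningful += 1
            if classify(combo) is CombinationClass.CIRCUMFERENTIAL:
                circumferential += 1
    return OracleReport(
        r=r,
        n_rad=n_rad,
        enumerated_total=total,
        enumerated_meaningful=meaningful,
        enumerated_circumferential=circumferential,
        closed_total=comb.binom(r * n_rad, r),
        closed_meaningful=comb.meaningful_combinations(r, n_rad),
        closed_circumferential=comb.circumferential_combinations(r, n_rad),
    )
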