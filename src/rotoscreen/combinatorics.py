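"""Closed-form counting and timing for rotary combination screens.

All counts are exact arbitrary-precision integers; floating point enters
only in the time models.  Core quantities, for an instrument with
``n_ring`` rings, ``n_rad`` radii and combination order ``r``:

* ``total_combinations`` — C(n_ring*n_rad, r), every r-subset of wells.
* ``meaningful_combinations`` — the dilution-reduced count
  r * n_rad**(r-1) * (n_rad - r + 1), valid under the dilution design
  restriction n_ring = n_dil = r.  A combination is *meaningful* when no
  drug appears in it at two or more dilution levels; the closed form is an
  empirical observation rather than a proven identity and is
  cross-checked against the brute-force enumerator where the two semantics
  provably coincide (r = 2 any n_rad, and n_rad = r).
* ``circumferential_combinations`` — meaningful combinations whose wells
  all lie on one ring: r * C(n_rad, r) (r rings, each contributing its
  C(n_rad, r) single-dilution subsets).
* ``positions_*`` — rotor positions, at n_rad combinations dispensed per
  position.
* ``screen_time_days`` / ``ml_screen_time_days`` — wall-clock models at a
  fixed per-position cycle time (default 10 s) and, for the single-ring
  staged ("machine learning") screen, a dispensing parallelism of 192
  droplets per position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction

from .geometry import InstrumentConfig

__all__ = [
    "binom",
    "total_combinations",
    "positions_no_dilution",
    "meaningful_combinations",
    "circumferential_combinations",
    "radial_combinations",
    "positions_with_dilution",
    "screen_time_days",
    "ml_screen_time_days",
    "DesignCounts",
    "table1_row",
    "table1",
    "TABLE1_CONFIGS",
    "round_half_up",
]

SECONDS_PER_DAY = 86_400

#: (r, n_rad) pairs of the 27 published reference configurations, in order.
TABLE1_CONFIGS: tuple[tuple[int, int], ...] = (
    (2, 2), (2, 3), (2, 4), (2, 6), (2, 8), (2, 10), (2, 20), (2, 30), (2, 48),
    (3, 3), (3, 4), (3, 6), (3, 8), (3, 10), (3, 20), (3, 30), (3, 40), (3, 48),
    (4, 4), (4, 6), (4, 8), (4, 10), (4, 20), (4, 30), (4, 35), (4, 40), (4, 48),
)


def binom(n: int, r: int) -> int:
    """Exact binomial coefficient C(n, r); 0 when r > n."""
    if n < 0 or r < 0:
        raise ValueError(f"binom needs nonnegative arguments, got ({n}, {r})")
    return math.comb(n, r)


def total_combinations(config: InstrumentConfig) -> int:
    """Number of r-subsets of all wells, C(n_rings * n_radii, r)."""
    return binom(config.n_wells, config.combo_order)


def positions_no_dilution(config: InstrumentConfig) -> int | Fraction:
    """Rotor positions for the full (no-dilution) screen.

    C(n_rings*n_radii, r) / n_radii, assuming the ideal n_radii
    combinations dispensed per position.  Returns an int when the division
    is exact, otherwise a :class:`~fractions.Fraction` (the ideal is then
    not attainable exactly).
    """
    q = Fraction(total_combinations(config), config.n_radii)
    return int(q) if q.denominator == 1 else q


def _check_dilution_args(r: int, n_rad: int) -> None:
    if r < 1:
        raise ValueError(f"combination order r must be >= 1, got {r}")
    if n_rad < r:
        raise ValueError(
            f"dilution design needs n_rad >= r, got n_rad={n_rad} < r={r}"
        )


def meaningful_combinations(r: int, n_rad: int) -> int:
    """Dilution-reduced combination count r * n_rad**(r-1) * (n_rad - r + 1).

    Assumes the dilution design (n_ring = n_dil = r).  Reduces to r**r when
    n_rad = r.
    """
    _check_dilution_args(r, n_rad)
    return r * n_rad ** (r - 1) * (n_rad - r + 1)


def circumferential_combinations(r: int, n_rad: int) -> int:
    """Meaningful combinations whose r wells all lie on a single ring."""
    _check_dilution_args(r, n_rad)
    return r * binom(n_rad, r)


def radial_combinations(r: int, n_rad: int) -> int:
    """Meaningful combinations spanning two or more rings (radial/mixed)."""
    n = meaningful_combinations(r, n_rad) - circumferential_combinations(r, n_rad)
    assert n >= 0
    return n


def positions_with_dilution(r: int, n_rad: int) -> int:
    """Rotor positions for the dilution screen: meaningful count / n_rad.

    The division is always exact: for r >= 2 the meaningful count factors
    as n_rad * [r * n_rad**(r-2) * (n_rad - r + 1)], and for r = 1 it is
    n_rad itself.
    """
    total = meaningful_combinations(r, n_rad)
    q, rem = divmod(total, n_rad)
    if rem:  # pragma: no cover - impossible for the closed form
        raise ArithmeticError(
            f"meaningful count {total} not divisible by n_rad={n_rad}"
        )
    return q


def screen_time_days(positions: int, seconds_per_position: float = 10.0) -> float:
    """Screen duration in days: positions * cycle time / 86 400."""
    if positions < 0:
        raise ValueError(f"positions must be >= 0, got {positions}")
    if seconds_per_position <= 0:
        raise ValueError(
            f"seconds_per_position must be > 0, got {seconds_per_position}"
        )
    return positions * seconds_per_position / SECONDS_PER_DAY


def ml_screen_time_days(
    r: int,
    n_rad: int,
    seconds_per_position: float = 10.0,
    droplets_per_position: int = 192,
) -> float:
    """Duration of the single-ring staged screen, in days.

    One ring holds n_rad wells at a single dilution; screening it takes
    C(n_rad, r) combinations of r droplets each, dispensed at
    ``droplets_per_position`` droplets per position (default 192, the full
    instrument's well count).  This is the per-step cost of the staged
    synergy search.
    """
    _check_dilution_args(r, n_rad)
    if droplets_per_position < 1:
        raise ValueError(
            f"droplets_per_position must be >= 1, got {droplets_per_position}"
        )
    droplets = binom(n_rad, r) * r
    positions = droplets / droplets_per_position
    return positions * seconds_per_position / SECONDS_PER_DAY


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as the published tables do."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class DesignCounts:
    """All counting and timing quantities for one instrument configuration.

    One row of the published configuration table: the full and
    dilution-reduced combination counts, their circumferential/radial
    decompositions, position counts, and the two time models.
    """

    r: int
    n_rad: int
    n_ring: int
    total_combinations: int
    meaningful_combinations: int
    circumferential_combinations: int
    radial_combinations: int
    circumferential_no_dilution: int
    radial_no_dilution: int
    positions_no_dilution: int | Fraction
    positions_with_dilution: int
    screen_time_days: float
    ml_screen_time_days: float

    def as_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["positions_no_dilution"], Fraction):
            d["positions_no_dilution"] = float(d["positions_no_dilution"])
        return d


def table1_row(
    r: int,
    n_rad: int,
    seconds_per_position: float = 10.0,
    droplets_per_position_ml: int = 192,
) -> DesignCounts:
    """Compute every design quantity for the dilution design (r, n_rad).

    The configuration has r rings (= r dilutions) and n_rad radii.  The
    no-dilution circumferential count is n_ring * C(n_rad, r) (all wells on
    one ring); its radial/mixed complement is total - circumferential.
    """
    _check_dilution_args(r, n_rad)
    config = InstrumentConfig(
        n_rings=r,
        n_radii=n_rad,
        combo_order=r,
        n_dilutions=r,
        seconds_per_position=seconds_per_position,
        droplets_per_position_ml=droplets_per_position_ml,
    )
    total = total_combinations(config)
    circ_nodil = r * binom(n_rad, r)
    meaningful = meaningful_combinations(r, n_rad)
    circ = circumferential_combinations(r, n_rad)
    return DesignCounts(
        r=r,
        n_rad=n_rad,
        n_ring=r,
        total_combinations=total,
        meaningful_combinations=meaningful,
        circumferential_combinations=circ,
        radial_combinations=meaningful - circ,
        circumferential_no_dilution=circ_nodil,
        radial_no_dilution=total - circ_nodil,
        positions_no_dilution=positions_no_dilution(config),
        positions_with_dilution=positions_with_dilution(r, n_rad),
        screen_time_days=screen_time_days(
            positions_with_dilution(r, n_rad), seconds_per_position
        ),
        ml_screen_time_days=ml_screen_time_days(
            r, n_rad, seconds_per_position, droplets_per_position_ml
        ),
    )


def table1(
    seconds_per_position: float = 10.0, droplets_per_position_ml: int = 192
) -> list[DesignCounts]:
    """The 27 published reference configurations, recomputed in order."""
    return [
        table1_row(r, n_rad, seconds_per_position, droplets_per_position_ml)
        for r, n_rad in TABLE1_CONFIGS
    ]
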