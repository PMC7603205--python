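"""Geometry of the rotary dispenser: concentric rings of wells and their contents.

The instrument is a stack of ``n_rings`` concentric rings, each carrying
``n_radii`` wells at a common angular pitch, so that the wells also line up
along ``n_radii`` radial lines ("radii").  Rings rotate; a shuttle travels
along a radius collecting one droplet per well it aligns with, so an
``r``-droplet combination is drawn from ``r`` distinct wells.

In the canonical *dilution layout* every radius is dedicated to one drug and
every ring to one dilution level of it: well ``(ring i, radius j)`` holds
drug ``j`` at dilution level ``i``.  Level 0 is the most concentrated stock;
levels increase with dilution.  All indices here are 0-based (ring 0
innermost, radii numbered clockwise); 1-based labels exist only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "InstrumentConfig",
    "Well",
    "WellMap",
    "ValidationReport",
    "ConfigError",
    "make_dilution_layout",
    "validate_config",
]


class ConfigError(ValueError):
    """An instrument configuration violates a structural invariant."""


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry and timing parameters of one instrument build.

    Parameters
    ----------
    n_rings : int
        Number of concentric rings. In the dilution design this equals both
        the number of dilution levels and the combination order.
    n_radii : int
        Number of radial well lines; in the dilution design, the number of
        distinct drugs.
    combo_order : int
        ``r``, droplets per combination.
    n_dilutions : int
        Number of dilution levels per drug.
    seconds_per_position : float
        Cycle time charged per rotor position (default 10 s, calibrated so
        that the screen-time model reproduces the published configuration
        table, e.g. 236 800 positions <-> 27.4 days).
    droplets_per_position_ml : int
        Dispensing parallelism assumed by the single-ring machine-learning
        time model (default 192, the well count of the full 48 x 4 build).
    """

    n_rings: int
    n_radii: int
    combo_order: int
    n_dilutions: int
    seconds_per_position: float = 10.0
    droplets_per_position_ml: int = 192

    def __post_init__(self) -> None:
        report = validate_config(self, dilution_mode=False)
        if not report.ok:
            raise ConfigError("; ".join(report.violations))

    @property
    def n_wells(self) -> int:
        return self.n_rings * self.n_radii


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of configuration validation: the config plus any violations."""

    config: "InstrumentConfig | None"
    violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def _violations(
    n_rings: int,
    n_radii: int,
    combo_order: int,
    n_dilutions: int,
    seconds_per_position: float,
    droplets_per_position_ml: int,
    dilution_mode: bool,
) -> list[str]:
    out: list[str] = []
    if n_rings < 1:
        out.append(f"n_rings must be >= 1, got {n_rings}")
    if n_radii < 1:
        out.append(f"n_radii must be >= 1, got {n_radii}")
    if n_dilutions < 1:
        out.append(f"n_dilutions must be >= 1, got {n_dilutions}")
    if combo_order < 1:
        out.append(f"combo_order must be >= 1, got {combo_order}")
    elif n_rings >= 1 and n_radii >= 1 and combo_order > n_rings * n_radii:
        out.append(
            f"combo_order r={combo_order} exceeds the well count "
            f"{n_rings}x{n_radii}={n_rings * n_radii}"
        )
    if seconds_per_position <= 0:
        out.append(f"seconds_per_position must be > 0, got {seconds_per_position}")
    if droplets_per_position_ml < 1:
        out.append(
            f"droplets_per_position_ml must be >= 1, got {droplets_per_position_ml}"
        )
    if dilution_mode and not (n_rings == n_dilutions == combo_order):
        out.append(
            "dilution design requires n_rings = n_dilutions = combo_order, "
            f"got n_rings={n_rings}, n_dilutions={n_dilutions}, r={combo_order}"
        )
    return out


def validate_config(
    config: InstrumentConfig, dilution_mode: bool = False
) -> ValidationReport:
    """Check every structural invariant of *config*.

    Returns a :class:`ValidationReport`; when ``dilution_mode`` is on, the
    dilution-design restriction (ring count = dilution count = combination
    order) is additionally enforced.  Violations are reported, never raised.
    """
    violations = _violations(
        config.n_rings,
        config.n_radii,
        config.combo_order,
        config.n_dilutions,
        config.seconds_per_position,
        config.droplets_per_position_ml,
        dilution_mode,
    )
    return ValidationReport(config=config if not violations else None,
                            violations=tuple(violations))


@dataclass(frozen=True, order=True)
class Well:
    """One well slot: position plus content.

    ``kind`` is ``"drug"`` (with ``drug`` id and ``dilution`` level),
    ``"cell"`` (a cell or organoid well; never counts toward drug
    redundancy), or ``"empty"``.
    """

    ring: int
    radius: int
    kind: str = "drug"
    drug: int | None = None
    dilution: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("drug", "cell", "empty"):
            raise ValueError(f"unknown well kind {self.kind!r}")
        if self.kind == "drug":
            if self.drug is None or self.dilution is None:
                raise ValueError("a drug well needs both drug id and dilution level")
        elif self.drug is not None or self.dilution is not None:
            raise ValueError(f"a {self.kind} well carries no drug content")

    @property
    def is_drug(self) -> bool:
        return self.kind == "drug"

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"


@dataclass(frozen=True)
class WellMap:
    """Assignment of content to every (ring, radius) slot of an instrument."""

    config: InstrumentConfig
    wells: tuple[Well, ...]
    _index: dict[tuple[int, int], Well] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        cfg = self.config
        seen: dict[tuple[int, int], Well] = {}
        for w in self.wells:
            if not (0 <= w.ring < cfg.n_rings and 0 <= w.radius < cfg.n_radii):
                raise ValueError(f"well ({w.ring}, {w.radius}) is outside the rotor")
            if w.is_drug and not (0 <= w.dilution < cfg.n_dilutions):
                raise ValueError(
                    f"dilution level {w.dilution} outside [0, {cfg.n_dilutions})"
                )
            if (w.ring, w.radius) in seen:
                raise ValueError(f"duplicate well slot ({w.ring}, {w.radius})")
            seen[(w.ring, w.radius)] = w
        if len(seen) != cfg.n_wells:
            raise ValueError(
                f"well map covers {len(seen)} slots, expected {cfg.n_wells}"
            )
        object.__setattr__(self, "_index", seen)

    def well(self, ring: int, radius: int) -> Well:
        return self._index[(ring, radius)]

    def occupied_wells(self) -> tuple[Well, ...]:
        """All non-empty wells in canonical (ring, radius) order."""
        return tuple(w for w in sorted(self.wells) if not w.is_empty)

    def drug_ids(self) -> tuple[int, ...]:
        return tuple(sorted({w.drug for w in self.wells if w.is_drug}))

    def is_canonical_dilution_layout(self) -> bool:
        """True iff well (i, j) holds drug j at dilution i for every slot."""
        return all(
            w.is_drug and w.drug == w.radius and w.dilution == w.ring
            for w in self.wells
        )


def make_dilution_layout(config: InstrumentConfig) -> WellMap:
    """Build the canonical dilution layout for *config*.

    Well ``(ring i, radius j)`` receives drug ``j`` at dilution level ``i``:
    one drug per radius, one dilution level per ring.  Requires the ring
    count to equal the dilution count.
    """
    if config.n_dilutions != config.n_rings:
        raise ConfigError(
            f"dilution layout needs n_dilutions == n_rings, got "
            f"{config.n_dilutions} != {config.n_rings}"
        )
    wells = tuple(
        Well(ring=i, radius=j, kind="drug", drug=j, dilution=i)
        for i in range(config.n_rings)
        for j in range(config.n_radii)
    )
    return WellMap(config=config, wells=wells)


def with_cell_well(wellmap: WellMap, ring: int, radius: int) -> WellMap:
    """Return a copy of *wellmap* with one slot replaced by a cell/organoid well."""
    wells = tuple(
        Well(ring=w.ring, radius=w.radius, kind="cell")
        if (w.ring, w.radius) == (ring, radius)
        else w
        for w in wellmap.wells
    )
    return replace(wellmap, wells=wells)
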