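"""Discrete rotor/shuttle scheduling: turn a target combination list into a
verifiable dispensing plan.

Model
-----
A *position* is a tuple of circumferential offsets, one per ring, in
well-pitch units (one pitch = 360°/n_radii).  With offset ``o_i`` on ring
``i``, the well at radius index ``j`` sits under radial line
``(j + o_i) mod n_radii``.  At a fixed position, up to ``n_radii`` shuttle
*passes* execute, one per radial outlet line; a pass collects the wells of
one combination.  The shuttle may bypass wells it does not need.  When a
combination takes several wells from the same ring, the ring advances in
incremental steps between collections within the pass (a *mixed* movement);
these intra-position steps are counted in the execution trace but do not
open a new position, matching the closed-form position accounting in
:mod:`rotoscreen.combinatorics`, which remains the authoritative ideal.

The greedy planner exploits rotational symmetry: rotating every radius
index of a combination by ``t`` produces a sibling that the same rotor
position dispenses on radial line ``t`` instead of line 0.  Targets are
therefore grouped into rotation orbits, one position per orbit.  No
optimality is claimed; the plan is deterministic and is validated by
replay (:func:`simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .combinatorics import screen_time_days
from .enumeration import Combination
from .geometry import Well, WellMap

__all__ = [
    "RotorPosition",
    "ShuttlePass",
    "DispensingPlan",
    "ExecutionTrace",
    "PlanningError",
    "TraceError",
    "plan_screen",
    "simulate",
    "position_efficiency",
]


class PlanningError(ValueError):
    """A target set cannot be scheduled on the given well map."""


class TraceError(RuntimeError):
    """Replay of a plan violated a geometric or ledger invariant."""


@dataclass(frozen=True)
class RotorPosition:
    """Circumferential offsets of every ring, reduced modulo n_radii."""

    ring_offsets: tuple[int, ...]

    def slot(self, ring: int, radius: int, n_radii: int) -> int:
        """Radial line under which well (ring, radius) sits at this position."""
        return (radius + self.ring_offsets[ring]) % n_radii


@dataclass(frozen=True)
class ShuttlePass:
    """One radial shuttle traversal dispensing one combination.

    ``collected_wells`` is ordered by collection; the first well taken from
    each ring must already be aligned with ``radius_index`` at the parent
    position's offsets, later same-ring wells arrive by incremental ring
    steps (``ring_steps`` counts them).
    """

    radius_index: int
    collected_wells: tuple[Well, ...]
    dispensed_combination: Combination
    ring_steps: int = 0


@dataclass(frozen=True)
class DispensingPlan:
    """Ordered rotor positions with their shuttle passes and a ledger."""

    wellmap: WellMap
    positions: tuple[RotorPosition, ...]
    passes: tuple[tuple[ShuttlePass, ...], ...]  # grouped by position
    ledger: dict[Combination, tuple[int, int]] = field(compare=False)
    # ledger maps combination -> (position index, pass index within position)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_combinations(self) -> int:
        return len(self.ledger)

    @property
    def n_droplets(self) -> int:
        return sum(c.r for c in self.ledger)


@dataclass(frozen=True)
class ExecutionTrace:
    """Counters from replaying a plan against the geometry."""

    n_positions: int
    n_passes: int
    n_droplets: int
    n_ring_steps: int
    elapsed_days: float


def _rotate_key(
    combo: Combination, t: int, n_radii: int
) -> tuple[tuple[int, int], ...]:
    """Canonical (ring, radius) key of *combo* rotated clockwise by t pitches."""
    return tuple(
        sorted((w.ring, (w.radius + t) % n_radii) for w in combo.wells)
    )


def _orbit_representative(
    combo: Combination, n_radii: int
) -> tuple[tuple[tuple[int, int], ...], int]:
    """Lexicographically smallest rotation of *combo* and the smallest t
    rotating that representative back onto *combo*."""
    keys = [(_rotate_key(combo, t, n_radii), t) for t in range(n_radii)]
    rep = min(k for k, _ in keys)
    # smallest t with rep rotated by t == combo's own key
    own = _rotate_key(combo, 0, n_radii)
    t_member = min(
        t for t in range(n_radii)
        if tuple(sorted((i, (j + t) % n_radii) for i, j in rep)) == own
    )
    return rep, t_member


def _pass_for(
    wellmap: WellMap, combo: Combination, radius_index: int, position: RotorPosition
) -> ShuttlePass:
    """Build the collection order for dispensing *combo* on *radius_index*."""
    n_radii = wellmap.config.n_radii
    collected: list[Well] = []
    ring_steps = 0
    for ring in sorted(combo.rings):
        ring_wells = [w for w in combo.wells if w.ring == ring]
        # clockwise step count needed to bring each well under the outlet line
        def steps(w: Well) -> int:
            return (radius_index - position.slot(w.ring, w.radius, n_radii)) % n_radii
        ring_wells.sort(key=steps)
        if steps(ring_wells[0]) != 0:
            raise PlanningError(
                f"no well of ring {ring} aligned with radius {radius_index}"
            )
        collected.extend(ring_wells)
        ring_steps += steps(ring_wells[-1])
    return ShuttlePass(
        radius_index=radius_index,
        collected_wells=tuple(collected),
        dispensed_combination=combo,
        ring_steps=ring_steps,
    )


def plan_screen(wellmap: WellMap, targets) -> DispensingPlan:
    """Schedule every target combination into rotor positions.

    Targets must be distinct, of one common size, and reference occupied
    wells of *wellmap*.  The plan is deterministic given the well map and
    the target order; combinations in one rotation orbit share a position.
    """
    cfg = wellmap.config
    n_radii = cfg.n_radii
    target_list = list(targets)
    seen: set[Combination] = set()
    sizes = {c.r for c in target_list}
    if len(sizes) > 1:
        raise PlanningError(f"targets have mixed sizes {sorted(sizes)}")
    for combo in target_list:
        if combo in seen:
            raise PlanningError(f"duplicate target combination {combo}")
        seen.add(combo)
        for w in combo.wells:
            slot_well = wellmap.well(w.ring, w.radius)
            if slot_well != w or w.is_empty:
                raise PlanningError(
                    f"combination {combo} references well ({w.ring}, {w.radius}) "
                    "that is empty or absent from the well map"
                )

    # group by rotation orbit, preserving first-appearance order
    buckets: dict[tuple, list[tuple[int, Combination]]] = {}
    order: list[tuple] = []
    for combo in target_list:
        rep, t = _orbit_representative(combo, n_radii)
        if rep not in buckets:
            buckets[rep] = []
            order.append(rep)
        buckets[rep].append((t, combo))

    positions: list[RotorPosition] = []
    grouped_passes: list[tuple[ShuttlePass, ...]] = []
    ledger: dict[Combination, tuple[int, int]] = {}
    for rep in order:
        members = sorted(buckets[rep])  # by pass radius t
        # offsets aligning the representative's first well per ring with line 0
        offsets = [0] * cfg.n_rings
        first_radius: dict[int, int] = {}
        for ring, radius in rep:
            first_radius.setdefault(ring, radius)
        for ring, radius in first_radius.items():
            offsets[ring] = (-radius) % n_radii
        position = RotorPosition(ring_offsets=tuple(offsets))
        pos_index = len(positions)
        passes = []
        for pass_index, (t, combo) in enumerate(members):
            sp = _pass_for(wellmap, combo, t, position)
            passes.append(sp)
            ledger[combo] = (pos_index, pass_index)
        positions.append(position)
        grouped_passes.append(tuple(passes))

    return DispensingPlan(
        wellmap=wellmap,
        positions=tuple(positions),
        passes=tuple(grouped_passes),
        ledger=ledger,
    )


def simulate(plan: DispensingPlan, wellmap: WellMap | None = None) -> ExecutionTrace:
    """Replay *plan* against the geometry, asserting every invariant.

    Checks per pass: wells exist and are occupied, no well collected twice,
    the first well taken from each ring is aligned with the outlet line at
    the position's offsets, and the collected set equals the dispensed
    combination.  Checks globally: the ledger covers every dispensed
    combination exactly once.  Returns counters and the modelled elapsed
    time at the configured per-position cycle time.
    """
    wellmap = wellmap if wellmap is not None else plan.wellmap
    cfg = wellmap.config
    n_radii = cfg.n_radii
    dispensed: set[Combination] = set()
    n_passes = 0
    n_droplets = 0
    n_ring_steps = 0
    for pos_index, (position, passes) in enumerate(zip(plan.positions, plan.passes)):
        if len(position.ring_offsets) != cfg.n_rings:
            raise TraceError(f"position {pos_index}: offset tuple has wrong arity")
        radii_used: set[int] = set()
        for sp in passes:
            if sp.radius_index in radii_used:
                raise TraceError(
                    f"position {pos_index}: radius {sp.radius_index} used twice"
                )
            radii_used.add(sp.radius_index)
            combo = sp.dispensed_combination
            if len(sp.collected_wells) != combo.r:
                raise TraceError(
                    f"position {pos_index}, radius {sp.radius_index}: collected "
                    f"{len(sp.collected_wells)} wells for an r={combo.r} combination"
                )
            if len(set(sp.collected_wells)) != len(sp.collected_wells):
                raise TraceError(
                    f"position {pos_index}, radius {sp.radius_index}: "
                    "a well is collected twice in one pass"
                )
            if set(sp.collected_wells) != set(combo.wells):
                raise TraceError(
                    f"position {pos_index}, radius {sp.radius_index}: collected "
                    "wells do not match the dispensed combination"
                )
            seen_rings: set[int] = set()
            for w in sp.collected_wells:
                actual = wellmap.well(w.ring, w.radius)
                if actual != w or actual.is_empty:
                    raise TraceError(
                        f"position {pos_index}, radius {sp.radius_index}: well "
                        f"({w.ring}, {w.radius}) is empty or differs from the map"
                    )
                if w.ring not in seen_rings:
                    seen_rings.add(w.ring)
                    if position.slot(w.ring, w.radius, n_radii) != sp.radius_index:
                        raise TraceError(
                            f"position {pos_index}, radius {sp.radius_index}: first "
                            f"well of ring {w.ring} not aligned with the outlet line"
                        )
            if combo in dispensed:
                raise TraceError(f"combination dispensed twice: {combo}")
            dispensed.add(combo)
            n_passes += 1
            n_droplets += combo.r
            n_ring_steps += sp.ring_steps
    ledger_set = set(plan.ledger)
    if ledger_set != dispensed:
        missing = ledger_set - dispensed
        extra = dispensed - ledger_set
        raise TraceError(
            f"ledger mismatch: {len(missing)} ledger entries never dispensed, "
            f"{len(extra)} dispensed combinations missing from the ledger"
        )
    return ExecutionTrace(
        n_positions=len(plan.positions),
        n_passes=n_passes,
        n_droplets=n_droplets,
        n_ring_steps=n_ring_steps,
        elapsed_days=screen_time_days(
            len(plan.positions), cfg.seconds_per_position
        ),
    )


def position_efficiency(plan: DispensingPlan) -> float:
    """Combinations dispensed per rotor position.

    The closed-form ideal is n_radii combinations per position; the greedy
    planner approaches it from below.
    """
    if plan.n_positions == 0:
        raise ValueError("plan has no positions")
    return plan.n_combinations / plan.n_positions
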