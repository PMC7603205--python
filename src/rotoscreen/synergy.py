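"""Synthetic dose-response surfaces, Bliss/Loewe reference models, and the
staged ring-by-ring synergy search.

Single agents follow Hill curves E(d) = emax * d**h / (ec50**h + d**h).
Combination expectations come from either of the two classical null
models:

* **Bliss independence** — probabilistic independence of fractional
  effects, E = 1 - prod(1 - e_i).
* **Loewe additivity** — dose additivity: the combined effect E solves
  sum_i d_i / D_i(E) = 1 where D_i(E) is the dose at which drug i alone
  reaches effect E (the inverse Hill curve).  A sham combination of one
  drug with itself is exactly additive under this model.

Observed combination effects are scored on the three-level scale used in
staged screening: 2 (synergistic) when observed exceeds the reference by
more than a threshold tau, 0 (antagonistic) when it falls short by more
than tau, else 1 (additive).

The search strategy mirrors instrument operation: screen one ring (a
single dilution level of every drug) circumferentially; when a score-2 set
appears, focus on the implicated drugs and test all of their non-redundant
dilution combinations; otherwise move to the next ring.  Counters report
combinations, droplets (r per combination), rotor positions (n_radii
combinations per position, rounded up per stage) and modelled screen time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .combinatorics import SECONDS_PER_DAY, binom
from .geometry import WellMap

__all__ = [
    "HillCurve",
    "ResponseSurface",
    "InteractionScore",
    "SearchResult",
    "SurfaceModelError",
    "bliss_expected",
    "loewe_expected",
    "score_interaction",
    "generate_surface",
    "ring_search",
]


class SurfaceModelError(RuntimeError):
    """A reference-model computation is ill-posed for the given curves."""


@dataclass(frozen=True)
class HillCurve:
    """Single-agent sigmoidal dose-response.

    emax in (0, 1] is the asymptotic effect fraction, ec50 > 0 the
    half-maximal dose (arbitrary concentration units), hill > 0 the slope.
    Effect at dose 0 is 0 and the curve is monotone nondecreasing.
    """

    emax: float
    ec50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.emax <= 1.0):
            raise ValueError(f"emax must be in (0, 1], got {self.emax}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")

    def effect(self, dose: float) -> float:
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        if dose == 0:
            return 0.0
        x = (dose / self.ec50) ** self.hill
        return self.emax * x / (1.0 + x)

    def inverse_dose(self, effect: float) -> float:
        """Dose producing *effect*; defined for 0 <= effect < emax."""
        if not (0.0 <= effect < self.emax):
            raise ValueError(
                f"effect {effect} outside [0, emax={self.emax}) is unreachable"
            )
        if effect == 0:
            return 0.0
        return self.ec50 * (effect / (self.emax - effect)) ** (1.0 / self.hill)


def bliss_expected(effects) -> float:
    """Bliss-independence expectation 1 - prod(1 - e_i) of fractional effects."""
    effects = list(effects)
    for e in effects:
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"effect {e} outside [0, 1]")
    return 1.0 - math.prod(1.0 - e for e in effects)


def loewe_expected(doses, curves, tol: float = 1e-9) -> float:
    """Loewe-additive expected effect of a dose vector.

    Solves sum_i d_i / D_i(E) = 1 for E on [0, min emax) by bracketed
    root-finding.  Doses of zero drop out; a single nonzero dose returns
    that drug's Hill effect exactly.
    """
    pairs = [(d, c) for d, c in zip(doses, curves, strict=True) if d > 0]
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if not pairs:
        return 0.0
    if len(pairs) == 1:
        d, c = pairs[0]
        return c.effect(d)
    e_cap = min(c.emax for _, c in pairs)

    def excess_dose(effect: float) -> float:
        return sum(d / c.inverse_dose(effect) for d, c in pairs) - 1.0

    hi = e_cap * (1.0 - 1e-12)
    if excess_dose(hi) > 0:
        raise SurfaceModelError(
            "Loewe equation has no solution below the shared effect ceiling "
            f"(min emax = {e_cap}); the dose vector saturates every curve"
        )
    lo = e_cap * 1e-15
    if excess_dose(lo) < 0:  # pragma: no cover - tiny doses only
        return 0.0
    return brentq(excess_dose, lo, hi, xtol=tol)


@dataclass(frozen=True)
class InteractionScore:
    """Three-level interaction call: 2 synergy, 1 additivity, 0 antagonism."""

    value: int
    excess: float  # observed - expected


def score_interaction(observed: float, expected: float, tau: float) -> InteractionScore:
    """Score an observed combination effect against its reference expectation."""
    if tau <= 0:
        raise ValueError(f"threshold tau must be > 0, got {tau}")
    for name, v in (("observed", observed), ("expected", expected)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} effect {v} outside [0, 1]")
    excess = observed - expected
    if excess > tau:
        value = 2
    elif -excess > tau:
        value = 0
    else:
        value = 1
    return InteractionScore(value=value, excess=excess)


@dataclass(frozen=True)
class ResponseSurface:
    """Synthetic multi-drug response surface.

    ``curves[i]`` is drug i's Hill curve; ``dose_ladder[i][lvl]`` its dose
    at dilution level lvl (level 0 most concentrated).  ``interactions``
    plants deviations: any combination whose drug set contains subset S is
    shifted by the associated strength (positive = synergy).  Noise is
    additive Gaussian on the observed effect, clipped to [0, 1], with a
    draw that depends only on ``seed`` and the queried (drug, level) set,
    so observations are reproducible and order-independent.
    """

    curves: tuple[HillCurve, ...]
    dose_ladder: tuple[tuple[float, ...], ...]
    interactions: tuple[tuple[frozenset[int], float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    reference: str = "bliss"

    def __post_init__(self) -> None:
        if self.reference not in ("bliss", "loewe"):
            raise ValueError(f"unknown reference model {self.reference!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.dose_ladder) != len(self.curves):
            raise ValueError("need one dose ladder per drug")

    @property
    def n_drugs(self) -> int:
        return len(self.curves)

    def dose(self, drug: int, level: int) -> float:
        return self.dose_ladder[drug][level]

    def single_effect(self, drug: int, level: int) -> float:
        return self.curves[drug].effect(self.dose(drug, level))

    def expected_effect(self, members) -> float:
        """Reference (null-model) effect of {(drug, level), ...}."""
        members = sorted(members)
        if self.reference == "bliss":
            return bliss_expected(
                self.single_effect(drug, lvl) for drug, lvl in members
            )
        return loewe_expected(
            [self.dose(drug, lvl) for drug, lvl in members],
            [self.curves[drug] for drug, _ in members],
        )

    def observed_effect(self, members) -> float:
        """Observed effect: reference + planted deviations + noise, in [0, 1]."""
        members = tuple(sorted(members))
        value = self.expected_effect(members)
        drugs = frozenset(drug for drug, _ in members)
        for subset, strength in self.interactions:
            if subset <= drugs:
                value += strength
        if self.noise_sd > 0:
            key = [self.seed] + [x for pair in members for x in pair]
            rng = np.random.default_rng(key)
            value += rng.normal(0.0, self.noise_sd)
        return float(min(1.0, max(0.0, value)))


def generate_surface(
    n_drugs: int,
    n_dilutions: int,
    seed: int = 0,
    interactions=(),
    noise_sd: float = 0.02,
    reference: str = "bliss",
    dilution_factor: float = 10.0,
    top_dose_ec50_multiple: float = 10.0,
    curves=None,
) -> ResponseSurface:
    """Draw a reproducible synthetic surface for ``n_drugs`` drugs.

    Per-drug Hill parameters are sampled from the seed: emax uniform on
    [0.1, 0.4] (weak-to-moderate single agents, the regime where
    combination screening is informative and planted deviations are not
    masked by the effect ceiling), ec50 log-normal around 1, hill uniform
    on [0.8, 2].  The dose ladder is a ``dilution_factor``-fold serial
    dilution from ``top_dose_ec50_multiple`` x ec50 at level 0.  Explicit
    ``curves`` override the sampling.
    """
    rng = np.random.default_rng(seed)
    if curves is None:
        curves = tuple(
            HillCurve(
                emax=float(rng.uniform(0.1, 0.4)),
                ec50=float(rng.lognormal(0.0, 0.5)),
                hill=float(rng.uniform(0.8, 2.0)),
            )
            for _ in range(n_drugs)
        )
    else:
        curves = tuple(curves)
        if len(curves) != n_drugs:
            raise ValueError("need one curve per drug")
    ladder = tuple(
        tuple(
            top_dose_ec50_multiple * c.ec50 / dilution_factor**lvl
            for lvl in range(n_dilutions)
        )
        for c in curves
    )
    return ResponseSurface(
        curves=curves,
        dose_ladder=ladder,
        interactions=tuple((frozenset(s), float(v)) for s, v in interactions),
        noise_sd=noise_sd,
        seed=seed,
        reference=reference,
    )


@dataclass(frozen=True)
class SearchStep:
    """One stage of the staged search: which ring or focus set was tested."""

    kind: str  # "ring" or "focus"
    detail: tuple
    combos_tested: int
    hits: tuple[frozenset[int], ...]


@dataclass
class SearchResult:
    """Outcome and cost accounting of a staged synergy search."""

    found_sets: list[frozenset[int]] = field(default_factory=list)
    combos_tested: int = 0
    droplets_used: int = 0
    positions_used: int = 0
    model_time_days: float = 0.0
    steps: list[SearchStep] = field(default_factory=list)

    def _charge(self, r: int, combos: int, n_radii: int, spp: float) -> None:
        self.combos_tested += combos
        self.droplets_used += r * combos
        positions = -(-combos // n_radii)  # ceil
        self.positions_used += positions
        self.model_time_days += positions * spp / SECONDS_PER_DAY


def ring_search(
    wellmap: WellMap,
    surface: ResponseSurface,
    strategy: str = "single-dilution-first",
    tau: float = 0.1,
) -> SearchResult:
    """Staged ring-by-ring synergy search on a canonical dilution layout.

    Step 1 scores every circumferential r-combination on ring 0 (the most
    concentrated dilution).  Each score-2 drug set triggers *focus mode*:
    all non-redundant dilution combinations of the implicated drugs are
    tested and the set is recorded if confirmed.  Under
    ``"single-dilution-first"`` the search stops after the first ring that
    produced a confirmed hit; under ``"exhaustive-ml"`` it always visits
    every ring.  Every tested combination is charged r droplets and
    positions at n_radii combinations per position.
    """
    if strategy not in ("single-dilution-first", "exhaustive-ml"):
        raise ValueError(f"unknown strategy {strategy!r}")
    cfg = wellmap.config
    if not wellmap.is_canonical_dilution_layout():
        raise ValueError("ring search requires the canonical dilution layout")
    if surface.n_drugs != cfg.n_radii:
        raise ValueError(
            f"surface covers {surface.n_drugs} drugs, layout has {cfg.n_radii}"
        )
    r = cfg.combo_order
    result = SearchResult()
    focused: set[frozenset[int]] = set()

    for ring in range(cfg.n_rings):
        hits: list[frozenset[int]] = []
        n_ring_combos = binom(cfg.n_radii, r)
        for drug_tuple in itertools.combinations(range(cfg.n_radii), r):
            members = [(drug, ring) for drug in drug_tuple]
            score = score_interaction(
                surface.observed_effect(members),
                surface.expected_effect(members),
                tau,
            )
            if score.value == 2:
                hits.append(frozenset(drug_tuple))
        result._charge(r, n_ring_combos, cfg.n_radii, cfg.seconds_per_position)
        result.steps.append(
            SearchStep(kind="ring", detail=(ring,), combos_tested=n_ring_combos,
                       hits=tuple(hits))
        )
        confirmed_this_ring = False
        for drug_set in hits:
            if drug_set in focused:
                continue
            focused.add(drug_set)
            confirmed = _focus(wellmap, surface, drug_set, tau, result)
            if confirmed:
                result.found_sets.append(drug_set)
                confirmed_this_ring = True
        if strategy == "single-dilution-first" and confirmed_this_ring:
            break
    return result


def _focus(
    wellmap: WellMap,
    surface: ResponseSurface,
    drug_set: frozenset[int],
    tau: float,
    result: SearchResult,
) -> bool:
    """Test every non-redundant dilution combination of *drug_set*.

    Returns True when any of them scores 2 (the hit is confirmed across
    the dilution grid).
    """
    cfg = wellmap.config
    drugs = sorted(drug_set)
    levels = range(cfg.n_dilutions)
    confirmed_members: list[tuple] = []
    n_tested = 0
    for level_choice in itertools.product(levels, repeat=len(drugs)):
        members = list(zip(drugs, level_choice))
        n_tested += 1
        score = score_interaction(
            surface.observed_effect(members),
            surface.expected_effect(members),
            tau,
        )
        if score.value == 2:
            confirmed_members.append(tuple(members))
    result._charge(len(drugs), n_tested, cfg.n_radii, cfg.seconds_per_position)
    result.steps.append(
        SearchStep(
            kind="focus",
            detail=tuple(drugs),
            combos_tested=n_tested,
            hits=(drug_set,) if confirmed_members else (),
        )
    )
    return bool(confirmed_members)
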