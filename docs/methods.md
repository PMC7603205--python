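# Methods

## Instrument model

The dispenser is modelled as `N_ring` concentric rings, each with
`N_rad` wells at a common angular pitch (well pitch = 360°/`N_rad`), so
wells also align along `N_rad` radial lines. Rings rotate independently;
a shuttle travels along a radial line and collects one droplet from each
well it aligns with, bypassing wells it does not need. An `r`-droplet
combination is an unordered set of `r` distinct wells; dispensing order is
a scheduling concern and never part of a combination's identity.

Indices are 0-based throughout (ring 0 innermost, radii clockwise);
dilution level 0 is the most concentrated stock and levels increase with
dilution. The canonical *dilution layout* places drug `j` at dilution
level `i` in well `(ring i, radius j)`: one drug per radius, one dilution
per ring. Cell/organoid wells are a separate content variant that never
participates in drug-redundancy logic.

## Counting

All counts are exact integers (Python arbitrary precision); floats appear
only in time models.

* Full screen: `nCr = C(N_ring·N_rad, r)` subsets, `N_p = nCr / N_rad`
  positions (reported as an exact rational when the division is not
  integral).
* Dilution screen (restriction `N_ring = N_dil = r`): the
  dilution-reduced count is the closed form
  `nC'r = r · N_rad^(r−1) · (N_rad − r + 1)`,
  which reduces to `r^r` when `N_rad = r`. The formula is an empirical
  observation, not a proven identity; this package treats it the same way
  and validates it against all 27 published reference configurations plus
  a brute-force enumerator (below).
* Circumferential decomposition: combinations whose wells share one ring
  number `N_c' = r · C(N_rad, r)` (each of the `r` rings contributes its
  single-dilution subsets); the radial/mixed remainder is
  `N_r' = nC'r − N_c'`. Neither formula is printed in the source table;
  both were reconstructed and verified cell-by-cell against all 27 rows.
* Positions with dilution: `N_p' = nC'r / N_rad`, provably integral
  (`nC'r` factors as `N_rad · [r · N_rad^(r−2) · (N_rad − r + 1)]` for
  `r ≥ 2`).

### Enumeration semantics and the bracketing discrepancy

The enumerator defines *redundant* purely as "some drug id appears in two
or more member wells" (two different drugs at the same dilution are fine —
they share a ring). This set-theoretic filter equals the closed form
exactly for `r = 2` (both give `2·N_rad·(N_rad−1)`) and for `N_rad = r`
(both give `r^r`), which the test suite verifies exhaustively at small
scale. For `N_rad > r ≥ 3` the filter counts **more** than the closed form
(108 vs 96 at `r = 3, N_rad = 4`) while the one-ring-only count is smaller;
whatever geometric reachability rule the closed form encodes between those
brackets is not recoverable from its published statement. The package
therefore always reports both numbers with an explicit agreement flag and
never reconciles them silently. Enumeration is streamed in deterministic
lexicographic order behind a configurable size bound (default 10⁶ subsets)
so the oracle cannot be invoked at commercial scale by accident.

### Reference-table defects

Three printed cells of the 27-row reference table disagree with the
models; the package asserts the model values and flags the cells:
`(r=4, N_rad=40)` radial count printed malformed ("91,06440" for
9,106,440); `(r=3, N_rad=48)` time printed 0.5 days where 6624 positions
at 10 s give 0.767; `(r=2, N_rad=3)` time printed as a truncation
(0.0004 for 0.000463). Two staged-screen time cells
(`(2,3)`, `(4,6)`) are likewise truncations rather than roundings. The
companion prose figure of "414,730 positions" for the commercial build is
treated as a typo for the table's 414,720 = `nC'r/48`.

## Time models

* Full/dilution screen: `days = positions × t_pos / 86 400` with
  `t_pos = 10 s` per rotor position by default. The constant is calibrated
  from the reference table itself (e.g. 236,800 positions ↔ 27.4 days)
  and reproduces 25 of the 27 printed times at their printed precision
  (half-up rounding); it is configurable. Well-refill time is out of
  scope beyond this constant.
* Single-ring staged screen: `C(N_rad, r) · r` droplets dispensed at 192
  droplets per position (the full build's well count — the parallelism the
  staged model assumes; configurable because it is not stated anywhere),
  then the same 10 s/position conversion. Note the droplet count equals
  `N_c'`/ring-count trivially; the model reproduces the printed staged
  times to 4 decimals for the anchor configurations.

## Scheduling

A *position* is a tuple of per-ring circumferential offsets (well-pitch
units, reduced mod `N_rad`); with offset `o_i`, well `(i, j)` sits under
radial line `(j + o_i) mod N_rad`. Up to `N_rad` shuttle passes execute
per position, one per outlet line.

The greedy planner exploits rotational symmetry: adding `t` to every
radius index of a combination yields a sibling dispensed at outlet line
`k + t` of the *same* position. Targets are grouped into rotation orbits
(orbit representative = lexicographically smallest rotation) and each
orbit becomes one position; offsets align the representative's first well
per ring with line 0. Combinations taking several wells from one ring are
handled by incremental ring steps between collections within a pass
(counted in the trace, not as new positions) — the closed forms remain the
authoritative position accounting, and the planner makes no optimality
claim. Guarantees, enforced by replay (`simulate`): complete,
duplicate-free ledger; `r` droplets per combination; first-well-per-ring
alignment at every pass; position count within 2× of the parallelism
bound `ceil(#targets/N_rad)` on all tested configurations (e.g. 30
positions for the 84-combination nine-well full screen against an ideal
of 28; 11 for its 27 meaningful combinations against an ideal of 9).
Plans are deterministic given the well map and target order.

## Synergy search

Single agents follow Hill curves `E(d) = emax·d^h/(ec50^h + d^h)`.
Null models: Bliss independence `1 − Π(1 − e_i)`, and Loewe additivity
solving `Σ d_i/D_i(E) = 1` by bracketed Brent root-finding (tolerance
1e−9) on `[0, min emax)`, with single-drug vectors short-circuited to the
exact Hill effect. The sham-combination identity (splitting one dose
across copies of the same curve) holds to 1e−6 and is property-tested.

Scoring is the three-level scale with a single threshold `τ` (default
0.1): 2 if observed − expected > τ, 0 if expected − observed > τ, else 1.
No multiple-testing correction is applied — a deliberate mirror of the
screening procedure being modelled, and a known limitation.

The staged search tests ring 0 (every drug at its most concentrated
dilution) circumferentially; each score-2 drug set triggers *focus mode* —
all `N_dil^r` non-redundant dilution combinations of the implicated drugs
are tested — and the `single-dilution-first` strategy stops after the
first ring that confirms a hit, while `exhaustive-ml` always visits all
rings. Costs are charged as `r` droplets per combination and
`ceil(combos/N_rad)` positions per stage, converted to days via the
10 s/position model.

## Synthetic surface generator

`generate_surface` draws per-drug Hill parameters from one seed:
`emax ~ U(0.1, 0.4)`, `ec50 ~ LogNormal(0, 0.5)`, `hill ~ U(0.8, 2)`; the
dose ladder is a 10-fold serial dilution from `10 × ec50` at level 0.
The low-emax default emulates weak-to-moderate single agents — the regime
where combination screening is informative — and keeps the combined null
expectation away from the effect ceiling, so a planted deviation is not
destroyed by clipping to [0, 1]; dilution ratio and top dose are
configurable. Planted interactions shift the observed effect of every
combination whose drug set contains the planted subset by a fixed
strength (positive = synergy, negative = antagonism), then Gaussian noise
(default sd 0.02) is added and the result clipped to [0, 1]. The noise
draw is keyed on the seed plus the queried (drug, level) set, so
observations are reproducible and independent of query order.

What the generator does *not* emulate: per-replicate biological
variability and plate effects, dose-dependent interaction strength
(planted shifts are constant across the dilution grid), receptor-level
mechanism, or readout noise structure. Passing recovery tests therefore
show that the staged search logic is correct under its own assumptions,
not that real organoid screens will behave this way.

The recovery benchmark runs 100 seeded surfaces on an 8-drug, 3-dilution,
`r = 3` layout with one planted synergistic triple (strength 0.3, noise
sd 0.02, `τ = 0.1`) and requires the planted set found in ≥ 95 runs while
always testing fewer combinations than the 1152-combination exhaustive
dilution-reduced screen. The small layout keeps the whole suite fast; the
search logic is scale-free.

## Numerical choices

Counts: exact integer arithmetic only. Printed-precision comparisons use
half-up rounding (the reference table's convention, except the truncated
cells noted above). Loewe inversion: Brent on a bracket excluding the
singular endpoints; degenerate dose vectors that saturate every curve
raise a model error rather than returning the ceiling. Ties in the
planner (collection order) are broken by ring index then clockwise step
count. All randomness flows through `numpy.random.default_rng` seeded
explicitly.
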