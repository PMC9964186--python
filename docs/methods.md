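# Methods

This note records the model as implemented, the conventions chosen where
the physics leaves freedom, the numerical choices, and what the test
conditions do and do not probe. Nothing here states a number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Lattice model

Each biological cell is the set of lattice pixels carrying its id; pixel
ownership evolves by elementary copy attempts (a random site copies its id
into a random 4-neighbour) accepted by the Metropolis rule at fluctuation
temperature `T` (default 50, an energy scale that produces both soft,
fluctuating shapes and hard, quasi-polygonal shapes across the parameter
ranges of interest). The energy has three terms per configuration:

* **Area compressibility** `λ_area (A − A0)²` — quadratic penalty for
  deviating from the target area `A0` (pixels; default 100, i.e. cells
  initialised as 10×10 squares).
* **Perimeter contractility** `λ_cont L²` — cortical actomyosin tension;
  `L` counts 4-neighbour links from owned to non-owned pixels.
* **Contact adhesion** — each unordered boundary link between two distinct
  cells costs the arithmetic mean of their adhesion coefficients
  (`λ_adh ≤ 0`, so cells prefer shared boundary); links against wall or
  barrier pixels cost zero.

Conventions chosen where the model definition leaves freedom, all of which
are consequential for quantitative (not qualitative) outcomes:

* **Cross-type adhesion** is the arithmetic mean of the two types'
  coefficients: symmetric, reduces to the shared value for same-type
  contacts and to zero against walls.
* **Neighbourhood order 1** (von Neumann) for both copy candidates and
  boundary-link counting. This is the simplest self-consistent convention;
  it makes the perimeter anisotropic (a diagonal edge is "longer" than an
  axis-aligned one), which slightly biases preferred cell orientations.
* **Perimeter = boundary links** (not boundary pixels), which makes `L`
  locally updatable and the incremental `ΔE` exact.
* **No connectivity constraint**: cells may transiently fragment; fragments
  share the parent's id and parameters.
* **Attempt direction**: pick source site, then target neighbour, copy the
  source id into the target.
* **Coordinates**: row-major 0-based grids, x = column = invasion axis; no
  periodic boundaries — every lattice is enclosed by a 1-pixel wall ring,
  which also removes bounds checks from the inner loop.
* **RNG**: one seeded `numpy` generator per run. Per sweep it is consumed
  in one documented block order (site picks, neighbour picks, acceptance
  uniforms), then turnover consumes one uniform per live cell (deaths) and
  one per eligible cell (divisions) in ascending cell-id order, then one
  orientation draw per executed division. Identical seeds therefore give
  bit-identical grids, time series, and event logs.

## Turnover

Once per MCS, after the sweep, in fixed order: deaths, divisions, purge.

* **Death**: each live cell independently with its type's probability `M`.
  The corpse keeps its id and type but switches to `λ_cont = 0`,
  `λ_adh = 0`, `A0 = 0`, `λ_area = 200`; the steep area penalty makes every
  shrinking copy strongly downhill, so corpses are extruded within tens of
  MCS and their registry entry is purged when the area reaches zero. The
  value 200 is large enough that corpses do not accumulate at the death
  rates considered (`M ≤ 0.003` keeps the dead fraction at a few percent,
  as the acceptance run shows).
* **Division**: only live cells at or above their target area are eligible
  (crowding suppresses division); each eligible cell divides with its
  type's probability `B`. The cell is split by a straight line through its
  area centroid at a uniformly random orientation — orientation-unbiased
  and area-balanced up to the discretisation of the cut; if a draw leaves
  one side empty it is redrawn (≤ 8 times), then a pixel-count median split
  along the longer axis is used. Daughters inherit the type's parameters
  and target area.
* Eligibility is evaluated once per MCS, after that MCS's deaths, so a cell
  cannot both die and divide in the same step.

## Protocols

* **Homogeneous equilibrium**: a fully tiled single-type layer runs under
  sweeps + turnover until the total count is stationary — two consecutive
  sliding windows (default 500 MCS) agree within 2% — then continues for a
  1000-MCS averaging window. Statistics are reported as mean ± SD over that
  window. Caps: 8000 MCS, after which the result is flagged non-stationary.
* **Invasion**: stage 1 (default 500 MCS) runs sweeps only; stage 2 runs
  turnover behind the barrier until each type's total count is stationary
  by the same windowed criterion, assessed per side independently (cap
  5000 MCS); stage 3 releases the barrier and runs until every cell of one
  type is gone (cap 50 000 MCS; hitting the cap flags the result
  incomplete). Stage durations are configurable; the defaults were chosen
  so that shape relaxation and density equilibration visibly plateau on the
  domains used here.
* **Barrier release**: the strip's pixels are handed to a placeholder cell
  carrying the dead-cell switch, so neighbours claim the strip through
  ordinary dynamics within a few MCS — no ad-hoc pixel assignment that
  could bias the initial front. The placeholder is excluded from per-type
  counts and purged like any corpse.

## Measurements

* **Units**: the domain width perpendicular to the invasion axis is the
  length unit (`L = 1`); densities are live cells per squared width, speeds
  in widths per MCS. Only live cells enter densities (corpses are
  transient).
* **Invasion speed** `v = slope/(L·ρ)`: the slope is the OLS growth rate of
  the invading type's total count, fitted from barrier release to 80% of
  the loser's extinction time (auto-window, overridable); `ρ` is the
  invader's own stationary density measured behind the barrier in stage 2.
* **Winner calls**: outright if one type's cells all vanish; otherwise OLS
  trends of both types' live counts, thinned to every 25th MCS to tame
  autocorrelation, both significant at α = 0.01 and of opposite sign.
* **Crowding bound**: for a neighbour of a vacated site to reach the
  division threshold, the mean live area must satisfy
  `A ≥ A0·Nc/(1+Nc)` with `Nc` the coordination number of a dead cell
  (≈ 6 for near-hexagonal packing), bounding the live count by
  `free_area·(1+Nc)/(A0·Nc)`. The implementation returns this expression
  exactly; note that rounding the coefficient `Nc/(1+Nc)` to 5/6 (as is
  sometimes done for a round bound of 1.2× the neutral count) gives a
  slightly looser bound — 480 instead of 466.7 for a 200×200 domain at
  `A0 = 100` — and the looser value is the appropriate comparison constant
  for the stationary live count.

## Reaction–diffusion theory

The canonical pulled-front speed is `v = 2·sqrt(D·(b1·m2 − b2·m1)/b2)`
(species 1 dominant): the linear-spreading speed obtained by linearising
the invader's equation about the invaded state `(0, 1 − m2/b2)`. The
equal-mortality and equal-birth specialisations are *derived from this
form* — `2·sqrt(D·m·(b1−b2)/b2)` and `2·sqrt(D·(m2−m1))` — because the
abbreviated forms are typeset ambiguously in places (square-root placement
and the factor 2); the solver cross-validation in the test suite confirms
the canonical form, including the factor 2, to within a few percent.

Solver: explicit central-difference (FTCS) integration with no-flux
boundaries, `dt ≤ 0.4·dx²/(2D)` and additionally `dt ≤ 0.2/max(rates)`
(relevant at small `D`), grids of ≥ 2000 points. At `dx = 0.5` the measured
front speeds sit ~3–5% below the closed form (discretisation plus the slow
algebraic convergence of pulled fronts); at `dx = 0.25` they agree within
~1.5%, which is the grid used for quantitative cross-checks. The front is
located as the level crossing of the invader's density at half its carrying
capacity — standard and insensitive to tail shape — and the speed is the
OLS slope of that position over the final third of the run, dropping any
times at which the front sits within two grid spacings of a boundary.

Note that the effective motility of lattice cells has no simple
correspondence to the PDE's diffusion coefficient `D`; the theory is used
for functional forms and orderings, not for absolute speed predictions, and
no fit of `D` to the lattice model is attempted.

## Scaled-down study conditions

The qualitative-direction and speed-trend studies run on a 140×80-pixel
interior (56 cells of 10×10 per side, plus a 2-pixel barrier strip) with
shortened stages (stage 1 = 300 MCS, stationarity window 300 MCS, stage-3
cap 9000 MCS), five seeds per configuration. These domains hold ~100–150
cells: large enough that front propagation dominates single-cell noise, and
small enough to keep full sweeps cheap. The homogeneous-layer reference
study runs at full 200×200 scale.

What the synthetic conditions do *not* probe: real epithelia regulate
division and death through signalling and substrate interactions (here both
are memoryless per-MCS coin flips), adhesion is uniform per type rather
than molecularly heterogeneous, and the lattice anisotropy of the order-1
neighbourhood has no biological counterpart. Passing tests therefore show
that the *mechanisms* (crowding-gated division, corpse-extrusion-mediated
competition, pulled-front kinematics) behave as designed, not that any
specific tissue is quantitatively reproduced.

## Numerical details and degenerate inputs

* Energies are floats; equality assertions use absolute tolerance 1e-9.
* The incremental `ΔE` of a copy touches only the four links incident to
  the target pixel plus the two affected cells' area/perimeter terms; the
  test suite asserts exact agreement with full recomputation on random
  mixed-viability lattices.
* Cells of fewer than 2 pixels skip division with a logged warning; a live
  cell reaching zero area raises an integrity error (impossible unless the
  state is corrupted); removing a cell with pixels still on the grid is an
  error.
* `total_energy` recounts areas and perimeters from the grid and raises on
  any disagreement with the registry rather than returning a silently wrong
  value.

## Known limitations

* Order-1 neighbourhood makes interfacial energies anisotropic; hexagonal
  packings are only approximate.
* No connectivity constraint: at high temperature or extreme parameters
  cells can fragment persistently.
* The invasion-speed estimator assumes a single straight front spanning the
  domain; it is not meaningful for enclosed islands or multi-front
  geometries.
* Front-interface roughness statistics are out of scope.
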