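# epinvade

Cellular Potts simulations of competitive invasion in epithelial
monolayers, together with the two-species reaction–diffusion front theory
used to interpret the measured invasion speeds.

## The scientific problem

In cell competition, two epithelial cell populations that meet at an
interface compete for space: the winner type invades and eventually
eliminates the loser — the mechanism by which transformed (pre-cancerous)
cells can expand into normal tissue, or by which healthy tissue eliminates
aberrant cells. `epinvade` asks how the *speed* of that invasion depends on
the cells' division and death rates and on their mechanical properties
(cortical contractility, area compressibility, cell–cell adhesion).

## The model

Cells live on a 2-D square lattice; each cell is the set of pixels carrying
its integer index. Configurations evolve by Metropolis pixel-copy dynamics
that stochastically minimise the energy

```
E = Σ_α λ_area (A_α − A0)²  +  Σ_α λ_cont L_α²  +  Σ_links φ(α_i, α_j)
```

where `A_α` is the cell's area, `L_α` its perimeter (4-neighbour boundary
links), and `φ` the per-link contact energy (mean of the two cells'
adhesion coefficients `λ_adh ≤ 0`; zero against walls). A copy attempt with
energy change `ΔE` is accepted with probability `min(1, exp(−ΔE/T))`; one
Monte Carlo step (MCS) is as many attempts as there are free pixels.

On top of the mechanics, once per MCS every live cell dies with probability
`M`, and every live cell that has reached its target area divides with
probability `B` (split by a random straight cut through its centroid). A
dying cell's parameters switch to `λ_cont = 0, λ_adh = 0, A0 = 0,
λ_area = 200`, so it shrinks and is extruded by its neighbours.

Two-type competition runs in three stages: (1) mechanical relaxation behind
a barrier, (2) turnover on, each side reaches its own homeostatic density,
(3) the barrier is released and the types compete until one disappears.
The invasion speed is `v = (ΔN/Δt) / (L·ρ)` — the growth slope of the
invading type's cell count divided by its equilibrium density, with the
domain width perpendicular to the invasion as the length unit `L = 1`.

The companion continuum model is a two-species logistic-competition PDE
whose pulled (Fisher–Kolmogorov) front moves at
`v = 2·sqrt(D·(b1·m2 − b2·m1)/b2)` when species 1 dominates
(`b1/m1 > b2/m2`); `epinvade.reaction_diffusion` provides the steady
states, their linear stability, the closed-form speeds, and a 1-D solver
for cross-validation.

## A worked example

```
$ python examples/invasion_division_rates.py
barrier removed at MCS 1260; type 2 went extinct
winner: type 1
growth slope: 0.0131 cells/MCS (stderr 3.4e-05, fit window (1261, 6586))
invader equilibrium density: 73.9 cells per squared width
invasion speed: 1.77e-04 widths/MCS
```

Two mechanically identical types on a 140×80 domain, type 1 dividing at
`B = 0.9` against `B = 0.1`: after barrier release type 1's cell count
grows linearly (a constant-speed front) until type 2 is extinct; dividing
the slope by the invader's own equilibrium density (73.9 cells per squared
perpendicular width) gives the front speed in widths per MCS.

The other scripts in `examples/` each demonstrate one capability:
`energy_basics.py` (hand-checkable Hamiltonian values),
`homogeneous_equilibrium.py` (homeostatic density of a single-type layer
against the crowding bound), and `rd_front_speed.py` (closed-form vs
numerical front speed of the continuum model).

The same protocols are available from the shell:

```
epinvade equilibrium --seed 1 --out-dir out/          # homogeneous layer
epinvade invasion --config my_run.yaml --out-dir out/ # three-stage protocol
epinvade rdfront --b1 2 --b2 1 --m1 0.25 --m2 0.5     # PDE front speed
epinvade analyze --timeseries out/timeseries.csv      # recompute summaries
```

Each run writes a time-series CSV (`mcs, type_id, live, dead, stage`), an
event log, plain-text PGM snapshots, and a manifest (config + seed +
output checksums); identical seeds reproduce bit-identical outputs.

## Layout

```
src/epinvade/
  cpm_core.py            lattice state, Hamiltonian, Metropolis sweeps
  _kernels.py            numba inner loops
  turnover.py            stochastic division, death, extrusion, purge
  experiments.py         monolayer builders, equilibrium + invasion protocols
  measurements.py        densities, growth fits, invasion speed, crowding bound
  reaction_diffusion.py  two-species PDE: steady states, stability, fronts
  cli_io.py              configs, manifests, writers, test fixtures
  cli.py                 `epinvade` command-line front end
docs/methods.md          model assumptions, conventions, numerical choices
examples/                one narrative script per capability
```
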