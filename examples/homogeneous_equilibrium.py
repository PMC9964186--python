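"""Homeostatic equilibrium of a single-type epithelial layer (scaled down).

Tiles a 100x100 interior with 100 soft cells (lambda_area=10,
lambda_cont=0.5), switches on stochastic division (B=0.03) and death
(M=0.001), and runs until the total cell count is stationary. The
stationary live count exceeds the neutral count (cells are slightly
compressed, so death events gate division) but stays below the
coordination-number crowding bound.
"""

from epinvade import CellTypeParams, ExperimentConfig, crowding_bound
from epinvade.experiments import run_homogeneous_equilibrium, stationary_stats
from epinvade.measurements import dead_fraction

cfg = ExperimentConfig(
    width=100, height=100,
    cell_types=(CellTypeParams(type_id=1, lambda_area=10.0, lambda_cont=0.5,
                               lambda_adh=-10.0, target_area=100.0,
                               birth_prob=0.03, death_prob=0.001),),
    max_mcs=3000, seed=42)

result = run_homogeneous_equilibrium(cfg)
stats = stationary_stats(result)
frac = dead_fraction(result.series, result.stationary_window())
bound = crowding_bound(cfg.width * cfg.height, 100.0, 6.0)

print(f"stationary from MCS {result.stationary_start} "
      f"(window {result.stationary_window()})")
print(f"live  cells: {stats['live_mean']:.1f} +/- {stats['live_sd']:.1f} "
      f"(started at 100, crowding bound {bound:.0f})")
print(f"dead  cells: {stats['dead_mean']:.1f} +/- {stats['dead_sd']:.1f} "
      f"({100 * frac:.1f}% of the layer)")
print(f"total cells: {stats['total_mean']:.1f} +/- {stats['total_sd']:.1f}")
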