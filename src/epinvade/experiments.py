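"""Monolayer construction and the two simulation protocols.

``run_homogeneous_equilibrium`` evolves a single-type layer under sweeps and
turnover until the total cell count is stationary, then keeps averaging for
a measurement window (homeostatic-equilibrium study).

``run_invasion`` runs the three-stage competition protocol: (1) mechanical
relaxation of both cell types with turnover off and a barrier separating
them; (2) turnover on, each side equilibrates its own density behind the
barrier; (3) the barrier is removed and the types compete until one
disappears (or a step cap is hit). The barrier strip is released by handing
its pixels to a shrinking placeholder (the dead-cell parameter switch), so
neighbouring cells claim the strip through ordinary dynamics within a few
MCS rather than by ad-hoc assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cpm_core import (CellTypeParams, LatticeState, PottsConfig, WALL,
                       mcs_sweep)
from .measurements import TimeSeries, stationary_onset
from .turnover import TurnoverEventLog, apply_turnover

#: type_id stamped on the barrier-remnant placeholder cell.
BARRIER_REMNANT_TYPE = 0


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Geometry, cell types, schedule, and seed of one simulation.

    ``width``/``height`` is the cell-bearing interior in pixels (walls and
    the barrier strip are added around/between it). For two-type runs the
    interior is split at ``barrier_column`` (default: the middle), the left
    part tiled with the first type and the right with the second, and a
    ``barrier_width``-pixel wall-like strip inserted between them.
    """

    width: int = 200
    height: int = 200
    cell_types: Tuple[CellTypeParams, ...] = (
        CellTypeParams(type_id=1, lambda_area=10.0, lambda_cont=0.5,
                       lambda_adh=-10.0, target_area=100.0,
                       birth_prob=0.03, death_prob=0.001),
    )
    initial_cell_side: int = 10
    temperature: float = 50.0
    seed: int = 0
    # homogeneous-equilibrium schedule
    max_mcs: int = 8000
    stat_window: int = 500
    stat_tol: float = 0.02
    min_stationary_mcs: int = 1000
    measure_mcs: int = 1000
    # invasion schedule
    stage1_mcs: int = 500
    stage2_max_mcs: int = 5000
    stage3_max_mcs: int = 50000
    barrier_column: Optional[int] = None
    barrier_width: int = 2
    snapshot_every: int = 0

    def __post_init__(self) -> None:
        side = self.initial_cell_side
        if side <= 0:
            raise ConfigError("initial_cell_side must be positive")
        if self.width % side or self.height % side:
            raise ConfigError("domain dimensions must be multiples of the initial cell side")
        if not self.cell_types:
            raise ConfigError("at least one cell type is required")
        tids = [t.type_id for t in self.cell_types]
        if len(set(tids)) != len(tids):
            raise ConfigError("cell type ids must be unique")
        for v, name in ((self.stage1_mcs, "stage1_mcs"),
                        (self.stage2_max_mcs, "stage2_max_mcs"),
                        (self.stage3_max_mcs, "stage3_max_mcs"),
                        (self.max_mcs, "max_mcs"),
                        (self.stat_window, "stat_window")):
            if v <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.cell_types) == 2:
            col = self.width // 2 if self.barrier_column is None else self.barrier_column
            if col % side or (self.width - col) % side or not (0 < col < self.width):
                raise ConfigError(
                    "barrier_column must split the interior into halves tileable "
                    "by the initial cell side")
        if self.barrier_width <= 0:
            raise ConfigError("barrier_width must be positive")

    @property
    def split_column(self) -> int:
        return self.width // 2 if self.barrier_column is None else self.barrier_column


@dataclass
class EquilibriumResult:
    series: TimeSeries
    lattice: LatticeState
    config: ExperimentConfig
    stationary: bool
    stationary_start: Optional[int]
    events: TurnoverEventLog

    def stationary_window(self) -> Tuple[int, int]:
        """The averaging window: stationarity onset to the end of the run."""
        lo = self.stationary_start if self.stationary_start is not None else int(
            self.series.mcs[-1] - self.config.measure_mcs)
        return max(lo, 0), int(self.series.mcs[-1])


@dataclass
class InvasionResult:
    series: TimeSeries
    lattice: LatticeState
    config: ExperimentConfig
    events: TurnoverEventLog
    barrier_removed_mcs: int
    extinct_type: Optional[int]
    complete: bool
    snapshots: List[Tuple[int, np.ndarray]] = field(default_factory=list)


# --------------------------------------------------------------------------- #
# builders


def _tile(owner: np.ndarray, r0: int, c0: int, rows: int, cols: int,
          side: int, first_id: int) -> int:
    cid = first_id
    for br in range(rows):
        for bc in range(cols):
            r = r0 + br * side
            c = c0 + bc * side
            owner[r:r + side, c:c + side] = cid
            cid += 1
    return cid


def build_monolayer(config: ExperimentConfig) -> LatticeState:
    """Square-tiled single-type monolayer surrounded by a one-pixel wall ring.

    Every cell starts as a side x side square at its target area; e.g. a
    200x200 interior at side 10 starts with exactly 400 cells of area 100.
    """
    if len(config.cell_types) != 1:
        raise ConfigError("build_monolayer requires exactly one cell type")
    side = config.initial_cell_side
    h, w = config.height + 2, config.width + 2
    owner = np.zeros((h, w), dtype=np.int32)
    _tile(owner, 1, 1, config.height // side, config.width // side, side, 1)
    wall = np.zeros((h, w), dtype=bool)
    wall[0, :] = wall[-1, :] = wall[:, 0] = wall[:, -1] = True
    params = config.cell_types[0]
    n = (config.height // side) * (config.width // side)
    return LatticeState.from_grid(owner, {cid: params for cid in range(1, n + 1)},
                                  wall_mask=wall)


def build_two_compartment(config: ExperimentConfig) -> LatticeState:
    """Two single-type compartments separated by a removable barrier strip.

    The left ``split_column`` pixels are tiled with the first type and the
    remaining interior with the second; a ``barrier_width`` column strip of
    wall-like barrier pixels (contact cost zero, never copied) is inserted
    between them and marked in ``barrier_mask`` until removal.
    """
    if len(config.cell_types) != 2:
        raise ConfigError("build_two_compartment requires exactly two cell types")
    side = config.initial_cell_side
    col = config.split_column
    wl, wr = col, config.width - col
    bw = config.barrier_width
    h = config.height + 2
    w = config.width + bw + 2
    owner = np.zeros((h, w), dtype=np.int32)
    left, right = config.cell_types
    params_of: Dict[int, CellTypeParams] = {}
    nxt = _tile(owner, 1, 1, config.height // side, wl // side, side, 1)
    for cid in range(1, nxt):
        params_of[cid] = left
    last = _tile(owner, 1, 1 + wl + bw, config.height // side, wr // side, side, nxt)
    for cid in range(nxt, last):
        params_of[cid] = right
    wall = np.zeros((h, w), dtype=bool)
    wall[0, :] = wall[-1, :] = wall[:, 0] = wall[:, -1] = True
    barrier = np.zeros((h, w), dtype=bool)
    barrier[1:-1, 1 + wl:1 + wl + bw] = True
    return LatticeState.from_grid(owner, params_of, wall_mask=wall,
                                  barrier_mask=barrier)


def remove_barrier(lattice: LatticeState) -> int:
    """Release the barrier strip as a shrinking placeholder cell.

    The strip's pixels are handed to a fresh non-viable cell carrying the
    dead-cell parameter switch (target area 0, compressibility 200), so
    adjacent cells absorb the strip through ordinary sweeps within a few
    MCS. Returns the placeholder's cell id.
    """
    if not lattice.barrier_mask.any():
        raise ValueError("lattice has no barrier to remove")
    pid = lattice._next_id
    placeholder = CellTypeParams(type_id=max(int(lattice._type.max()), 0) + 1,
                                 lambda_area=0.0, lambda_cont=0.0,
                                 lambda_adh=0.0, target_area=0.0)
    lattice.register_cell(pid, placeholder, alive=True)
    lattice._type[pid] = BARRIER_REMNANT_TYPE
    lattice.set_dead(pid)
    lattice.owner[lattice.barrier_mask] = pid
    lattice.barrier_mask[:] = False
    lattice.recount_cell(pid)
    return pid


# --------------------------------------------------------------------------- #
# protocols


class _Recorder:
    def __init__(self, type_ids: List[int]) -> None:
        self.type_ids = list(type_ids)
        self.mcs: List[int] = []
        self.live: Dict[int, List[int]] = {t: [] for t in self.type_ids}
        self.dead: Dict[int, List[int]] = {t: [] for t in self.type_ids}
        self.stage: List[int] = []
        self.stage_starts: Dict[int, int] = {}

    def record(self, lattice: LatticeState, mcs: int, stage: int) -> None:
        counts = lattice.counts_by_type(self.type_ids)
        self.mcs.append(mcs)
        self.stage.append(stage)
        if stage not in self.stage_starts:
            self.stage_starts[stage] = mcs
        for tid in self.type_ids:
            live, dead = counts[tid]
            self.live[tid].append(live)
            self.dead[tid].append(dead)

    def series(self) -> TimeSeries:
        return TimeSeries(
            mcs=np.asarray(self.mcs, dtype=int),
            live={t: np.asarray(v, dtype=int) for t, v in self.live.items()},
            dead={t: np.asarray(v, dtype=int) for t, v in self.dead.items()},
            stage=np.asarray(self.stage, dtype=int),
            stage_starts=dict(self.stage_starts),
        )


def run_homogeneous_equilibrium(config: ExperimentConfig,
                                rng: Optional[np.random.Generator] = None
                                ) -> EquilibriumResult:
    """Single-type layer under sweeps + turnover until dynamical equilibrium.

    Stationarity of the total cell count is declared when two consecutive
    sliding windows of ``stat_window`` MCS agree within ``stat_tol``
    (relative); the run then continues for ``measure_mcs`` more steps that
    form the averaging window. If the ``max_mcs`` cap is reached first the
    result is flagged non-stationary.
    """
    if len(config.cell_types) != 1:
        raise ConfigError("run_homogeneous_equilibrium requires a single cell type")
    ct = config.cell_types[0]
    if ct.birth_prob == 0.0 and ct.death_prob > 0.0:
        raise ConfigError("with B=0 and M>0 the layer has no equilibrium (extinction)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lattice = build_monolayer(config)
    potts = PottsConfig(temperature=config.temperature)
    rec = _Recorder([ct.type_id])
    events = TurnoverEventLog()
    turnover_on = ct.birth_prob > 0.0 or ct.death_prob > 0.0
    onset: Optional[int] = None
    check_every = max(config.stat_window // 5, 1)
    for mcs in range(1, config.max_mcs + 1):
        mcs_sweep(lattice, potts, rng)
        if turnover_on:
            apply_turnover(lattice, rng, mcs=mcs, event_log=events)
        rec.record(lattice, mcs, stage=2)
        if onset is None and mcs >= config.min_stationary_mcs and mcs % check_every == 0:
            total = np.asarray(rec.live[ct.type_id]) + np.asarray(rec.dead[ct.type_id])
            idx = stationary_onset(total, config.stat_window, config.stat_tol)
            if idx is not None:
                onset = rec.mcs[idx]
        if onset is not None and mcs >= onset + config.stat_window + config.measure_mcs:
            break
    return EquilibriumResult(series=rec.series(), lattice=lattice, config=config,
                             stationary=onset is not None, stationary_start=onset,
                             events=events)


def run_invasion(config: ExperimentConfig,
                 rng: Optional[np.random.Generator] = None) -> InvasionResult:
    """Three-stage two-type competition run.

    Stage 1: sweeps only (turnover off), barrier in place, for
    ``stage1_mcs`` steps. Stage 2: turnover on behind the barrier until both
    types' total counts are stationary (window ``stat_window``, tolerance
    ``stat_tol``, assessed per side independently) or ``stage2_max_mcs``.
    Stage 3: barrier released; run until one type's cells (live and dead)
    are all gone, or ``stage3_max_mcs``; in the latter case the result is
    flagged incomplete.
    """
    if len(config.cell_types) != 2:
        raise ConfigError("run_invasion requires exactly two cell types")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lattice = build_two_compartment(config)
    potts = PottsConfig(temperature=config.temperature)
    tids = [t.type_id for t in config.cell_types]
    rec = _Recorder(tids)
    events = TurnoverEventLog()
    snapshots: List[Tuple[int, np.ndarray]] = []
    mcs = 0

    def snap(m: int) -> None:
        if config.snapshot_every and m % config.snapshot_every == 0:
            snapshots.append((m, lattice.owner.copy()))

    for _ in range(config.stage1_mcs):
        mcs += 1
        mcs_sweep(lattice, potts, rng)
        rec.record(lattice, mcs, stage=1)
        snap(mcs)

    check_every = max(config.stat_window // 5, 1)
    stage2_start = mcs
    for _ in range(config.stage2_max_mcs):
        mcs += 1
        mcs_sweep(lattice, potts, rng)
        apply_turnover(lattice, rng, mcs=mcs, event_log=events)
        rec.record(lattice, mcs, stage=2)
        snap(mcs)
        steps = mcs - stage2_start
        if steps >= 2 * config.stat_window and steps % check_every == 0:
            ok = True
            for tid in tids:
                tot = (np.asarray(rec.live[tid][stage2_start:])
                       + np.asarray(rec.dead[tid][stage2_start:]))
                if stationary_onset(tot, config.stat_window, config.stat_tol) is None:
                    ok = False
                    break
            if ok:
                break

    remove_barrier(lattice)
    barrier_removed = mcs
    extinct: Optional[int] = None
    for _ in range(config.stage3_max_mcs):
        mcs += 1
        mcs_sweep(lattice, potts, rng)
        apply_turnover(lattice, rng, mcs=mcs, event_log=events)
        rec.record(lattice, mcs, stage=3)
        snap(mcs)
        counts = lattice.counts_by_type(tids)
        for tid in tids:
            if sum(counts[tid]) == 0:
                extinct = tid
                break
        if extinct is not None:
            break

    return InvasionResult(series=rec.series(), lattice=lattice, config=config,
                          events=events, barrier_removed_mcs=barrier_removed,
                          extinct_type=extinct, complete=extinct is not None,
                          snapshots=snapshots)


def stationary_stats(result: EquilibriumResult) -> Dict[str, float]:
    """Mean and SD of live/dead/total counts over the stationary window."""
    series = result.series
    lo, hi = result.stationary_window()
    m = series.window_mask((lo, hi))
    live = series.live_all()[m].astype(float)
    dead = series.dead_all()[m].astype(float)
    tot = live + dead
    return {
        "live_mean": float(live.mean()), "live_sd": float(live.std()),
        "dead_mean": float(dead.mean()), "dead_sd": float(dead.std()),
        "total_mean": float(tot.mean()), "total_sd": float(tot.std()),
        "window_lo": float(lo), "window_hi": float(hi),
        "stationary": float(result.stationary),
    }
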