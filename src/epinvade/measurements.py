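"""Summary statistics for simulation runs.

Equilibrium densities and dead fractions of homogeneous layers, linear fits
to the growth of the invading population, the invasion speed
v = (dN/dt) / (L * rho), and the crowding bound on the stationary live-cell
count. Length unit convention: the domain width perpendicular to the
invasion axis is L = 1, so densities are cells per squared width and speeds
are widths per MCS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TimeSeries:
    """Per-MCS live/dead cell counts by type, with stage markers.

    ``stage`` labels each MCS with the protocol stage it belongs to
    (1 = mechanical relaxation, 2 = turnover equilibration, 3 = competition;
    homogeneous runs use a single stage 2). ``stage_starts`` maps each stage
    label to the first MCS of that stage.
    """

    mcs: np.ndarray
    live: Dict[int, np.ndarray]
    dead: Dict[int, np.ndarray]
    stage: np.ndarray
    stage_starts: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.mcs)
        for d in (self.live, self.dead):
            for tid, v in d.items():
                if len(v) != n:
                    raise ValueError(f"count vector for type {tid} has wrong length")
                if np.any(np.asarray(v) < 0):
                    raise ValueError("cell counts must be non-negative")
        if len(self.stage) != n:
            raise ValueError("stage vector has wrong length")
        starts = [self.stage_starts[k] for k in sorted(self.stage_starts)]
        if starts != sorted(starts):
            raise ValueError("stage markers must be ordered")

    def types(self) -> List[int]:
        return sorted(self.live)

    def total(self, type_id: int) -> np.ndarray:
        return self.live[type_id] + self.dead[type_id]

    def live_all(self) -> np.ndarray:
        return np.sum([self.live[t] for t in self.types()], axis=0)

    def dead_all(self) -> np.ndarray:
        return np.sum([self.dead[t] for t in self.types()], axis=0)

    def window_mask(self, window: Optional[Tuple[int, int]]) -> np.ndarray:
        if window is None:
            return np.ones(len(self.mcs), dtype=bool)
        lo, hi = window
        return (self.mcs >= lo) & (self.mcs <= hi)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid in self.types():
            rows.append(pd.DataFrame({
                "mcs": self.mcs,
                "type_id": tid,
                "live": self.live[tid],
                "dead": self.dead[tid],
                "stage": self.stage,
            }))
        if not rows:
            return pd.DataFrame(columns=["mcs", "type_id", "live", "dead", "stage"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimeSeries":
        if frame.empty:
            return cls(mcs=np.array([], dtype=int), live={}, dead={},
                       stage=np.array([], dtype=int))
        mcs = np.asarray(sorted(frame["mcs"].unique()), dtype=int)
        live, dead = {}, {}
        stage = None
        for tid, sub in frame.groupby("type_id"):
            sub = sub.sort_values("mcs")
            live[int(tid)] = sub["live"].to_numpy(dtype=int)
            dead[int(tid)] = sub["dead"].to_numpy(dtype=int)
            stage = sub["stage"].to_numpy(dtype=int)
        starts = {}
        for s in np.unique(stage):
            starts[int(s)] = int(mcs[np.argmax(stage == s)])
        return cls(mcs=mcs, live=live, dead=dead, stage=stage, stage_starts=starts)


@dataclass
class InvasionSummary:
    """Headline numbers of one competition run.

    ``slope`` is the OLS growth rate of the invading type's total cell count
    (cells per MCS), ``equilibrium_density`` the invader's pre-competition
    density (cells per squared perpendicular width), and
    ``speed = slope / (L * rho)`` with L = 1 the front speed in widths per
    MCS; the winner's identity carries the direction.
    """

    winner: Optional[int]
    slope: float
    slope_stderr: float
    equilibrium_density: float
    speed: float
    fit_window: Tuple[int, int]
    complete: bool


# ------------------------------------------------------------------------- #


def dead_fraction(series: TimeSeries, window: Optional[Tuple[int, int]] = None) -> float:
    """Time-averaged dead/(dead+live) fraction over the window."""
    m = series.window_mask(window)
    if not m.any():
        raise ValueError("empty averaging window")
    live = series.live_all()[m].astype(float)
    dead = series.dead_all()[m].astype(float)
    tot = live + dead
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, dead / np.where(tot > 0, tot, 1.0), 0.0)
    return float(frac.mean())


def equilibrium_density(series: TimeSeries, domain_area: float,
                        window: Optional[Tuple[int, int]] = None,
                        type_id: Optional[int] = None,
                        stationary: bool = True) -> float:
    """Mean live-cell count per unit area over the window.

    ``domain_area`` must be expressed in units where the width perpendicular
    to the invasion axis is L = 1 (i.e. area = extent_parallel / extent_perp
    in pixels). Only live cells are counted; dead cells are transient.
    """
    if domain_area <= 0:
        raise ValueError("domain_area must be positive")
    m = series.window_mask(window)
    if not m.any():
        raise ValueError("empty averaging window")
    live = series.live[type_id][m] if type_id is not None else series.live_all()[m]
    if not stationary:
        warnings.warn("density averaged over a window flagged non-stationary",
                      stacklevel=2)
    return float(live.mean() / domain_area)


def fit_linear_growth(series: TimeSeries, type_id: int,
                      window: Optional[Tuple[int, int]] = None
                      ) -> Tuple[float, float]:
    """OLS slope (cells/MCS) of a type's total count, with its standard error.

    With ``window=None`` the fit window is chosen automatically: from the
    start of the competition stage (stage 3) to 80% of the way to the losing
    type's extinction (or the end of the series if no type goes extinct).
    """
    if window is None:
        window = default_fit_window(series, type_id)
    m = series.window_mask(window)
    if m.sum() < 10:
        raise ValueError("fit window contains fewer than 10 points")
    x = series.mcs[m].astype(float)
    y = series.total(type_id)[m].astype(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit window")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def default_fit_window(series: TimeSeries, invader: int) -> Tuple[int, int]:
    """Auto fit window: barrier removal to 80% of the loser's extinction time."""
    in_stage3 = series.stage == 3
    if not in_stage3.any():
        raise ValueError("series contains no competition-stage (stage 3) data")
    t0 = int(series.mcs[in_stage3][0])
    t_end = int(series.mcs[in_stage3][-1])
    others = [t for t in series.types() if t != invader]
    for tid in others:
        tot = series.total(tid)
        gone = in_stage3 & (tot == 0)
        if gone.any():
            t_ext = int(series.mcs[gone][0])
            t_end = min(t_end, t0 + int(0.8 * (t_ext - t0)))
    return t0, t_end


def invasion_speed(slope: float, rho: float, L: float = 1.0) -> float:
    """Front speed v = slope / (L * rho), in widths per MCS."""
    if rho <= 0:
        raise ValueError("equilibrium density must be positive")
    return slope / (L * rho)


def crowding_bound(free_area: float, target_area: float, coordination: float = 6.0) -> float:
    """Upper bound on the stationary live-cell count.

    Division requires a cell to reach its target area A0, which next to a
    vacated (dead) site requires the mean live area to satisfy
    A >= A0 * Nc / (1 + Nc), where Nc is the mean coordination number of a
    dead cell. The live count is therefore bounded by
    free_area * (1 + Nc) / (A0 * Nc).
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    if coordination < 1:
        raise ValueError("coordination number must be >= 1")
    return free_area * (1.0 + coordination) / (target_area * coordination)


def invasion_direction(series: TimeSeries, alpha: float = 0.01,
                       thin: int = 25) -> Optional[int]:
    """Winning type of a competition run, or None if no significant trend.

    If one type's total count reaches zero during stage 3 the survivor wins
    outright. Otherwise the live counts of both types are thinned (to tame
    the autocorrelation of per-MCS counts) and fitted by OLS; a winner is
    declared only if both slopes are significant at level ``alpha``
    (two-sided) and point in opposite directions.
    """
    in_stage3 = series.stage == 3
    if not in_stage3.any():
        raise ValueError("series contains no competition-stage (stage 3) data")
    types = series.types()
    if len(types) != 2:
        raise ValueError("invasion_direction expects exactly two cell types")
    a, b = types
    tot_a = series.total(a)[in_stage3]
    tot_b = series.total(b)[in_stage3]
    if (tot_a == 0).any():
        return b
    if (tot_b == 0).any():
        return a
    n3 = int(in_stage3.sum())
    thin = max(1, min(thin, n3 // 20))  # keep >= 20 points on short series
    x = series.mcs[in_stage3].astype(float)[::thin]
    if x.size < 10:
        raise ValueError("too few stage-3 points for a trend test")
    slopes = {}
    pvals = {}
    for tid in (a, b):
        y = series.live[tid][in_stage3].astype(float)[::thin]
        res = stats.linregress(x, y)
        slopes[tid] = res.slope
        pvals[tid] = res.pvalue
    if pvals[a] < alpha and pvals[b] < alpha and slopes[a] * slopes[b] < 0:
        return a if slopes[a] > 0 else b
    return None


def summarize_invasion(series: TimeSeries, width_px: int, height_px: int,
                       barrier_column: Optional[int] = None,
                       complete: bool = True,
                       stationary_window: int = 500) -> InvasionSummary:
    """Winner, growth slope, invader density, and speed of a competition run.

    The invader's equilibrium density is estimated from its own side during
    the last ``stationary_window`` MCS of stage 2 (the per-type equilibration
    stage behind the barrier), expressed per squared perpendicular width
    (L = height in pixels). Speed is v = slope / (L * rho) with L = 1.
    """
    winner = invasion_direction(series)
    if winner is None:
        return InvasionSummary(winner=None, slope=0.0, slope_stderr=0.0,
                               equilibrium_density=float("nan"), speed=0.0,
                               fit_window=(0, 0), complete=complete)
    window = default_fit_window(series, winner)
    slope, stderr = fit_linear_growth(series, winner, window)
    if barrier_column is None:
        barrier_column = width_px // 2
    types = series.types()
    side_w = barrier_column if winner == types[0] else width_px - barrier_column
    stage2 = series.stage == 2
    t2_end = int(series.mcs[stage2][-1])
    m = stage2 & (series.mcs >= t2_end - stationary_window)
    rho = float(series.live[winner][m].mean()) / (side_w / height_px)
    speed = invasion_speed(slope, rho)
    return InvasionSummary(winner=winner, slope=slope, slope_stderr=stderr,
                           equilibrium_density=rho, speed=speed,
                           fit_window=window, complete=complete)


def stationary_onset(values: np.ndarray, window: int, tol: float,
                     min_index: int = 0) -> Optional[int]:
    """First index at which two consecutive window means agree within tol.

    Returns the index marking the start of the stationary regime (the
    beginning of the later window), or None if the criterion is never met.
    """
    v = np.asarray(values, dtype=float)
    for end in range(max(2 * window, min_index + window), len(v) + 1, window // 5 or 1):
        m2 = v[end - window:end].mean()
        m1 = v[end - 2 * window:end - window].mean()
        if abs(m2 - m1) <= tol * max(abs(m1), 1.0):
            return end - window
    return None
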