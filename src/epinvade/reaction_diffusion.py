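"""Two-species competition reaction-diffusion model and its front speeds.

The continuum counterpart of the lattice competition:

    d(rho1)/dt = b1 * rho1 * (1 - rho1 - rho2) - m1 * rho1 + D * rho1_xx
    d(rho2)/dt = b2 * rho2 * (1 - rho1 - rho2) - m2 * rho2 + D * rho2_xx

with reproduction rates b1, b2, mortalities m1, m2, and a common diffusion
coefficient D. The uniform system has steady states (0,0), (0, 1-m2/b2),
(1-m1/b1, 0); when b1/m1 > b2/m2 species 1 dominates and a pulled
(Fisher-Kolmogorov) front of species 1 replaces species 2 at the
linear-spreading speed

    v = 2 * sqrt(D * (b1*m2 - b2*m1) / b2),

set by the growth rate of species 1 linearised about the invaded state
(0, 1-m2/b2). The specialisations to equal mortalities and equal birth
rates are derived from this canonical form and cross-checked against the 1D
solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RDParams:
    """Reaction-diffusion coefficients (rates per time, D in length^2/time)."""

    b1: float
    b2: float
    m1: float
    m2: float
    D: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b1", "b2", "m1", "m2", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SteadyState:
    rho1: float
    rho2: float
    name: str
    viable: bool  # non-negative densities and well-defined


@dataclass(frozen=True)
class StabilityResult:
    state: Tuple[float, float]
    eigenvalues: Tuple[complex, complex]
    stable: bool
    neutral: bool  # degenerate b1/m1 == b2/m2 case


@dataclass
class FrontSolution:
    """Output of the 1D solver: grids, final fields, and the front trace."""

    params: RDParams
    x: np.ndarray
    times: np.ndarray
    front_position: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    invader: int
    level: float
    dt: float
    dx: float
    empirical_speed: Optional[float] = None


# --------------------------------------------------------------------------- #


def steady_states(params: RDParams) -> List[SteadyState]:
    """The three uniform steady states; negative-density states are flagged."""
    if params.b1 <= 0 or params.b2 <= 0:
        raise ValueError("steady states require b1, b2 > 0")
    s1 = 1.0 - params.m1 / params.b1
    s2 = 1.0 - params.m2 / params.b2
    return [
        SteadyState(0.0, 0.0, "extinction", True),
        SteadyState(0.0, s2, "species2-only", s2 > 0),
        SteadyState(s1, 0.0, "species1-only", s1 > 0),
    ]


def reaction_terms(params: RDParams, rho1: float, rho2: float) -> Tuple[float, float]:
    """The local (diffusion-free) reaction rates of both species."""
    shared = 1.0 - rho1 - rho2
    f1 = params.b1 * rho1 * shared - params.m1 * rho1
    f2 = params.b2 * rho2 * shared - params.m2 * rho2
    return f1, f2


def reaction_jacobian(params: RDParams, rho1: float, rho2: float) -> np.ndarray:
    b1, b2, m1, m2 = params.b1, params.b2, params.m1, params.m2
    return np.array([
        [b1 * (1.0 - 2.0 * rho1 - rho2) - m1, -b1 * rho1],
        [-b2 * rho2, b2 * (1.0 - rho1 - 2.0 * rho2) - m2],
    ])


def dominant_species(params: RDParams) -> int:
    """1 or 2 for the dominant species; 0 in the degenerate b1/m1 = b2/m2 case."""
    d = params.b1 * params.m2 - params.b2 * params.m1
    if d > 0:
        return 1
    if d < 0:
        return 2
    return 0


def classify_stability(params: RDParams,
                       state: Tuple[float, float]) -> StabilityResult:
    """Eigenvalues and stability of the reaction Jacobian at a uniform state.

    Stable iff both eigenvalues have negative real part. The degenerate case
    b1/m1 = b2/m2 (a continuum of neutral coexistence directions) is flagged
    neutral rather than labelled.
    """
    rho1, rho2 = state
    eig = np.linalg.eigvals(reaction_jacobian(params, rho1, rho2))
    neutral = dominant_species(params) == 0
    stable = bool(np.all(eig.real < 0)) and not neutral
    return StabilityResult(state=(float(rho1), float(rho2)),
                           eigenvalues=(complex(eig[0]), complex(eig[1])),
                           stable=stable, neutral=neutral)


def front_speed(params: RDParams) -> float:
    """Closed-form pulled-front speed of the dominant species.

    For species 1 dominant, v = 2*sqrt(D*(b1*m2 - b2*m1)/b2) -- the
    Fisher-Kolmogorov linear-spreading speed at the invaded state. When
    species 2 dominates the roles swap; at exact parity the speed is zero.
    """
    who = dominant_species(params)
    if who == 0:
        return 0.0
    if who == 1:
        rate = (params.b1 * params.m2 - params.b2 * params.m1) / params.b2
    else:
        rate = (params.b2 * params.m1 - params.b1 * params.m2) / params.b1
    return 2.0 * math.sqrt(params.D * rate)


def front_speed_equal_mortality(D: float, m: float, b1: float, b2: float) -> float:
    """Speed when m1 = m2 = m: 2*sqrt(D*m*(b1-b2)/b2) (b1 > b2)."""
    return front_speed(RDParams(b1=b1, b2=b2, m1=m, m2=m, D=D))


def front_speed_equal_birth(D: float, m1: float, m2: float) -> float:
    """Speed when b1 = b2: 2*sqrt(D*(m2-m1)) (m2 > m1), independent of b."""
    return 2.0 * math.sqrt(D * abs(m2 - m1))


# --------------------------------------------------------------------------- #
# numerical solver


def _front_crossing(field_: np.ndarray, x: np.ndarray, level: float,
                    rightward: bool) -> float:
    idx = np.nonzero(field_ >= level)[0]
    if idx.size == 0:
        return math.nan
    if rightward:
        i = int(idx.max())
        if i + 1 >= x.size:
            return float(x[-1])
        f0, f1 = field_[i], field_[i + 1]
        frac = (f0 - level) / (f0 - f1) if f0 != f1 else 0.0
        return float(x[i] + frac * (x[i + 1] - x[i]))
    i = int(idx.min())
    if i == 0:
        return float(x[0])
    f0, f1 = field_[i], field_[i - 1]
    frac = (f0 - level) / (f0 - f1) if f0 != f1 else 0.0
    return float(x[i] - frac * (x[i] - x[i - 1]))


def solve_1d(params: RDParams, *, n: int = 2000, dx: float = 0.5,
             dt: Optional[float] = None, t_end: float = 100.0,
             interface: Optional[float] = None, n_record: int = 200,
             initial: Optional[Tuple[np.ndarray, np.ndarray]] = None
             ) -> FrontSolution:
    """Integrate the competition PDE in 1D with no-flux boundaries.

    Explicit central-difference diffusion with dt <= 0.4*dx^2/(2D) unless a
    smaller dt is given. The default initial condition is the sharp-interface
    one: species 1 at its carrying capacity left of ``interface`` (default:
    the domain midpoint), species 2 at its carrying capacity to the right.
    The invader's level crossing (half its carrying capacity) is recorded at
    ``n_record`` times. Raises FloatingPointError if the step blows up.
    """
    if params.D <= 0:
        raise ValueError("front problems require D > 0")
    dt_max = 0.4 * dx * dx / (2.0 * params.D)
    if dt is None:
        # also resolve the fastest reaction, relevant when D is tiny
        fastest = max(params.b1, params.b2, params.m1, params.m2, 1e-12)
        dt = min(dt_max, 0.2 / fastest)
    elif dt > dt_max:
        raise ValueError(f"dt={dt} exceeds the stable explicit step {dt_max}")
    x = np.arange(n) * dx
    cap1 = max(0.0, 1.0 - params.m1 / params.b1) if params.b1 > 0 else 0.0
    cap2 = max(0.0, 1.0 - params.m2 / params.b2) if params.b2 > 0 else 0.0
    if initial is not None:
        rho1 = np.array(initial[0], dtype=float)
        rho2 = np.array(initial[1], dtype=float)
        if rho1.shape != x.shape or rho2.shape != x.shape:
            raise ValueError("initial condition shape must match the grid")
    else:
        if interface is None:
            interface = x[-1] / 2.0
        rho1 = np.where(x < interface, cap1, 0.0)
        rho2 = np.where(x >= interface, cap2, 0.0)
    invader = dominant_species(params)
    rightward = invader != 2
    cap_inv = cap1 if invader != 2 else cap2
    level = 0.5 * cap_inv if cap_inv > 0 else 0.5
    steps = max(int(round(t_end / dt)), 1)
    rec_every = max(steps // n_record, 1)
    times: List[float] = []
    fronts: List[float] = []
    inv_dt_dx2 = dt * params.D / (dx * dx)
    b1, b2, m1, m2 = params.b1, params.b2, params.m1, params.m2
    for step in range(1, steps + 1):
        shared = 1.0 - rho1 - rho2
        lap1 = np.empty_like(rho1)
        lap2 = np.empty_like(rho2)
        lap1[1:-1] = rho1[2:] - 2.0 * rho1[1:-1] + rho1[:-2]
        lap2[1:-1] = rho2[2:] - 2.0 * rho2[1:-1] + rho2[:-2]
        lap1[0] = 2.0 * (rho1[1] - rho1[0])        # no-flux (reflecting ghost)
        lap1[-1] = 2.0 * (rho1[-2] - rho1[-1])
        lap2[0] = 2.0 * (rho2[1] - rho2[0])
        lap2[-1] = 2.0 * (rho2[-2] - rho2[-1])
        rho1 = rho1 + dt * (b1 * rho1 * shared - m1 * rho1) + inv_dt_dx2 * lap1
        rho2 = rho2 + dt * (b2 * rho2 * shared - m2 * rho2) + inv_dt_dx2 * lap2
        if step % rec_every == 0 or step == steps:
            if not (np.isfinite(rho1).all() and np.isfinite(rho2).all()):
                raise FloatingPointError("explicit step blew up; reduce dt")
            inv_field = rho1 if invader != 2 else rho2
            times.append(step * dt)
            fronts.append(_front_crossing(inv_field, x, level, rightward))
    if (rho1.min() < -1e-6 or rho2.min() < -1e-6
            or rho1.max() > 1.0 + 1e-6 or rho2.max() > 1.0 + 1e-6):
        raise FloatingPointError("densities left [0, 1]; reduce dt")
    return FrontSolution(params=params, x=x, times=np.asarray(times),
                         front_position=np.asarray(fronts),
                         rho1=rho1, rho2=rho2, invader=invader, level=level,
                         dt=dt, dx=dx)


def measure_front_speed(solution: FrontSolution,
                        fit_fraction: float = 1.0 / 3.0) -> float:
    """Empirical front speed: OLS on the level-crossing trace.

    Fits position vs time over the final ``fit_fraction`` of the recorded
    trace and returns the absolute slope (the travel direction is available
    from the trace itself). Times at which the front sits within two grid
    spacings of a boundary are dropped with a truncated-window warning.
    """
    t = solution.times
    p = solution.front_position
    keep = np.isfinite(p)
    lo_edge = solution.x[0] + 2 * solution.dx
    hi_edge = solution.x[-1] - 2 * solution.dx
    inside = keep & (p > lo_edge) & (p < hi_edge)
    if inside.sum() < keep.sum():
        warnings.warn("front reached the domain boundary; fit window truncated",
                      stacklevel=2)
    t, p = t[inside], p[inside]
    if t.size < 3:
        raise ValueError("too few valid front positions to fit a speed")
    cut = t[0] + (1.0 - fit_fraction) * (t[-1] - t[0])
    m = t >= cut
    res = stats.linregress(t[m], p[m])
    speed = abs(float(res.slope))
    solution.empirical_speed = speed
    return speed
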