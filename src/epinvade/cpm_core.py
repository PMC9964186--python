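"""Cellular Potts lattice, Hamiltonian, and Metropolis pixel-copy dynamics.

A two-dimensional epithelial monolayer is represented on a square lattice
where each cell occupies the set of pixels carrying its integer index
(0 is the wall/barrier sentinel). Configurations evolve by elementary pixel
copies: a random site ``i`` attempts to copy its index into a random
4-neighbour ``j``, accepted with the Metropolis rule at fluctuation
temperature ``T``. The effective energy being minimised is

    E = sum_a lam_area * (A_a - A0_a)^2
      + sum_a lam_cont * L_a^2
      + sum_links phi(a_i, a_j)

with ``A_a`` the cell area (pixel count), ``L_a`` the perimeter measured as
the number of 4-neighbour links from owned to non-owned pixels, and ``phi``
the per-link contact energy: the arithmetic mean of the two cells' adhesion
coefficients for cell-cell links, and zero for links against the wall or
barrier. Adhesion coefficients are negative for live cells, so cells prefer
to share boundary with neighbours, balanced by perimeter contractility.

Conventions: order-1 (von Neumann) neighbourhood for both copy candidates
and boundary links; 0-based row-major grids with x = column as the invasion
axis; no periodic boundaries -- every lattice built here is enclosed by a
one-pixel wall ring, which also makes the inner loops bounds-check free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterator, Mapping, NamedTuple, Optional, Tuple

import numpy as np

from . import _kernels

#: Owner-grid sentinel for wall and (pre-removal) barrier pixels.
WALL = 0

#: Area-compressibility coefficient imposed on dead cells so they shrink.
DEAD_LAMBDA_AREA = 200.0


class LatticeIntegrityError(RuntimeError):
    """Registry and owner grid disagree (corrupted state)."""


@dataclass(frozen=True)
class CellTypeParams:
    """Mechanical and turnover parameters shared by one cell type.

    Energies are in the model's dimensionless units; areas in pixels;
    perimeters in boundary links. ``birth_prob`` (B) and ``death_prob`` (M)
    are per-cell probabilities per Monte Carlo step.
    """

    type_id: int
    lambda_area: float
    lambda_cont: float
    lambda_adh: float
    target_area: float
    birth_prob: float = 0.0
    death_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.type_id <= 0:
            raise ValueError("type_id must be a positive integer")
        if self.lambda_area < 0:
            raise ValueError("lambda_area must be >= 0")
        if self.lambda_cont < 0:
            raise ValueError("lambda_cont must be >= 0")
        if self.lambda_adh > 0:
            raise ValueError(
                "lambda_adh must be <= 0 for live cell types "
                "(cells preferentially expand shared boundaries)"
            )
        if self.target_area < 0:
            raise ValueError("target_area must be >= 0")
        if not 0.0 <= self.birth_prob <= 1.0:
            raise ValueError("birth_prob must lie in [0, 1]")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PottsConfig:
    """Dynamics parameters: fluctuation temperature and neighbourhood."""

    temperature: float = 50.0
    neighborhood_order: int = 1
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.neighborhood_order != 1:
            raise ValueError("only the order-1 (4-neighbour) lattice is supported")


@dataclass
class CellRecord:
    """Snapshot of one cell: identity, viability, geometry, effective params.

    ``lambda_*`` and ``target_area`` are the parameters currently in force;
    after death they differ from the cell type's parameters (contractility
    and adhesion zeroed, target area zero, compressibility raised so the
    corpse shrinks and is extruded).
    """

    cell_id: int
    type_id: int
    alive: bool
    area: int
    perimeter: int
    lambda_area: float
    lambda_cont: float
    lambda_adh: float
    target_area: float
    birth_prob: float
    death_prob: float

    @property
    def effective_params(self) -> Dict[str, float]:
        return {
            "lambda_area": self.lambda_area,
            "lambda_cont": self.lambda_cont,
            "lambda_adh": self.lambda_adh,
            "target_area": self.target_area,
        }


class SweepStats(NamedTuple):
    attempts: int
    accepted: int


_DEAD_EFFECTIVE = {
    "lambda_area": DEAD_LAMBDA_AREA,
    "lambda_cont": 0.0,
    "lambda_adh": 0.0,
    "target_area": 0.0,
}


class LatticeState:
    """Pixel-ownership grid, wall/barrier masks, and the cell registry.

    The per-cell state lives in flat numpy arrays indexed by cell id (the
    hot path requirement); :class:`CellRecord` objects returned by
    :meth:`record` / :attr:`registry` are read-only snapshots. All lattices
    are fully enclosed by a one-pixel ring of wall pixels.
    """

    def __init__(self, owner: np.ndarray,
                 wall_mask: np.ndarray,
                 barrier_mask: Optional[np.ndarray] = None) -> None:
        owner = np.ascontiguousarray(owner, dtype=np.int32)
        if owner.ndim != 2:
            raise ValueError("owner grid must be 2-D")
        self.owner = owner
        self.wall_mask = np.ascontiguousarray(wall_mask, dtype=bool)
        if barrier_mask is None:
            barrier_mask = np.zeros_like(owner, dtype=bool)
        self.barrier_mask = np.ascontiguousarray(barrier_mask, dtype=bool)
        if self.wall_mask.shape != owner.shape or self.barrier_mask.shape != owner.shape:
            raise ValueError("mask shapes must match the owner grid")
        edge = np.zeros_like(self.wall_mask)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        if not self.wall_mask[edge].all():
            raise ValueError("lattice must be enclosed by a one-pixel wall ring")

        cap = 64
        while cap <= int(owner.max(initial=0)):
            cap *= 2
        self._cap = cap
        self._in_use = np.zeros(cap, dtype=bool)
        self._alive = np.zeros(cap, dtype=bool)
        self._type = np.zeros(cap, dtype=np.int32)
        self._area = np.zeros(cap, dtype=np.int64)
        self._perim = np.zeros(cap, dtype=np.int64)
        self._lam_area = np.zeros(cap, dtype=np.float64)
        self._lam_cont = np.zeros(cap, dtype=np.float64)
        self._lam_adh = np.zeros(cap, dtype=np.float64)
        self._target = np.zeros(cap, dtype=np.float64)
        self._birth = np.zeros(cap, dtype=np.float64)
        self._death = np.zeros(cap, dtype=np.float64)
        self._next_id = 1

    # ------------------------------------------------------------------ #
    # construction helpers

    @classmethod
    def from_grid(cls, owner: np.ndarray,
                  params_of: Mapping[int, CellTypeParams],
                  wall_mask: Optional[np.ndarray] = None,
                  barrier_mask: Optional[np.ndarray] = None) -> "LatticeState":
        """Build a state from an owner grid and per-cell-id type parameters.

        Areas and perimeters are recounted from the grid. If no wall mask is
        given, every zero-owner pixel is treated as wall.
        """
        owner = np.asarray(owner, dtype=np.int32)
        if wall_mask is None:
            wall_mask = owner == WALL
            if barrier_mask is not None:
                wall_mask = wall_mask & ~np.asarray(barrier_mask, dtype=bool)
        state = cls(owner, wall_mask, barrier_mask)
        ids = np.unique(owner)
        ids = ids[ids > 0]
        for cid in ids:
            state.register_cell(int(cid), params_of[int(cid)])
        state.recount_all()
        state._next_id = int(ids.max()) + 1 if ids.size else 1
        return state

    # ------------------------------------------------------------------ #
    # geometry

    @property
    def height(self) -> int:
        return self.owner.shape[0]

    @property
    def width(self) -> int:
        return self.owner.shape[1]

    @property
    def free_pixel_count(self) -> int:
        """Pixels that are neither wall nor barrier (the attempt budget per MCS)."""
        return int((~self.wall_mask & ~self.barrier_mask).sum())

    # ------------------------------------------------------------------ #
    # registry

    def register_cell(self, cell_id: int, params: CellTypeParams,
                      alive: bool = True) -> None:
        if cell_id <= 0:
            raise ValueError("cell ids must be positive")
        self._ensure_capacity(cell_id + 1)
        if self._in_use[cell_id]:
            raise ValueError(f"cell id {cell_id} already registered")
        self._in_use[cell_id] = True
        self._alive[cell_id] = alive
        self._type[cell_id] = params.type_id
        self._lam_area[cell_id] = params.lambda_area
        self._lam_cont[cell_id] = params.lambda_cont
        self._lam_adh[cell_id] = params.lambda_adh
        self._target[cell_id] = params.target_area
        self._birth[cell_id] = params.birth_prob
        self._death[cell_id] = params.death_prob
        self._next_id = max(self._next_id, cell_id + 1)

    def allocate_cell(self, like: int) -> int:
        """Register a fresh cell inheriting the parameters of cell ``like``."""
        cid = self._next_id
        self._ensure_capacity(cid + 1)
        self._in_use[cid] = True
        self._alive[cid] = self._alive[like]
        self._type[cid] = self._type[like]
        self._lam_area[cid] = self._lam_area[like]
        self._lam_cont[cid] = self._lam_cont[like]
        self._lam_adh[cid] = self._lam_adh[like]
        self._target[cid] = self._target[like]
        self._birth[cid] = self._birth[like]
        self._death[cid] = self._death[like]
        self._next_id = cid + 1
        return cid

    def remove_cell(self, cell_id: int) -> None:
        if not self._in_use[cell_id]:
            raise KeyError(cell_id)
        if self._area[cell_id] != 0:
            raise LatticeIntegrityError(
                f"cannot remove cell {cell_id} with non-zero area {self._area[cell_id]}"
            )
        self._in_use[cell_id] = False
        self._alive[cell_id] = False

    def ids(self) -> np.ndarray:
        """Registered cell ids in ascending order."""
        return np.flatnonzero(self._in_use)

    def live_ids(self) -> np.ndarray:
        return np.flatnonzero(self._in_use & self._alive)

    def record(self, cell_id: int) -> CellRecord:
        if not (0 < cell_id < self._cap and self._in_use[cell_id]):
            raise KeyError(cell_id)
        return CellRecord(
            cell_id=int(cell_id),
            type_id=int(self._type[cell_id]),
            alive=bool(self._alive[cell_id]),
            area=int(self._area[cell_id]),
            perimeter=int(self._perim[cell_id]),
            lambda_area=float(self._lam_area[cell_id]),
            lambda_cont=float(self._lam_cont[cell_id]),
            lambda_adh=float(self._lam_adh[cell_id]),
            target_area=float(self._target[cell_id]),
            birth_prob=float(self._birth[cell_id]),
            death_prob=float(self._death[cell_id]),
        )

    @property
    def registry(self) -> Dict[int, CellRecord]:
        return {int(cid): self.record(int(cid)) for cid in self.ids()}

    def __iter__(self) -> Iterator[CellRecord]:
        for cid in self.ids():
            yield self.record(int(cid))

    def area_of(self, cell_id: int) -> int:
        return int(self._area[cell_id])

    def is_alive(self, cell_id: int) -> bool:
        return bool(self._in_use[cell_id] and self._alive[cell_id])

    def set_dead(self, cell_id: int) -> None:
        """Apply the dead-cell parameter switch (internal; see turnover.mark_dead)."""
        self._alive[cell_id] = False
        self._lam_area[cell_id] = _DEAD_EFFECTIVE["lambda_area"]
        self._lam_cont[cell_id] = _DEAD_EFFECTIVE["lambda_cont"]
        self._lam_adh[cell_id] = _DEAD_EFFECTIVE["lambda_adh"]
        self._target[cell_id] = _DEAD_EFFECTIVE["target_area"]

    def counts_by_type(self, type_ids) -> Dict[int, Tuple[int, int]]:
        """(live, dead) cell counts for each requested type id."""
        out = {}
        tt = self._type
        use = self._in_use
        alive = self._alive
        for tid in type_ids:
            sel = use & (tt == tid)
            live = int((sel & alive).sum())
            dead = int(sel.sum()) - live
            out[int(tid)] = (live, dead)
        return out

    # ------------------------------------------------------------------ #
    # recounting and validation

    def _padded_owner(self) -> np.ndarray:
        # wall ring is already present, but padding keeps slicing uniform
        return np.pad(self.owner, 1, mode="constant", constant_values=WALL)

    def recount_all(self) -> None:
        """Recompute every cell's area and perimeter from the grid."""
        counts = np.bincount(self.owner.ravel(), minlength=self._cap)
        self._area[:] = 0
        n = min(len(counts), self._cap)
        self._area[:n] = counts[:n]
        self._area[WALL] = 0
        self._perim[:] = 0
        pad = self._padded_owner()
        core = pad[1:-1, 1:-1]
        for shifted in (pad[:-2, 1:-1], pad[2:, 1:-1], pad[1:-1, :-2], pad[1:-1, 2:]):
            mism = (core != shifted) & (core > 0)
            cnt = np.bincount(core[mism], minlength=self._cap)
            self._perim[: len(cnt)] += cnt[: self._cap]

    def recount_cell(self, cell_id: int) -> None:
        mask = self.owner == cell_id
        self._area[cell_id] = int(mask.sum())
        pad = self._padded_owner()
        core = pad[1:-1, 1:-1]
        per = 0
        for shifted in (pad[:-2, 1:-1], pad[2:, 1:-1], pad[1:-1, :-2], pad[1:-1, 2:]):
            per += int(((core != shifted) & mask).sum())
        self._perim[cell_id] = per

    def validate(self) -> None:
        """Raise LatticeIntegrityError on any violated lattice invariant."""
        blocked = self.wall_mask | self.barrier_mask
        if (self.owner[blocked] != WALL).any():
            raise LatticeIntegrityError("wall/barrier pixels must carry the 0 sentinel")
        if (self.owner[~blocked] <= 0).any():
            raise LatticeIntegrityError("every free pixel must be owned by a cell")
        grid_ids = np.unique(self.owner[self.owner > 0])
        for cid in grid_ids:
            if cid >= self._cap or not self._in_use[cid]:
                raise LatticeIntegrityError(f"grid references unregistered cell {cid}")
        areas = np.bincount(self.owner.ravel(), minlength=self._cap)[: self._cap]
        areas[WALL] = 0
        if not np.array_equal(areas, self._area):
            raise LatticeIntegrityError("stored areas disagree with a full recount")
        if int(self._area.sum()) != self.free_pixel_count:
            raise LatticeIntegrityError("registry areas do not sum to the free pixel count")
        saved = self._perim.copy()
        self.recount_all()
        ok = np.array_equal(saved, self._perim)
        if not ok:
            raise LatticeIntegrityError("stored perimeters disagree with a full recount")
        dead = self._in_use & ~self._alive
        for cid in np.flatnonzero(dead):
            if self._type[cid] <= 0:
                continue  # barrier-remnant placeholder uses the same switch
            if (self._lam_area[cid] != DEAD_LAMBDA_AREA or self._lam_cont[cid] != 0.0
                    or self._lam_adh[cid] != 0.0 or self._target[cid] != 0.0):
                raise LatticeIntegrityError(f"dead cell {cid} has wrong effective params")

    def copy(self) -> "LatticeState":
        dup = LatticeState(self.owner.copy(), self.wall_mask.copy(), self.barrier_mask.copy())
        dup._ensure_capacity(self._cap)
        for name in ("_in_use", "_alive", "_type", "_area", "_perim", "_lam_area",
                     "_lam_cont", "_lam_adh", "_target", "_birth", "_death"):
            getattr(dup, name)[: self._cap] = getattr(self, name)
        dup._next_id = self._next_id
        return dup

    def _ensure_capacity(self, n: int) -> None:
        if n <= self._cap:
            return
        cap = self._cap
        while cap < n:
            cap *= 2
        for name in ("_in_use", "_alive", "_type", "_area", "_perim", "_lam_area",
                     "_lam_cont", "_lam_adh", "_target", "_birth", "_death"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            new[: self._cap] = old
            setattr(self, name, new)
        self._cap = cap


# ---------------------------------------------------------------------- #
# energy


def contact_cost(cell_a: Optional[CellRecord], cell_b: Optional[CellRecord]) -> float:
    """Boundary energy per link between two distinct owners.

    ``None`` (or the WALL sentinel) stands for a wall/barrier pixel: such
    links cost nothing. Cell-cell links cost the arithmetic mean of the two
    cells' effective adhesion coefficients, which reduces to the single
    shared coefficient for same-type live contacts.
    """
    a_wall = cell_a is None or cell_a == WALL
    b_wall = cell_b is None or cell_b == WALL
    if a_wall or b_wall:
        return 0.0
    if cell_a.cell_id == cell_b.cell_id:
        raise ValueError("contact_cost requires two distinct owners")
    return 0.5 * (cell_a.lambda_adh + cell_b.lambda_adh)


def total_energy(lattice: LatticeState, config: Optional[PottsConfig] = None) -> float:
    """Full Hamiltonian of the lattice (deterministic for a fixed state).

    Areas and perimeters are recounted from the grid and checked against the
    registry, so an inconsistent state raises LatticeIntegrityError instead
    of returning a silently wrong energy. Each unordered boundary link is
    counted exactly once.
    """
    lattice.validate()
    use = lattice._in_use
    e = float(np.sum(lattice._lam_area[use]
                     * (lattice._area[use] - lattice._target[use]) ** 2))
    e += float(np.sum(lattice._lam_cont[use] * lattice._perim[use].astype(float) ** 2))

    own = lattice.owner
    adh = lattice._lam_adh
    for a, b in ((own[:, :-1], own[:, 1:]), (own[:-1, :], own[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        if m.any():
            e += float(np.sum(0.5 * (adh[a[m]] + adh[b[m]])))
    return e


def _flat_index(lattice: LatticeState, pixel: Tuple[int, int]) -> int:
    r, c = pixel
    if not (0 <= r < lattice.height and 0 <= c < lattice.width):
        raise ValueError(f"pixel {pixel} outside the lattice")
    return r * lattice.width + c


def delta_energy(lattice: LatticeState,
                 source_pixel: Tuple[int, int],
                 target_pixel: Tuple[int, int],
                 config: Optional[PottsConfig] = None) -> float:
    """Energy change of copying the source pixel's owner into the target pixel.

    Computed incrementally from the four links incident to the target pixel;
    equals total_energy(after) - total_energy(before) exactly (up to float
    rounding). Raises ValueError on contract violations: non-adjacent pixels,
    equal owners, or a wall/barrier source or target.
    """
    sr, sc = source_pixel
    tr, tc = target_pixel
    if abs(sr - tr) + abs(sc - tc) != 1:
        raise ValueError("source and target must be order-1 neighbours")
    i = _flat_index(lattice, source_pixel)
    j = _flat_index(lattice, target_pixel)
    flat = lattice.owner.ravel()
    s, t = int(flat[i]), int(flat[j])
    if s == t:
        raise ValueError("source and target pixels share the same owner")
    if s <= 0:
        raise ValueError("source pixel is wall/barrier")
    if t <= 0:
        raise ValueError("target pixel is wall/barrier")
    de, _, _ = _kernels.delta_energy_at(
        flat, lattice.width, i, j,
        lattice._area, lattice._perim, lattice._lam_area,
        lattice._lam_cont, lattice._lam_adh, lattice._target,
    )
    return float(de)


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept dE <= 0, else accept w.p. exp(-dE/T).

    Consumes exactly one uniform draw from ``rng`` in the dE > 0 branch and
    none otherwise.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0.0:
        return True
    return bool(rng.random() < math.exp(-delta_e / temperature))


def mcs_sweep(lattice: LatticeState, config: PottsConfig,
              rng: np.random.Generator) -> SweepStats:
    """One Monte Carlo step: as many copy attempts as there are free pixels.

    Each attempt draws a uniform lattice site, a uniform 4-neighbour
    direction, and one acceptance uniform (the random streams are pre-drawn
    in that order, in one block per sweep, so runs with equal seeds are
    bit-identical). Attempts whose source or target is wall/barrier, or
    whose owners coincide, are skipped but counted.
    """
    n = lattice.free_pixel_count
    sites = rng.integers(0, lattice.height * lattice.width, size=n, dtype=np.int64)
    dirs = rng.integers(0, 4, size=n, dtype=np.int64)
    urand = rng.random(n)
    accepted = _kernels.sweep(
        lattice.owner.ravel(), lattice.width, sites, dirs, urand,
        float(config.temperature),
        lattice._area, lattice._perim, lattice._lam_area,
        lattice._lam_cont, lattice._lam_adh, lattice._target,
    )
    return SweepStats(attempts=n, accepted=int(accepted))


def dead_effective_params() -> Dict[str, float]:
    """The parameter switch applied to dying cells."""
    return dict(_DEAD_EFFECTIVE)
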