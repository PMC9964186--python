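"""Stochastic cell division and death, applied once per Monte Carlo step.

Within every MCS, each live cell dies with its type's probability M; each
live cell at or above its target area divides with probability B. Dying
cells undergo the dead-cell parameter switch (contractility and adhesion
zeroed, target area zero, compressibility raised to 200) so that ordinary
Potts dynamics shrinks and extrudes them; cells whose area reaches zero are
purged from the registry. The per-MCS ordering is fixed as
sweep -> deaths -> divisions -> purge, and every random draw is consumed in
ascending cell-id order, so identical seeds reproduce identical event logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .cpm_core import CellRecord, LatticeIntegrityError, LatticeState

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurnoverEvent:
    """One division, death, or removal event."""

    mcs: int
    event: str  # "division" | "death" | "removal"
    cell_id: int
    type_id: int
    daughter_a: Optional[int] = None
    daughter_b: Optional[int] = None


@dataclass
class TurnoverEventLog:
    events: List[TurnoverEvent] = field(default_factory=list)

    def append(self, event: TurnoverEvent) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        cols = ["mcs", "event", "cell_id", "type_id", "daughter_a", "daughter_b"]
        return pd.DataFrame([vars(e) for e in self.events], columns=cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_deaths(lattice: LatticeState, rng: np.random.Generator) -> List[int]:
    """Ids of live cells selected to die this MCS.

    Each live cell is selected independently with its type's death
    probability M; dead cells are never drawn. One uniform per live cell,
    consumed in ascending cell-id order.
    """
    ids = lattice.live_ids()
    if ids.size == 0:
        return []
    draws = rng.random(ids.size)
    sel = draws < lattice._death[ids]
    return [int(c) for c in ids[sel]]


def mark_dead(lattice: LatticeState, cell_id: int) -> CellRecord:
    """Kill a live cell: apply the dead-cell parameter switch.

    The cell keeps its id and type for bookkeeping but its effective
    parameters become (lambda_cont=0, lambda_adh=0, A0=0, lambda_area=200),
    so the area term drives it to shrink until it vanishes. Killing an
    already-dead cell is a contract violation, not a no-op.
    """
    rec = lattice.record(cell_id)
    if not rec.alive:
        raise ValueError(f"cell {cell_id} is already dead")
    lattice.set_dead(cell_id)
    return lattice.record(cell_id)


def sample_divisions(lattice: LatticeState, rng: np.random.Generator) -> List[int]:
    """Ids of live cells selected to divide this MCS.

    Only live cells whose area has reached their target area (A >= A0) are
    eligible; each eligible cell is selected independently with its type's
    division probability B. One uniform per eligible cell, ascending id
    order.
    """
    ids = lattice.live_ids()
    if ids.size == 0:
        return []
    eligible = ids[lattice._area[ids] >= lattice._target[ids]]
    if eligible.size == 0:
        return []
    draws = rng.random(eligible.size)
    sel = draws < lattice._birth[eligible]
    return [int(c) for c in eligible[sel]]


_MAX_CUT_RETRIES = 8


def divide_cell(lattice: LatticeState, cell_id: int,
                rng: np.random.Generator) -> Optional[Tuple[int, int]]:
    """Split a cell in two by a straight cut through its area centroid.

    The cut orientation is uniform in [0, pi); pixels on the non-negative
    side of the line move to a freshly allocated daughter carrying the
    parent's type parameters, so both daughters are live with the type's
    target area and their areas sum exactly to the parent's. If a draw
    leaves one side empty the orientation is redrawn (up to 8 times), after
    which the cell is split at the pixel-count median along its longer axis.
    Cells of fewer than 2 pixels cannot divide; the event is skipped with a
    logged warning and ``None`` is returned.
    """
    if not lattice.is_alive(cell_id):
        raise ValueError(f"cell {cell_id} is not a live cell")
    ys, xs = np.nonzero(lattice.owner == cell_id)
    n = ys.size
    if n < 2:
        log.warning("division of cell %d skipped: area %d < 2", cell_id, n)
        return None
    cy = ys.mean()
    cx = xs.mean()
    side = None
    for _ in range(_MAX_CUT_RETRIES):
        theta = rng.uniform(0.0, np.pi)
        trial = (xs - cx) * np.cos(theta) + (ys - cy) * np.sin(theta) >= 0.0
        k = int(trial.sum())
        if 0 < k < n:
            side = trial
            break
    if side is None:
        # degenerate geometry: median split along the longer axis
        if np.ptp(xs) >= np.ptp(ys):
            order = np.lexsort((ys, xs))
        else:
            order = np.lexsort((xs, ys))
        side = np.zeros(n, dtype=bool)
        side[order[n // 2:]] = True
    daughter = lattice.allocate_cell(like=cell_id)
    lattice.owner[ys[side], xs[side]] = daughter
    lattice.recount_cell(cell_id)
    lattice.recount_cell(daughter)
    return cell_id, daughter


def purge_vanished(lattice: LatticeState) -> List[int]:
    """Remove every registry entry whose area reached zero.

    A live cell at zero area indicates a corrupted state and raises
    LatticeIntegrityError (live cells can only lose their last pixel after
    the death switch zeroed their target area).
    """
    ids = lattice.ids()
    gone = ids[lattice._area[ids] == 0]
    removed = []
    for cid in gone:
        if lattice._alive[cid]:
            raise LatticeIntegrityError(f"live cell {cid} has zero area")
        lattice.remove_cell(int(cid))
        removed.append(int(cid))
    return removed


def apply_turnover(lattice: LatticeState, rng: np.random.Generator,
                   mcs: int = 0,
                   event_log: Optional[TurnoverEventLog] = None) -> List[TurnoverEvent]:
    """Deaths, then divisions, then purge, for one MCS (run after the sweep).

    Division eligibility is evaluated after this MCS's deaths, so a cell
    that just died cannot divide. Returns the events of this MCS, also
    appended to ``event_log`` when given.
    """
    events: List[TurnoverEvent] = []
    for cid in sample_deaths(lattice, rng):
        rec = mark_dead(lattice, cid)
        events.append(TurnoverEvent(mcs, "death", cid, rec.type_id))
    for cid in sample_divisions(lattice, rng):
        pair = divide_cell(lattice, cid, rng)
        if pair is None:
            continue
        parent, daughter = pair
        events.append(TurnoverEvent(mcs, "division", parent,
                                    int(lattice._type[parent]), parent, daughter))
    for cid in purge_vanished(lattice):
        events.append(TurnoverEvent(mcs, "removal", cid, int(lattice._type[cid])))
    if event_log is not None:
        for e in events:
            event_log.append(e)
    return events
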