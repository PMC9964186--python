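"""Shared fixtures and the independent full-recompute energy oracle."""

import numpy as np
import pytest

from epinvade.cpm_core import CellTypeParams, LatticeState


def oracle_energy(lattice: LatticeState) -> float:
    """Full energy recomputation, independent of the package's total_energy.

    Recounts every cell's area and perimeter directly from the owner grid
    and enumerates each unordered boundary link once via explicit pairwise
    comparisons of padded shifts. Used as the reference for incremental
    delta-energy checks.
    """
    owner = lattice.owner
    recs = {r.cell_id: r for r in lattice}
    e = 0.0
    pad = np.pad(owner, 1, constant_values=0)
    core = pad[1:-1, 1:-1]
    shifts = [pad[:-2, 1:-1], pad[2:, 1:-1], pad[1:-1, :-2], pad[1:-1, 2:]]
    for cid, rec in recs.items():
        mask = core == cid
        area = int(mask.sum())
        perim = sum(int(((core != s) & mask).sum()) for s in shifts)
        e += rec.lambda_area * (area - rec.target_area) ** 2
        e += rec.lambda_cont * perim ** 2
    # horizontal links
    for a, b in ((owner[:, :-1], owner[:, 1:]), (owner[:-1, :], owner[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        for ca, cb in zip(a[m].tolist(), b[m].tolist()):
            e += 0.5 * (recs[ca].lambda_adh + recs[cb].lambda_adh)
    return e


def random_voronoi_lattice(rng: np.random.Generator, size: int = 20,
                           n_cells: int = 4, dead_fraction: float = 0.0,
                           params: CellTypeParams = None) -> LatticeState:
    """Random small lattice: pixels assigned to the nearest of n seed points."""
    if params is None:
        params = CellTypeParams(type_id=1, lambda_area=2.0, lambda_cont=1.0,
                                lambda_adh=-10.0, target_area=60.0)
    seeds = rng.uniform(1, size - 1, size=(n_cells, 2))
    rr, cc = np.mgrid[0:size, 0:size]
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    owner = np.argmin(d2, axis=-1).astype(np.int32) + 1
    owner[0, :] = owner[-1, :] = owner[:, 0] = owner[:, -1] = 0
    present = np.unique(owner[owner > 0])
    state = LatticeState.from_grid(owner, {int(c): params for c in present})
    if dead_fraction > 0:
        from epinvade.turnover import mark_dead
        for cid in present:
            if rng.random() < dead_fraction:
                mark_dead(state, int(cid))
    return state


def legal_copy_attempt(lattice: LatticeState, rng: np.random.Generator):
    """A uniformly drawn legal (source, target) neighbour pixel pair."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    while True:
        r = int(rng.integers(1, lattice.height - 1))
        c = int(rng.integers(1, lattice.width - 1))
        dr, dc = offsets[int(rng.integers(0, 4))]
        r2, c2 = r + dr, c + dc
        s = lattice.owner[r, c]
        t = lattice.owner[r2, c2]
        if s > 0 and t > 0 and s != t:
            return (r, c), (r2, c2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_lattice():
    from epinvade.cli_io import make_fixture
    return make_fixture("two_cell_toy")


@pytest.fixture
def grid_lattice():
    from epinvade.cli_io import make_fixture
    return make_fixture("four_cell_grid")
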