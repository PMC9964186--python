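"""Energies of tiny hand-checkable configurations.

Builds two toy lattices and prints their Hamiltonian terms: the energy of a
configuration is the sum of area-compressibility, perimeter-contractility,
and contact-adhesion penalties, and the Metropolis dynamics samples
low-energy configurations at temperature T.
"""

import numpy as np

from epinvade import CellTypeParams, LatticeState, delta_energy, total_energy
from epinvade.cli_io import make_fixture

# two 2x2 cells sharing one edge, lam_area=1, lam_cont=1, lam_adh=-10, A0=4
toy = make_fixture("two_cell_toy")
print("two-cell toy energy:", total_energy(toy))
print("  (= 2 perimeters of 8 links squared, minus 10 per shared link x2 = 108)")

# both cells sit at their target area, so pushing one pixel across the
# shared edge costs the pure area term 2*lam_area plus boundary reshaping
de = delta_energy(toy, (1, 2), (1, 3))
print("energy cost of one pixel copy across the interface:", de)

# a single cell at its target area with no other penalties is at E = 0
owner = np.zeros((12, 12), np.int32)
owner[1:11, 1:11] = 1
lat = LatticeState.from_grid(
    owner, {1: CellTypeParams(type_id=1, lambda_area=5.0, lambda_cont=0.0,
                              lambda_adh=0.0, target_area=100.0)})
print("relaxed single cell energy:", total_energy(lat), "(all terms vanish)")
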