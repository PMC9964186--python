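"""Numba inner loops for the Potts dynamics.

All kernels operate on a flat row-major int32 owner array (wall/barrier
sentinel 0) and on per-cell arrays indexed directly by cell id. They are the
only hot path in the package; everything else is plain numpy/python.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _phi(a, b, lam_adh):
    # Boundary energy per link. Zero against wall/barrier (owner <= 0) and
    # for same-cell pairs (the Kronecker delta); otherwise the arithmetic
    # mean of the two cells' effective adhesion coefficients.
    if a <= 0 or b <= 0 or a == b:
        return 0.0
    return 0.5 * (lam_adh[a] + lam_adh[b])


@njit(cache=True)
def delta_energy_at(owner, width, i, j, area, perim, lam_area, lam_cont, lam_adh, target):
    """Exact energy change of copying owner[i] into site j.

    Returns (dE, dL_source, dL_target). Assumes owner[i] != owner[j], both
    positive, and i, j order-1 neighbours; callers enforce the contract.
    """
    s = owner[i]
    t = owner[j]
    o0 = owner[j - width]
    o1 = owner[j + width]
    o2 = owner[j - 1]
    o3 = owner[j + 1]

    ns = 0
    nt = 0
    if o0 == s:
        ns += 1
    elif o0 == t:
        nt += 1
    if o1 == s:
        ns += 1
    elif o1 == t:
        nt += 1
    if o2 == s:
        ns += 1
    elif o2 == t:
        nt += 1
    if o3 == s:
        ns += 1
    elif o3 == t:
        nt += 1

    # area term: source gains one pixel, target loses one
    das = area[s] - target[s]
    dat = area[t] - target[t]
    de = lam_area[s] * ((das + 1.0) ** 2 - das ** 2)
    de += lam_area[t] * ((dat - 1.0) ** 2 - dat ** 2)

    # perimeter term (boundary links from owned to non-owned pixels)
    dls = 4 - 2 * ns
    dlt = 2 * nt - 4
    ps = float(perim[s])
    pt = float(perim[t])
    de += lam_cont[s] * ((ps + dls) ** 2 - ps ** 2)
    de += lam_cont[t] * ((pt + dlt) ** 2 - pt ** 2)

    # contact term: only the four links incident to j change
    de += _phi(s, o0, lam_adh) - _phi(t, o0, lam_adh)
    de += _phi(s, o1, lam_adh) - _phi(t, o1, lam_adh)
    de += _phi(s, o2, lam_adh) - _phi(t, o2, lam_adh)
    de += _phi(s, o3, lam_adh) - _phi(t, o3, lam_adh)
    return de, dls, dlt


@njit(cache=True)
def sweep(owner, width, sites, dirs, urand, temperature,
          area, perim, lam_area, lam_cont, lam_adh, target):
    """One Monte Carlo step: len(sites) elementary copy attempts.

    sites/dirs/urand are pre-drawn random streams (site index, neighbour
    direction 0..3, acceptance uniform). Illegal picks (wall/barrier source
    or target, same owner) are skipped but still count as attempts.
    Returns the number of accepted copies.
    """
    accepted = 0
    for k in range(sites.shape[0]):
        i = sites[k]
        s = owner[i]
        if s <= 0:
            continue
        d = dirs[k]
        if d == 0:
            j = i - width
        elif d == 1:
            j = i + width
        elif d == 2:
            j = i - 1
        else:
            j = i + 1
        t = owner[j]
        if t == s or t <= 0:
            continue
        de, dls, dlt = delta_energy_at(
            owner, width, i, j, area, perim, lam_area, lam_cont, lam_adh, target
        )
        if de <= 0.0 or urand[k] < np.exp(-de / temperature):
            owner[j] = s
            area[s] += 1
            area[t] -= 1
            perim[s] += dls
            perim[t] += dlt
            accepted += 1
    return accepted
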