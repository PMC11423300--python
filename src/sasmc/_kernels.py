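"""Numba kernels behind the Monte Carlo engine.

The scalar pair energy duplicates the closed forms in :mod:`sasmc.potentials`
(a unit test pins the two against each other); everything here works on raw
arrays so that the hot loops compile.  Positions are nm, energies k_B*T.

Each kernel that consumes randomness seeds numba's own generator from an
explicit 31-bit integer, so trajectories are exactly reproducible from
(seed, inputs) within one numba version.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pair_potential",
    "total_energy_kernel",
    "particle_energy",
    "run_mc_kernel",
    "rdf_counts_kernel",
]


@njit(cache=True)
def pair_potential(d2, four_r2, a_vdw, c_el, kappa, rc2):
    """DLVO energy for squared distance d2 (no overlap; 0 beyond cutoff)."""
    if d2 >= rc2:
        return 0.0
    u = 0.0
    if a_vdw != 0.0:
        t = four_r2 / d2
        u -= a_vdw * (0.5 * four_r2 / (d2 - four_r2) + 0.5 * t + np.log(1.0 - t))
    if c_el != 0.0:
        d = np.sqrt(d2)
        u += c_el * np.exp(-kappa * d) / d
    return u


@njit(cache=True)
def _min_image_d2(dx, dy, dz, box):
    dx -= box * np.round(dx / box)
    dy -= box * np.round(dy / box)
    dz -= box * np.round(dz / box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def particle_energy(pos, i, box, hc2, four_r2, a_vdw, c_el, kappa, rc2):
    """Energy of particle i against all others; flags hard-core overlap."""
    n = pos.shape[0]
    e = 0.0
    xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
    for j in range(n):
        if j == i:
            continue
        d2 = _min_image_d2(pos[j, 0] - xi, pos[j, 1] - yi, pos[j, 2] - zi, box)
        if d2 <= hc2:
            return 0.0, True
        e += pair_potential(d2, four_r2, a_vdw, c_el, kappa, rc2)
    return e, False


@njit(cache=True)
def total_energy_kernel(pos, box, hc2, four_r2, a_vdw, c_el, kappa, rc2):
    """Pairwise sum over unique pairs under minimum image; (energy, overlap)."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 1, n):
            d2 = _min_image_d2(pos[j, 0] - xi, pos[j, 1] - yi,
                               pos[j, 2] - zi, box)
            if d2 <= hc2:
                return 0.0, True
            e += pair_potential(d2, four_r2, a_vdw, c_el, kappa, rc2)
    return e, False


@njit(cache=True)
def run_mc_kernel(pos, box, hc2, four_r2, a_vdw, c_el, kappa, rc2,
                  max_disp, n_steps, seed, snap_steps, snaps):
    """Run single-particle Metropolis steps in place.

    One step = pick a random particle, propose a uniform displacement in
    [-max_disp, max_disp]^3, wrap periodically, accept with the Metropolis
    rule min(1, e^{-dE}); overlap-creating moves are always rejected.

    ``snap_steps`` is a sorted array of step indices at which a copy of the
    configuration is written into ``snaps``.

    Returns (accumulated energy change, accepted-move count).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    delta_e = 0.0
    n_accept = 0
    k = 0
    n_snap = snap_steps.shape[0]
    for step in range(n_steps):
        i = np.random.randint(0, n)
        x_old = pos[i, 0]
        y_old = pos[i, 1]
        z_old = pos[i, 2]
        e_old, _ = particle_energy(pos, i, box, hc2, four_r2,
                                   a_vdw, c_el, kappa, rc2)
        xn = x_old + (2.0 * np.random.random() - 1.0) * max_disp
        yn = y_old + (2.0 * np.random.random() - 1.0) * max_disp
        zn = z_old + (2.0 * np.random.random() - 1.0) * max_disp
        pos[i, 0] = xn - box * np.floor(xn / box)
        pos[i, 1] = yn - box * np.floor(yn / box)
        pos[i, 2] = zn - box * np.floor(zn / box)
        e_new, overlap = particle_energy(pos, i, box, hc2, four_r2,
                                         a_vdw, c_el, kappa, rc2)
        accept = False
        if not overlap:
            de = e_new - e_old
            if de <= 0.0:
                accept = True
            elif np.random.random() < np.exp(-de):
                accept = True
        if accept:
            delta_e += e_new - e_old
            n_accept += 1
        else:
            pos[i, 0] = x_old
            pos[i, 1] = y_old
            pos[i, 2] = z_old
        if k < n_snap and step == snap_steps[k]:
            for p in range(n):
                snaps[k, p, 0] = pos[p, 0]
                snaps[k, p, 1] = pos[p, 1]
                snaps[k, p, 2] = pos[p, 2]
            k += 1
    return delta_e, n_accept


@njit(cache=True)
def rdf_counts_kernel(snaps, box, r_max, n_bins):
    """Histogram of minimum-image pair distances over all snapshots."""
    counts = np.zeros(n_bins, dtype=np.int64)
    n_snap = snaps.shape[0]
    n = snaps.shape[1]
    scale = n_bins / r_max
    for s in range(n_snap):
        for i in range(n - 1):
            xi, yi, zi = snaps[s, i, 0], snaps[s, i, 1], snaps[s, i, 2]
            for j in range(i + 1, n):
                d2 = _min_image_d2(snaps[s, j, 0] - xi, snaps[s, j, 1] - yi,
                                   snaps[s, j, 2] - zi, box)
                d = np.sqrt(d2)
                if d < r_max:
                    counts[int(d * scale)] += 1
    return counts
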