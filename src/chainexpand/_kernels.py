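"""Numba-compiled inner loops for the bead-spring Langevin engine.

Everything in this module works in simulation units (sigma, m, kBT, tu)
on raw float64 arrays.  Randomness comes from a ``numpy.random.Generator``
passed in by the caller, so seeding policy lives entirely in the wrappers
(:mod:`chainexpand.model`, :mod:`chainexpand.engine`); tests exercise the
kernels against brute-force oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: WCA cutoff in units of sigma.
RCUT_FACTOR = 2.0 ** (1.0 / 6.0)

#: Verlet-list skin in units of sigma (rebuild when a bead moves SKIN/2).
SKIN = 0.5

#: Distance floor guarding the 1/r singularity for overlapping beads.
R_FLOOR = 1e-6


@njit(cache=True, inline="always")
def _pair_force_mag(r, eps, sigma):
    """Radial WCA force magnitude (positive = repulsive) at distance r."""
    sr2 = (sigma / r) ** 2
    sr6 = sr2 * sr2 * sr2
    return 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r


@njit(cache=True)
def _add_bond_forces(pos, f, k_spring, b0):
    n = pos.shape[0]
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        b = np.sqrt(dx * dx + dy * dy + dz * dz)
        if b < R_FLOOR:
            b = R_FLOOR
        fm = -k_spring * (b - b0)  # positive = push apart
        fx = fm * dx / b
        fy = fm * dy / b
        fz = fm * dz / b
        f[i + 1, 0] += fx
        f[i + 1, 1] += fy
        f[i + 1, 2] += fz
        f[i, 0] -= fx
        f[i, 1] -= fy
        f[i, 2] -= fz


@njit(cache=True)
def forces_bruteforce(pos, eps, sigma, k_spring, b0, fcap):
    """All-pairs WCA + harmonic-bond forces; O(N^2) reference path."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    rcut2 = (RCUT_FACTOR * sigma) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut2:
                r = np.sqrt(r2)
                if r < R_FLOOR:
                    r = R_FLOOR
                fm = _pair_force_mag(r, eps, sigma)
                if fcap > 0.0 and fm > fcap:
                    fm = fcap
                fx = fm * dx / r
                fy = fm * dy / r
                fz = fm * dz / r
                f[i, 0] += fx
                f[i, 1] += fy
                f[i, 2] += fz
                f[j, 0] -= fx
                f[j, 1] -= fy
                f[j, 2] -= fz
    _add_bond_forces(pos, f, k_spring, b0)
    return f


#: Half-shell cell offsets (13 of 26 neighbours; the rest follow by symmetry).
_HALF_OFFSETS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
], dtype=np.int64)


@njit(cache=True)
def build_pairs(pos, rv, pi, pj):
    """Fill (pi, pj) with all bead pairs closer than rv; return the count.

    Beads are binned into a cell grid (edge >= rv, cell count capped near
    4N so dilute expanded coils do not blow up the grid) with a counting
    sort, then cell pairs are enumerated over a half shell of offsets so
    every bead pair is visited exactly once.  Returns -1 on capacity
    overflow of the output arrays.
    """
    n = pos.shape[0]
    rv2 = rv * rv
    cap = pi.shape[0]
    xmin = pos[0, 0]
    ymin = pos[0, 1]
    zmin = pos[0, 2]
    xmax = xmin
    ymax = ymin
    zmax = zmin
    for i in range(1, n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        elif pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        elif pos[i, 1] > ymax:
            ymax = pos[i, 1]
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        elif pos[i, 2] > zmax:
            zmax = pos[i, 2]
    ncap = int((4.0 * n) ** (1.0 / 3.0)) + 1
    ncx = min(max(1, int((xmax - xmin) / rv)), ncap)
    ncy = min(max(1, int((ymax - ymin) / rv)), ncap)
    ncz = min(max(1, int((zmax - zmin) / rv)), ncap)
    ncells = ncx * ncy * ncz
    ex = (xmax - xmin) / ncx + 1e-12
    ey = (ymax - ymin) / ncy + 1e-12
    ez = (zmax - zmin) / ncz + 1e-12
    cellid = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / ex)
        cy = int((pos[i, 1] - ymin) / ey)
        cz = int((pos[i, 2] - zmin) / ez)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        ci = (cx * ncy + cy) * ncz + cz
        cellid[i] = ci
        counts[ci + 1] += 1
    for c in range(ncells):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    offs = counts[:-1].copy()
    for i in range(n):
        order[offs[cellid[i]]] = i
        offs[cellid[i]] += 1
    count = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c1 = (cx * ncy + cy) * ncz + cz
                a1 = counts[c1]
                b1 = counts[c1 + 1]
                if a1 == b1:
                    continue
                # pairs inside the cell
                for ii in range(a1, b1):
                    i = order[ii]
                    for jj in range(ii + 1, b1):
                        j = order[jj]
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < rv2:
                            if count >= cap:
                                return -1
                            pi[count] = i
                            pj[count] = j
                            count += 1
                # pairs with the half shell of neighbour cells
                for k in range(13):
                    qx = cx + _HALF_OFFSETS[k, 0]
                    qy = cy + _HALF_OFFSETS[k, 1]
                    qz = cz + _HALF_OFFSETS[k, 2]
                    if qx < 0 or qx >= ncx or qy < 0 or qy >= ncy \
                            or qz < 0 or qz >= ncz:
                        continue
                    c2 = (qx * ncy + qy) * ncz + qz
                    a2 = counts[c2]
                    b2 = counts[c2 + 1]
                    for ii in range(a1, b1):
                        i = order[ii]
                        for jj in range(a2, b2):
                            j = order[jj]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx * dx + dy * dy + dz * dz < rv2:
                                if count >= cap:
                                    return -1
                                pi[count] = i
                                pj[count] = j
                                count += 1
    return count


@njit(cache=True)
def forces_from_pairs(pos, f, pi, pj, npairs, eps, sigma, fcap):
    """Accumulate WCA forces over a pre-built candidate pair list."""
    rcut2 = (RCUT_FACTOR * sigma) ** 2
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rcut2:
            r = np.sqrt(r2)
            if r < R_FLOOR:
                r = R_FLOOR
            fm = _pair_force_mag(r, eps, sigma)
            if fcap > 0.0 and fm > fcap:
                fm = fcap
            fx = fm * dx / r
            fy = fm * dy / r
            fz = fm * dz / r
            f[i, 0] += fx
            f[i, 1] += fy
            f[i, 2] += fz
            f[j, 0] -= fx
            f[j, 1] -= fy
            f[j, 2] -= fz


@njit(cache=True)
def compute_forces(pos, eps, sigma, k_spring, b0, fcap):
    """Total bonded + nonbonded forces for one configuration.

    Small systems use the all-pairs loop directly; larger ones build the
    cell-binned candidate list once.  Both routes are exact (the candidate
    list over-includes, the cutoff test filters).
    """
    n = pos.shape[0]
    if n < 72:
        return forces_bruteforce(pos, eps, sigma, k_spring, b0, fcap)
    cap = 80 * n
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    npairs = build_pairs(pos, RCUT_FACTOR * sigma, pi, pj)
    if npairs < 0:
        return forces_bruteforce(pos, eps, sigma, k_spring, b0, fcap)
    f = np.zeros((n, 3))
    forces_from_pairs(pos, f, pi, pj, npairs, eps, sigma, fcap)
    _add_bond_forces(pos, f, k_spring, b0)
    return f


@njit(cache=True)
def reflect_wall(pos, vel, wall_radius):
    """Specular reflection of beads about the sphere of ``wall_radius``.

    Position is mirrored radially (r -> 2*wall_radius - r) and the radial
    velocity component is negated when pointing outward; speed is conserved.
    """
    n = pos.shape[0]
    for i in range(n):
        r2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
        if r2 > wall_radius * wall_radius:
            r = np.sqrt(r2)
            ux = pos[i, 0] / r
            uy = pos[i, 1] / r
            uz = pos[i, 2] / r
            rnew = 2.0 * wall_radius - r
            if rnew < 0.0:
                rnew = 0.0
            pos[i, 0] = rnew * ux
            pos[i, 1] = rnew * uy
            pos[i, 2] = rnew * uz
            vr = vel[i, 0] * ux + vel[i, 1] * uy + vel[i, 2] * uz
            if vr > 0.0:
                vel[i, 0] -= 2.0 * vr * ux
                vel[i, 1] -= 2.0 * vr * uy
                vel[i, 2] -= 2.0 * vr * uz
    return pos, vel


@njit(cache=True)
def gyration_accumulate(pos, out_row):
    """Write Rg^2 and the 6 unique gyration-tensor entries into out_row.

    Layout: [Rg2, Gxx, Gyy, Gzz, Gxy, Gxz, Gyz].
    """
    n = pos.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(n):
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    cx /= n
    cy /= n
    cz /= n
    gxx = 0.0
    gyy = 0.0
    gzz = 0.0
    gxy = 0.0
    gxz = 0.0
    gyz = 0.0
    for i in range(n):
        dx = pos[i, 0] - cx
        dy = pos[i, 1] - cy
        dz = pos[i, 2] - cz
        gxx += dx * dx
        gyy += dy * dy
        gzz += dz * dz
        gxy += dx * dy
        gxz += dx * dz
        gyz += dy * dz
    gxx /= n
    gyy /= n
    gzz /= n
    gxy /= n
    gxz /= n
    gyz /= n
    out_row[0] = gxx + gyy + gzz
    out_row[1] = gxx
    out_row[2] = gyy
    out_row[3] = gzz
    out_row[4] = gxy
    out_row[5] = gxz
    out_row[6] = gyz


@njit(cache=True)
def run_md(pos, vel, n_steps, sample_steps,
           dt, mass, eta, kBT, eps, sigma, k_spring, b0,
           wall_radius, gen, noise_on, fcap, record_frames):
    """Integrate ``n_steps`` BAOAB Langevin steps, sampling observables.

    Parameters
    ----------
    pos, vel : (N,3) float64, modified in place.
    sample_steps : sorted int64 array of step indices in [0, n_steps] at
        which Rg^2 and the gyration tensor are recorded.
    wall_radius : reflecting-sphere radius for bead centers; <= 0 disables
        the wall (released chain).
    gen : numpy.random.Generator (mutated; caller owns seeding).
    noise_on : 0 disables the random kick (test hook; friction remains).
    fcap : per-pair force cap; <= 0 disables capping (production).
    record_frames : if nonzero, bead positions are stored at every sample.

    Returns
    -------
    samples : (n_samples, 7) array [Rg2, Gxx, Gyy, Gzz, Gxy, Gxz, Gyz]
    frames : (n_samples, N, 3) positions (size 0 along axis 0 if disabled)
    max_radius : largest bead-center distance from the origin seen at any
        sampling time (confinement audit).
    ok : 0 if coordinates went non-finite or the pair list overflowed.
    """
    n = pos.shape[0]
    nsamp = sample_steps.shape[0]
    samples = np.zeros((nsamp, 7))
    if record_frames != 0:
        frames = np.zeros((nsamp, n, 3))
    else:
        frames = np.zeros((0, n, 3))
    c = np.exp(-eta * dt / mass)
    sdev = np.sqrt((1.0 - c * c) * kBT / mass)
    half_dt = 0.5 * dt
    half_dt_m = 0.5 * dt / mass
    rv = RCUT_FACTOR * sigma + SKIN
    cap = 80 * n
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    ref = pos.copy()
    npairs = build_pairs(pos, rv, pi, pj)
    ok = 1
    if npairs < 0:
        ok = 0
        npairs = 0
    f = np.zeros((n, 3))
    forces_from_pairs(pos, f, pi, pj, npairs, eps, sigma, fcap)
    _add_bond_forces(pos, f, k_spring, b0)
    trigger2 = (0.5 * SKIN) ** 2
    si = 0
    max_radius = 0.0
    for step in range(n_steps + 1):
        while si < nsamp and sample_steps[si] == step:
            gyration_accumulate(pos, samples[si])
            if record_frames != 0:
                for i in range(n):
                    frames[si, i, 0] = pos[i, 0]
                    frames[si, i, 1] = pos[i, 1]
                    frames[si, i, 2] = pos[i, 2]
            for i in range(n):
                r2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
                if r2 > max_radius * max_radius:
                    max_radius = np.sqrt(r2)
            if not np.isfinite(samples[si, 0]):
                ok = 0
            si += 1
        if step == n_steps or ok == 0:
            break
        # B: half kick
        for i in range(n):
            vel[i, 0] += half_dt_m * f[i, 0]
            vel[i, 1] += half_dt_m * f[i, 1]
            vel[i, 2] += half_dt_m * f[i, 2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # O: exact Ornstein-Uhlenbeck friction + noise
        if noise_on != 0:
            for i in range(n):
                vel[i, 0] = c * vel[i, 0] + sdev * gen.standard_normal()
                vel[i, 1] = c * vel[i, 1] + sdev * gen.standard_normal()
                vel[i, 2] = c * vel[i, 2] + sdev * gen.standard_normal()
        else:
            for i in range(n):
                vel[i, 0] *= c
                vel[i, 1] *= c
                vel[i, 2] *= c
        # A: half drift
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # wall reflection after the position update
        if wall_radius > 0.0:
            reflect_wall(pos, vel, wall_radius)
        # Verlet-list maintenance: rebuild when any bead moved half a skin
        rebuild = False
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            if dx * dx + dy * dy + dz * dz > trigger2:
                rebuild = True
                break
        if rebuild:
            npairs = build_pairs(pos, rv, pi, pj)
            if npairs < 0:
                ok = 0
                npairs = 0
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        # B: half kick with fresh forces
        for i in range(n):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        forces_from_pairs(pos, f, pi, pj, npairs, eps, sigma, fcap)
        _add_bond_forces(pos, f, k_spring, b0)
        for i in range(n):
            vel[i, 0] += half_dt_m * f[i, 0]
            vel[i, 1] += half_dt_m * f[i, 1]
            vel[i, 2] += half_dt_m * f[i, 2]
    return samples, frames, max_radius, ok


@njit(cache=True)
def min_nonbonded_distance(pos):
    """Smallest distance between beads more than one bond apart."""
    n = pos.shape[0]
    dmin = 1e30
    for i in range(n):
        for j in range(i + 2, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < dmin:
                dmin = d
    return dmin


@njit(cache=True)
def has_overlap(pos_a, pos_b, rmin):
    """True if any inter-set pair distance is below rmin (SAW dimerization)."""
    rmin2 = rmin * rmin
    for i in range(pos_a.shape[0]):
        for j in range(pos_b.shape[0]):
            dx = pos_a[i, 0] - pos_b[j, 0]
            dy = pos_a[i, 1] - pos_b[j, 1]
            dz = pos_a[i, 2] - pos_b[j, 2]
            if dx * dx + dy * dy + dz * dz < rmin2:
                return True
    return False


@njit(cache=True)
def grow_walk_in_sphere(n, bond, radius, gen, max_tries):
    """Random walk of n beads with fixed bond length inside a sphere.

    Overlaps between non-bonded beads are allowed (removed later by the
    capped-force push-off); only the wall constraint is enforced.  Returns
    (positions, ok).
    """
    pos = np.zeros((n, 3))
    while True:
        x = (2.0 * gen.random() - 1.0) * radius
        y = (2.0 * gen.random() - 1.0) * radius
        z = (2.0 * gen.random() - 1.0) * radius
        if x * x + y * y + z * z <= radius * radius:
            pos[0, 0] = x
            pos[0, 1] = y
            pos[0, 2] = z
            break
    for i in range(1, n):
        placed = False
        for _ in range(max_tries):
            while True:
                ux = 2.0 * gen.random() - 1.0
                uy = 2.0 * gen.random() - 1.0
                uz = 2.0 * gen.random() - 1.0
                u2 = ux * ux + uy * uy + uz * uz
                if 1e-12 < u2 <= 1.0:
                    break
            norm = np.sqrt(u2)
            x = pos[i - 1, 0] + bond * ux / norm
            y = pos[i - 1, 1] + bond * uy / norm
            z = pos[i - 1, 2] + bond * uz / norm
            if x * x + y * y + z * z <= radius * radius:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                placed = True
                break
        if not placed:
            return pos, False
    return pos, True
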