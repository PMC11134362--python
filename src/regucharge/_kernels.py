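"""Numba-compiled inner loops: pair interactions, Langevin blocks, MC energies.

All kernels work on flat numpy arrays in reduced units (k_BT = 1, m = 1,
lengths in nm) with a cubic periodic box and the minimum-image convention.
Electrostatics here are screened Debye-Hueckel pairs, truncated at ``rcut``
and shifted to zero at the cutoff; the explicit-ion Ewald path lives in
:mod:`regucharge.ewald`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)
NEIGHBOR_SKIN = 0.6


@njit(cache=True)
def _mic(d, L):
    return d - L * np.rint(d / L)


@njit(cache=True)
def pair_energy(pos, q, L, bonds, bond_k, bond_r0, eps, sigma, kappa, lb, rcut):
    """Total potential energy: bonds + WCA + shifted-truncated DH.

    Returns np.inf on a hard-core overlap.
    """
    N = pos.shape[0]
    rc_wca = WCA_CUT_FACTOR * sigma
    rc_wca2 = rc_wca * rc_wca
    shift = np.exp(-kappa * rcut) / rcut if rcut > 0 else 0.0
    U = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mic(pos[i, 0] - pos[j, 0], L)
        dy = _mic(pos[i, 1] - pos[j, 1], L)
        dz = _mic(pos[i, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        U += 0.5 * bond_k * (r - bond_r0) * (r - bond_r0)
    for i in range(N - 1):
        for j in range(i + 1, N):
            dx = _mic(pos[i, 0] - pos[j, 0], L)
            dy = _mic(pos[i, 1] - pos[j, 1], L)
            dz = _mic(pos[i, 2] - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc_wca2:
                if r2 < 1e-18:
                    return np.inf
                s2 = sigma * sigma / r2
                s6 = s2 * s2 * s2
                U += 4.0 * eps * (s6 * s6 - s6) + eps
            if lb != 0.0 and q[i] != 0.0 and q[j] != 0.0:
                r = np.sqrt(r2)
                if r < rcut:
                    U += lb * q[i] * q[j] * (np.exp(-kappa * r) / r - shift)
    return U


@njit(cache=True)
def _forces_into(pos, q, L, bonds, bond_k, bond_r0, eps, sigma, kappa, lb, rcut,
                 wi, wj, n_w, ci, F):
    """Forces from bonds, WCA over the neighbour list and DH over charged beads."""
    N = pos.shape[0]
    rc_wca2 = (WCA_CUT_FACTOR * sigma) ** 2
    for a in range(N):
        F[a, 0] = 0.0
        F[a, 1] = 0.0
        F[a, 2] = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mic(pos[i, 0] - pos[j, 0], L)
        dy = _mic(pos[i, 1] - pos[j, 1], L)
        dz = _mic(pos[i, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            fmag = -bond_k * (r - bond_r0) / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz
    for p in range(n_w):
        i = wi[p]
        j = wj[p]
        dx = _mic(pos[i, 0] - pos[j, 0], L)
        dy = _mic(pos[i, 1] - pos[j, 1], L)
        dz = _mic(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc_wca2 and r2 > 1e-18:
            s2 = sigma * sigma / r2
            s6 = s2 * s2 * s2
            fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2  # (1/r dU/dr) with sign
            F[i, 0] += fr * dx
            F[i, 1] += fr * dy
            F[i, 2] += fr * dz
            F[j, 0] -= fr * dx
            F[j, 1] -= fr * dy
            F[j, 2] -= fr * dz
    nc = ci.shape[0]
    if lb != 0.0:
        for a in range(nc - 1):
            i = ci[a]
            for bidx in range(a + 1, nc):
                j = ci[bidx]
                dx = _mic(pos[i, 0] - pos[j, 0], L)
                dy = _mic(pos[i, 1] - pos[j, 1], L)
                dz = _mic(pos[i, 2] - pos[j, 2], L)
                r2 = dx * dx + dy * dy + dz * dz
                r = np.sqrt(r2)
                if r < rcut and r > 1e-12:
                    e = np.exp(-kappa * r)
                    # -dU/dr = lb q q e (kappa r + 1)/r^2 ; divide by r for vector
                    fr = lb * q[i] * q[j] * e * (kappa * r + 1.0) / (r2 * r)
                    F[i, 0] += fr * dx
                    F[i, 1] += fr * dy
                    F[i, 2] += fr * dz
                    F[j, 0] -= fr * dx
                    F[j, 1] -= fr * dy
                    F[j, 2] -= fr * dz


@njit(cache=True)
def _build_wca_list(pos, L, rlist2, wi, wj):
    N = pos.shape[0]
    n = 0
    cap = wi.shape[0]
    for i in range(N - 1):
        for j in range(i + 1, N):
            dx = _mic(pos[i, 0] - pos[j, 0], L)
            dy = _mic(pos[i, 1] - pos[j, 1], L)
            dz = _mic(pos[i, 2] - pos[j, 2], L)
            if dx * dx + dy * dy + dz * dz < rlist2:
                if n >= cap:
                    return -1
                wi[n] = i
                wj[n] = j
                n += 1
    return n


@njit(cache=True)
def ld_block(pos, vel, q, L, bonds, bond_k, bond_r0, eps, sigma, kappa, lb, rcut,
             dt, gamma, noise, nlist_every):
    """Integrate ``noise.shape[0]`` BAOAB Langevin steps in place.

    Returns 0 on success, 1 on non-finite coordinates, 2 on neighbour-list
    overflow.  With gamma = 0 the O-step is the identity and the scheme
    reduces to velocity Verlet.
    """
    n_steps = noise.shape[0]
    N = pos.shape[0]
    rlist = WCA_CUT_FACTOR * sigma + NEIGHBOR_SKIN
    rlist2 = rlist * rlist
    cap = 16 + N * 128
    wi = np.empty(cap, dtype=np.int64)
    wj = np.empty(cap, dtype=np.int64)
    nc = 0
    for i in range(N):
        if q[i] != 0.0:
            nc += 1
    ci = np.empty(nc, dtype=np.int64)
    k = 0
    for i in range(N):
        if q[i] != 0.0:
            ci[k] = i
            k += 1
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    F = np.zeros((N, 3))
    n_w = _build_wca_list(pos, L, rlist2, wi, wj)
    if n_w < 0:
        return 2
    _forces_into(pos, q, L, bonds, bond_k, bond_r0, eps, sigma, kappa, lb, rcut,
                 wi, wj, n_w, ci, F)
    for step in range(n_steps):
        if step > 0 and step % nlist_every == 0:
            n_w = _build_wca_list(pos, L, rlist2, wi, wj)
            if n_w < 0:
                return 2
        for a in range(N):
            for d in range(3):
                vel[a, d] += 0.5 * dt * F[a, d]
                pos[a, d] += 0.5 * dt * vel[a, d]
                vel[a, d] = c1 * vel[a, d] + c2 * noise[step, a, d]
                pos[a, d] += 0.5 * dt * vel[a, d]
        _forces_into(pos, q, L, bonds, bond_k, bond_r0, eps, sigma, kappa, lb, rcut,
                     wi, wj, n_w, ci, F)
        for a in range(N):
            for d in range(3):
                vel[a, d] += 0.5 * dt * F[a, d]
    ok = True
    for a in range(N):
        for d in range(3):
            if not np.isfinite(pos[a, d]) or not np.isfinite(vel[a, d]):
                ok = False
            elif np.abs(vel[a, d]) > 1e15:   # thermal scale is 1: runaway
                ok = False
    return 0 if ok else 1


@njit(cache=True)
def mol_delta_u(pos, q, L, mol_beads, disp, eps, sigma, kappa, lb, rcut):
    """Energy change for a rigid displacement of one molecule.

    Intramolecular terms are invariant, so only WCA + DH pairs between the
    molecule's beads and the rest are summed.  Returns a large finite number
    on hard-core overlap so exp(-dU) underflows to rejection.
    """
    N = pos.shape[0]
    nb = mol_beads.shape[0]
    rc_wca = WCA_CUT_FACTOR * sigma
    rc_wca2 = rc_wca * rc_wca
    shift = np.exp(-kappa * rcut) / rcut if rcut > 0 else 0.0
    in_mol = np.zeros(N, dtype=np.uint8)
    for k in range(nb):
        in_mol[mol_beads[k]] = 1
    du = 0.0
    for k in range(nb):
        i = mol_beads[k]
        for j in range(N):
            if in_mol[j] == 1:
                continue
            for which in range(2):
                if which == 0:
                    dx = _mic(pos[i, 0] + disp[0] - pos[j, 0], L)
                    dy = _mic(pos[i, 1] + disp[1] - pos[j, 1], L)
                    dz = _mic(pos[i, 2] + disp[2] - pos[j, 2], L)
                    sgn = 1.0
                else:
                    dx = _mic(pos[i, 0] - pos[j, 0], L)
                    dy = _mic(pos[i, 1] - pos[j, 1], L)
                    dz = _mic(pos[i, 2] - pos[j, 2], L)
                    sgn = -1.0
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc_wca2:
                    if r2 < 0.25 * sigma * sigma:
                        if sgn > 0:
                            return 1e30
                    else:
                        s2 = sigma * sigma / r2
                        s6 = s2 * s2 * s2
                        du += sgn * (4.0 * eps * (s6 * s6 - s6) + eps)
                if lb != 0.0 and q[i] != 0.0 and q[j] != 0.0:
                    r = np.sqrt(r2)
                    if r < rcut:
                        du += sgn * lb * q[i] * q[j] * (np.exp(-kappa * r) / r - shift)
    return du


@njit(cache=True)
def site_delta_u(pos, q, L, site_bead, dq, kappa, lb, rcut):
    """Electrostatic energy change when bead ``site_bead`` changes charge by dq."""
    if lb == 0.0 or dq == 0.0:
        return 0.0
    N = pos.shape[0]
    shift = np.exp(-kappa * rcut) / rcut if rcut > 0 else 0.0
    du = 0.0
    for j in range(N):
        if j == site_bead or q[j] == 0.0:
            continue
        dx = _mic(pos[site_bead, 0] - pos[j, 0], L)
        dy = _mic(pos[site_bead, 1] - pos[j, 1], L)
        dz = _mic(pos[site_bead, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rcut and r > 1e-12:
            du += dq * q[j] * lb * (np.exp(-kappa * r) / r - shift)
    return du
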