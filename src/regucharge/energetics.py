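"""Potential energy and forces.

Three contributions: Weeks-Chandler-Andersen (WCA) excluded volume between
all bead pairs, harmonic bonds, and electrostatics.  Electrostatics come in
two interchangeable treatments:

``debye_hueckel_implicit_ions`` (default)
    Screened Coulomb pairs u(r) = z1 z2 lambda_B exp(-kappa r)/r between the
    polymer charges, with kappa set by the ionic strength
    (kappa^2 = 8 pi lambda_B N_A I for 1:1 salt).  In total energies and
    forces the pair term is truncated at ``dh_cutoff_factor / kappa``
    (capped at L/2) and shifted to zero at the cutoff.

``coulomb_explicit_ions``
    Bare Coulomb z1 z2 lambda_B / r with explicit small ions and the
    long-range part summed by standard Ewald (see :mod:`regucharge.ewald`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .system_model import InvalidArgumentError, SystemState
from .units import BJERRUM_WATER_NM, kappa_from_ionic_strength

DH_MODE = "debye_hueckel_implicit_ions"
EWALD_MODE = "coulomb_explicit_ions"


class OverlapError(FloatingPointError):
    """Raised when beads overlap so closely that the energy is non-finite."""


@dataclass(frozen=True)
class ForceField:
    """Interaction parameters in reduced units (energies in k_BT, lengths nm)."""

    wca_epsilon: float = 1.0
    sigma: float = 0.35
    bond_k: float = 400.0
    bond_r0: float = 0.4
    bjerrum_length: float = BJERRUM_WATER_NM
    electrostatics_mode: str = DH_MODE
    kappa: float = 0.0
    dh_cutoff_factor: float = 4.0
    manning_renormalize: bool = True
    coulomb_real_space_cutoff: float = 0.0   # 0 -> L/2 at evaluation time
    ewald_accuracy: float = 1e-5

    def __post_init__(self) -> None:
        if self.bjerrum_length < 0 or self.kappa < 0:
            raise InvalidArgumentError("bjerrum_length and kappa must be non-negative")
        if self.electrostatics_mode not in (DH_MODE, EWALD_MODE):
            raise InvalidArgumentError(f"unknown electrostatics mode {self.electrostatics_mode!r}")

    @classmethod
    def from_ionic_strength(cls, ionic_strength: float, **kwargs) -> "ForceField":
        lb = kwargs.pop("bjerrum_length", BJERRUM_WATER_NM)
        kappa = kappa_from_ionic_strength(ionic_strength, lb)
        return cls(bjerrum_length=lb, kappa=kappa, **kwargs)

    def dh_cutoff(self, box_length: float) -> float:
        half = box_length / 2.0
        if self.kappa > 0:
            return min(self.dh_cutoff_factor / self.kappa, half)
        return half


def wca_energy(r: float, epsilon: float, sigma: float) -> float:
    """Purely repulsive cut-and-shifted Lennard-Jones (WCA) pair energy."""
    if r <= 0:
        raise InvalidArgumentError("r must be positive")
    rc = _kernels.WCA_CUT_FACTOR * sigma
    if r >= rc:
        return 0.0
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6) + epsilon


def bond_energy(r: float, k: float, r0: float) -> float:
    """Harmonic bond (k/2)(r - r0)^2."""
    if r < 0:
        raise InvalidArgumentError("r must be non-negative")
    return 0.5 * k * (r - r0) ** 2


def electrostatic_pair_energy(r: float, z1: float, z2: float, ff: ForceField) -> float:
    """Bare pair law of the active electrostatics mode (no cutoff shift).

    DH mode: z1 z2 lambda_B exp(-kappa r)/r; explicit mode: z1 z2 lambda_B/r
    (the periodic long-range correction is applied at total-energy level).
    """
    if r <= 0:
        raise InvalidArgumentError("r must be positive")
    lb = ff.bjerrum_length
    if ff.electrostatics_mode == DH_MODE:
        return z1 * z2 * lb * math.exp(-ff.kappa * r) / r
    return z1 * z2 * lb / r


def effective_charges(state: SystemState, ff: ForceField) -> np.ndarray:
    """Charges entering the implicit-ion energetics.

    A strong polyelectrolyte above the Manning threshold (xi = lambda_B / b
    > 1) carries a diffuse layer of condensed counterions that linearized
    Debye-Hueckel theory cannot represent; the standard Oosawa-Manning
    closure replaces its bare line charge by the renormalized value 1/xi per
    bare charge.  With ``manning_renormalize`` (DH mode only) the
    permanently ionized polyanion sites are therefore scaled by
    min(1, b/lambda_B); the weakly/fluctuating oligocation charges sit below
    the threshold and are never renormalized.  Bookkeeping (electroneutrality,
    ionization, trajectory output) always uses the bare integer charges.
    """
    q = state.bead_charges()
    if (ff.electrostatics_mode == DH_MODE and ff.manning_renormalize
            and ff.bjerrum_length > 0):
        frac = min(1.0, ff.bond_r0 / ff.bjerrum_length)
        q[state.meta.polyanion_bead_mask] *= frac
    return q


def _kernel_args(state: SystemState, ff: ForceField):
    q = effective_charges(state, ff)
    L = state.box_length
    return state.positions, q, L, state.meta.bonds, ff.bond_k, ff.bond_r0, \
        ff.wca_epsilon, ff.sigma, ff.kappa, ff.bjerrum_length, ff.dh_cutoff(L)


def total_energy(state: SystemState, ff: ForceField) -> float:
    """Total potential energy of a state [k_BT].

    Raises :class:`OverlapError` when a hard-core overlap makes it non-finite.
    """
    if ff.electrostatics_mode == EWALD_MODE:
        from . import ewald
        pos, q, L, bonds, bond_k, bond_r0, eps, sigma, _, lb, rcut = _kernel_args(state, ff)
        u_short = _kernels.pair_energy(pos, q, L, bonds, bond_k, bond_r0, eps, sigma, 0.0, 0.0, rcut)
        if not np.isfinite(u_short):
            raise OverlapError("overlapping beads: non-finite energy")
        u_elec = ewald.ewald_energy(pos, q, L, lb, ff.ewald_accuracy,
                                    rcut=ff.coulomb_real_space_cutoff or None)
        return float(u_short + u_elec)
    u = _kernels.pair_energy(*_kernel_args(state, ff))
    if not np.isfinite(u):
        raise OverlapError("overlapping beads: non-finite energy")
    return float(u)


def forces(state: SystemState, ff: ForceField) -> np.ndarray:
    """Per-bead force array, -grad U."""
    pos, q, L, bonds, bond_k, bond_r0, eps, sigma, kappa, lb, rcut = _kernel_args(state, ff)
    N = pos.shape[0]
    F = np.zeros((N, 3))
    wi = np.empty(N * (N - 1) // 2 + 1, dtype=np.int64)
    wj = np.empty_like(wi)
    n_w = _kernels._build_wca_list(pos, L, (_kernels.WCA_CUT_FACTOR * sigma + _kernels.NEIGHBOR_SKIN) ** 2, wi, wj)
    if ff.electrostatics_mode == EWALD_MODE:
        from . import ewald
        ci = np.empty(0, dtype=np.int64)
        _kernels._forces_into(pos, q, L, bonds, bond_k, bond_r0, eps, sigma,
                              0.0, 0.0, rcut, wi, wj, n_w, ci, F)
        F += ewald.ewald_forces(pos, q, L, lb, ff.ewald_accuracy,
                                rcut=ff.coulomb_real_space_cutoff or None)
        return F
    ci = np.flatnonzero(q != 0.0).astype(np.int64)
    _kernels._forces_into(pos, q, L, bonds, bond_k, bond_r0, eps, sigma,
                          kappa, lb, rcut, wi, wj, n_w, ci, F)
    return F


def site_flip_delta_energy(state: SystemState, ff: ForceField, bead_index: int, dq: float) -> float:
    """Energy change when one bead's charge changes by ``dq`` at fixed coordinates.

    In DH mode this is the only term in the constant-pH Delta-U (implicit ions
    carry no explicit interactions); in explicit mode the full Ewald
    difference is taken by the sampler instead.
    """
    pos, q, L, _, _, _, _, _, kappa, lb, rcut = _kernel_args(state, ff)
    return float(_kernels.site_delta_u(pos, q, L, bead_index, dq, kappa, lb, rcut))
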