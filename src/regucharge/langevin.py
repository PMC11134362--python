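"""Langevin dynamics at fixed ionization state.

BAOAB splitting of the Langevin equation with unit masses and k_BT = 1:
half kick, half drift, Ornstein-Uhlenbeck velocity refresh
(v <- e^{-gamma dt} v + sqrt(1 - e^{-2 gamma dt}) R), half drift, half kick.
With gamma = 0 the refresh is the identity and the scheme reduces to
velocity Verlet, which is the basis of the energy-conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .energetics import DH_MODE, ForceField, forces
from .system_model import InvalidArgumentError, SystemState


class UnstableTimestepError(RuntimeError):
    pass


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integrator settings (reduced time units)."""

    dt: float = 0.005
    gamma: float = 1.0
    n_steps_per_block: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gamma < 0:
            raise InvalidArgumentError("dt must be positive and gamma non-negative")


def ld_step(state: SystemState, ff: ForceField, params: IntegratorParams,
            rng: Optional[np.random.Generator] = None,
            noise: Optional[np.ndarray] = None) -> SystemState:
    """One BAOAB step; returns a new state (mode-agnostic reference path)."""
    new = state.copy()
    dt, gamma = params.dt, params.gamma
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    if noise is None:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        noise = rng.standard_normal(new.positions.shape) if c2 > 0 else np.zeros_like(new.positions)
    F = forces(new, ff)
    new.velocities += 0.5 * dt * F
    new.positions += 0.5 * dt * new.velocities
    new.velocities = c1 * new.velocities + c2 * noise
    new.positions += 0.5 * dt * new.velocities
    F = forces(new, ff)
    new.velocities += 0.5 * dt * F
    diverged = not (np.isfinite(new.positions).all() and np.isfinite(new.velocities).all())
    if diverged or np.abs(new.velocities).max() > 1e15:
        raise UnstableTimestepError(f"diverging coordinates after LD step; dt={dt} too large?")
    return new


def run_ld(state: SystemState, ff: ForceField, params: IntegratorParams, n_steps: int,
           rng: Optional[np.random.Generator] = None, in_place: bool = False,
           nlist_every: int = 10, max_chunk: int = 20000) -> SystemState:
    """Integrate ``n_steps`` Langevin steps.

    DH mode runs through the compiled block kernel; explicit-ion mode falls
    back to the per-step reference path (small systems only).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    st = state if in_place else state.copy()
    if ff.electrostatics_mode != DH_MODE:
        for _ in range(n_steps):
            st = ld_step(st, ff, params, rng=rng)
        return st
    q = st.bead_charges()
    L = st.box_length
    done = 0
    while done < n_steps:
        chunk = min(max_chunk, n_steps - done)
        noise = rng.standard_normal((chunk, st.positions.shape[0], 3))
        status = _kernels.ld_block(
            st.positions, st.velocities, q, L, st.meta.bonds,
            ff.bond_k, ff.bond_r0, ff.wca_epsilon, ff.sigma,
            ff.kappa, ff.bjerrum_length, ff.dh_cutoff(L),
            params.dt, params.gamma, noise, nlist_every,
        )
        if status == 1:
            raise UnstableTimestepError(f"non-finite coordinates during LD block; dt={params.dt} too large?")
        if status == 2:
            raise RuntimeError("neighbour list overflow")
        done += chunk
    return st
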