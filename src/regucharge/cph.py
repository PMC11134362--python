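"""Constant-pH Monte Carlo coupled to Langevin dynamics.

A trial move flips the protonation state of one randomly chosen titratable
site.  Deprotonation of a base (charged -> neutral, xi = +1) inserts one
monovalent cation to keep the box electroneutral; protonation (xi = -1)
deletes one.  In the implicit-ion Debye-Hueckel mode insertion/deletion is
count-only, so Delta U contains only the change of the screened polymer
electrostatics; in the explicit-ion mode the ion is placed uniformly at
random in the box and Delta U is the full Ewald energy difference.  The
move is accepted with probability

    min{1, exp(-Delta U + xi ln10 (pH - pKa))}        (energies in k_BT)

which reduces to the Henderson-Hasselbalch law in the ideal (non-
interacting) limit -- the decisive consistency check for the sign
convention of xi.  Protonation with no deletable cation left is auto-
rejected.  Trial moves are never proposed on the polyanion: its side
chains are kept fully ionized (pH >> its pKa in the regime of interest).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .energetics import (DH_MODE, ForceField, effective_charges,
                         site_flip_delta_energy, total_energy)
from .langevin import IntegratorParams, UnstableTimestepError, run_ld
from .system_model import InvalidArgumentError, SystemState
from .trajectory import Trajectory
from .units import LN10

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpHParams:
    """Constant-pH sampling parameters.

    ``moves_per_cycle = None`` means one attempted move per titratable site
    per cycle.
    """

    pH: float
    pKa: float = 10.68
    moves_per_cycle: Optional[int] = None
    ld_steps_per_cycle: int = 100
    translation_moves: bool = True
    translation_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moves_per_cycle is not None and self.moves_per_cycle < 1:
            raise InvalidArgumentError("moves_per_cycle must be >= 1")
        if self.ld_steps_per_cycle < 0:
            raise InvalidArgumentError("ld_steps_per_cycle must be >= 0")


def acceptance_probability(delta_u: float, xi: int, pH: float, pKa: float) -> float:
    """min{1, exp(-Delta U + xi ln10 (pH - pKa))} with energies in k_BT."""
    if not math.isfinite(delta_u):
        return 0.0
    arg = -delta_u + xi * LN10 * (pH - pKa)
    return 1.0 if arg >= 0.0 else math.exp(arg)


def propose_move(state: SystemState, site: int,
                 rng: Optional[np.random.Generator] = None
                 ) -> Tuple[Optional[SystemState], int]:
    """Trial flip of one titratable site with electroneutrality bookkeeping.

    Returns ``(trial_state, xi)``; the trial state is ``None`` when the move
    is auto-rejected (protonation with no deletable cation).
    """
    meta = state.meta
    tit_beads = meta.titratable_beads
    if site < 0 or site >= tit_beads.size:
        raise InvalidArgumentError(f"site {site} is not a titratable site index")
    implicit = state.ion_active.size == 0
    trial = state.copy()
    s = int(state.ionization[site])
    if s == 1:
        xi = +1
        trial.ionization[site] = 0
        if implicit:
            trial.implicit_cation_count += 1
        else:
            if rng is None:
                rng = np.random.default_rng()
            slots = np.flatnonzero(meta.is_ion & (meta.valence > 0))
            inactive = slots[trial.ion_active[_ion_index(meta, slots)] == 0]
            if inactive.size == 0:
                raise RuntimeError("cation pool exhausted; enlarge the pool at build time")
            pick = inactive[0]
            trial.ion_active[_ion_index(meta, np.array([pick]))[0]] = 1
            trial.positions[pick] = rng.uniform(0.0, state.box_length, size=3)
    else:
        xi = -1
        trial.ionization[site] = 1
        if implicit:
            if state.implicit_cation_count == 0:
                return None, xi
            trial.implicit_cation_count -= 1
        else:
            if rng is None:
                rng = np.random.default_rng()
            slots = np.flatnonzero(meta.is_ion & (meta.valence > 0))
            active = slots[trial.ion_active[_ion_index(meta, slots)] == 1]
            if active.size == 0:
                return None, xi
            pick = active[int(rng.integers(active.size))]
            trial.ion_active[_ion_index(meta, np.array([pick]))[0]] = 0
    assert abs(trial.total_charge()) < 1e-9
    return trial, xi


def _ion_index(meta, bead_indices: np.ndarray) -> np.ndarray:
    """Map bead indices of ions to positions in the ``ion_active`` array."""
    ion_beads = np.flatnonzero(meta.is_ion)
    lookup = {int(b): k for k, b in enumerate(ion_beads)}
    return np.array([lookup[int(b)] for b in bead_indices], dtype=np.int64)


def run_cph_ld(state: SystemState, ff: ForceField, integ: IntegratorParams,
               cph: CpHParams, n_cycles: int, warmup_cycles: int,
               rng: Optional[np.random.Generator] = None,
               log_every: int = 500) -> Trajectory:
    """Alternate constant-pH MC sweeps with Langevin blocks; record one frame
    per cycle after warmup.

    One RNG stream drives, per cycle and in this order: the MC site indices,
    the MC acceptance uniforms (and ion placement draws in explicit mode),
    then the Gaussian block noise of the LD steps -- so a run is reproducible
    bit-for-bit at fixed seed in DH mode.
    """
    if n_cycles <= warmup_cycles:
        raise InvalidArgumentError("n_cycles must exceed warmup_cycles")
    if rng is None:
        rng = np.random.default_rng(cph.seed)
    st = state.copy()
    meta = st.meta
    tit_beads = meta.titratable_beads
    n_sites = tit_beads.size
    if n_sites == 0:
        raise InvalidArgumentError("system has no titratable sites")
    moves = cph.moves_per_cycle or n_sites
    implicit = ff.electrostatics_mode == DH_MODE and st.ion_active.size == 0

    q = effective_charges(st, ff)
    # integer bookkeeping for the electroneutrality invariant (bare charges)
    net_polymer = int(round(st.bead_charges().sum()))
    L = st.box_length
    rcut = ff.dh_cutoff(L)
    oc_mol_beads = [meta.molecule_beads(int(m)) for m in meta.oligocation_mol_ids]
    frames_pos, frames_q, frames_ion = [], [], []
    rows = []
    for cycle in range(n_cycles):
        accepted = 0
        for _ in range(moves):
            site = int(rng.integers(n_sites))
            u_rand = rng.random()
            bead = int(tit_beads[site])
            s = int(st.ionization[site])
            xi = +1 if s == 1 else -1
            if implicit:
                dq = -float(meta.valence[bead]) if s == 1 else float(meta.valence[bead])
                if xi == -1 and st.implicit_cation_count == 0:
                    continue
                du = _kernels.site_delta_u(st.positions, q, L, bead, dq,
                                           ff.kappa, ff.bjerrum_length, rcut)
                if u_rand < acceptance_probability(du, xi, cph.pH, cph.pKa):
                    st.ionization[site] = 1 - s
                    q[bead] += dq
                    net_polymer += int(dq)
                    st.implicit_cation_count += xi
                    accepted += 1
            else:
                trial, xi = propose_move(st, site, rng=rng)
                if trial is None:
                    continue
                du = total_energy(trial, ff) - total_energy(st, ff)
                if u_rand < acceptance_probability(du, xi, cph.pH, cph.pKa):
                    st = trial
                    q = effective_charges(st, ff)
                    net_polymer = int(round(st.bead_charges().sum()))
                    accepted += 1
            # electroneutrality is a hard invariant of the sampler
            if implicit:
                assert net_polymer + st.implicit_cation_count - st.implicit_anion_count == 0
            else:
                assert abs(st.total_charge()) < 1e-9
        if cph.translation_moves and implicit:
            # rigid-body MC displacements of whole oligocations: equilibrium-
            # preserving moves that accelerate condensation/release exchange
            # far beyond what centre-of-mass diffusion alone provides
            for mol_beads in oc_mol_beads:
                teleport = rng.random() < 0.5
                if teleport:
                    disp = rng.uniform(0.0, L, size=3)
                else:
                    disp = rng.normal(scale=cph.translation_step, size=3)
                u_rand = rng.random()
                du = _kernels.mol_delta_u(st.positions, q, L, mol_beads, disp,
                                          ff.wca_epsilon, ff.sigma, ff.kappa,
                                          ff.bjerrum_length, rcut)
                if du < 700 and u_rand < math.exp(min(0.0, -du)):
                    st.positions[mol_beads] += disp
        if cph.ld_steps_per_cycle > 0:
            if implicit:
                noise = rng.standard_normal((cph.ld_steps_per_cycle, st.positions.shape[0], 3))
                status = _kernels.ld_block(
                    st.positions, st.velocities, q, L, meta.bonds,
                    ff.bond_k, ff.bond_r0, ff.wca_epsilon, ff.sigma,
                    ff.kappa, ff.bjerrum_length, rcut,
                    integ.dt, integ.gamma, noise, 10,
                )
                if status == 1:
                    raise UnstableTimestepError(f"non-finite coordinates in cycle {cycle}; dt={integ.dt}")
                if status == 2:
                    raise RuntimeError("neighbour list overflow")
            else:
                st = run_ld(st, ff, integ, cph.ld_steps_per_cycle, rng=rng, in_place=True)
                q = st.bead_charges()
        if cycle >= warmup_cycles:
            frames_pos.append(st.positions.copy())
            frames_q.append(st.bead_charges().astype(np.float32))
            frames_ion.append(st.ionization.copy())
            rows.append({
                "cycle": cycle,
                "alpha": float(st.ionization.mean()),
                "energy": total_energy(st, ff),
                "acceptance": accepted / moves,
            })
        if log_every and cycle % log_every == 0:
            logger.info("cycle=%d alpha=%.4f acc=%.3f", cycle,
                        float(st.ionization.mean()), accepted / max(moves, 1))
    scalars = pd.DataFrame(rows)
    return Trajectory(
        meta=meta, box_length=L,
        positions=np.stack(frames_pos),
        charges=np.stack(frames_q),
        ionization=np.stack(frames_ion),
        scalars=scalars,
        info={"pH": cph.pH, "pKa": cph.pKa, "seed": cph.seed,
              "mode": ff.electrostatics_mode},
    )
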