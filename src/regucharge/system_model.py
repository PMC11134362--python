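"""System composition and construction.

A two-beads-per-monomer bead--spring model of a strong polyanion
(methacrylate-like, side chains permanently carrying -1) and short weak
polybase oligocations (lysine-like, side chains titratable with
pKa = 10.68).  Each monomer contributes one neutral backbone bead and one
side-chain bead bonded to it; backbone beads form a single linear path.
Chain ends carry no extra ionizable groups (the experimental oligomers are
end-protected).

Small ions are either implicit (Debye-Hueckel screening plus integer
bookkeeping, the default) or explicit charged beads appended to the state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .units import box_length_from_concentration, number_density

POLYANION = "polyanion"
OLIGOCATION = "oligocation"
ION = "ion"

#: conjugate-acid pKa of the lysine side-chain ammonium group
PKA_LYSINE = 10.68
#: monomer pKa of methacrylic acid (not titrated here: pH >> pKa, chain kept fully ionized)
PKA_PMAA = 4.28


class InvalidArgumentError(ValueError):
    """Raised when an operation is called with arguments violating its preconditions."""


@dataclass(frozen=True)
class BeadSpec:
    """One bead species of the coarse-grained model."""

    label: str
    valence_when_ionized: int
    is_titratable: bool
    pKa: float = math.nan
    diameter_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.is_titratable and not math.isfinite(self.pKa):
            raise InvalidArgumentError("titratable bead requires a finite pKa")
        if self.diameter_sigma <= 0:
            raise InvalidArgumentError("diameter_sigma must be positive")
        if self.valence_when_ionized not in (-1, 0, 1):
            raise InvalidArgumentError("valence must be -1, 0 or +1")


def default_bead_specs(pka_lysine: float = PKA_LYSINE, sigma: float = 0.35) -> dict:
    """Bead species used throughout: polyanion backbone/side, oligocation backbone/side."""
    return {
        "pa_backbone": BeadSpec("MB", 0, False, diameter_sigma=sigma),
        "pa_side": BeadSpec("MS", -1, False, diameter_sigma=sigma),
        "oc_backbone": BeadSpec("LB", 0, False, diameter_sigma=sigma),
        "oc_side": BeadSpec("LS", +1, True, pKa=pka_lysine, diameter_sigma=sigma),
    }


@dataclass(frozen=True)
class ChainTopology:
    """Linear backbone with one pendant side-chain bead per monomer.

    Bead ordering: backbone of monomer i at index 2i, its side chain at 2i+1.
    """

    chain_kind: str
    n_monomers: int
    beads: tuple
    bonds: tuple

    @property
    def n_beads(self) -> int:
        return len(self.beads)


def build_topology(kind: str, n_monomers: int, bead_specs: Sequence[BeadSpec]) -> ChainTopology:
    """Build a two-beads-per-monomer chain topology.

    Parameters
    ----------
    kind:
        ``"polyanion"`` or ``"oligocation"``.
    n_monomers:
        Number of monomeric units (>= 1).
    bead_specs:
        Pair ``(backbone_spec, side_spec)``.
    """
    if kind not in (POLYANION, OLIGOCATION):
        raise InvalidArgumentError(f"unknown chain kind {kind!r}")
    if n_monomers < 1:
        raise InvalidArgumentError("n_monomers must be >= 1")
    backbone, side = bead_specs
    beads = []
    bonds = []
    for i in range(n_monomers):
        beads.append(backbone)
        beads.append(side)
        bonds.append((2 * i, 2 * i + 1))
        if i > 0:
            bonds.append((2 * (i - 1), 2 * i))
    return ChainTopology(kind, n_monomers, tuple(beads), tuple(bonds))


def _allowed_oligocation_lengths(n_oligo_monomers: int) -> list:
    return [d for d in range(1, n_oligo_monomers + 1) if n_oligo_monomers % d == 0]


@dataclass(frozen=True)
class SystemComposition:
    """Composition of one simulated solution.

    ``monomer_ratio`` is (oligocation monomers : polyanion monomers); with the
    default 1:2 and m = 48 there are 24 lysine monomers, i.e. 24/n oligomers.
    Temperature enters only through k_BT = 1 (reduced units).
    """

    polyanion_length: int = 48
    oligocation_length: int = 8
    n_polyanion_chains: int = 1
    monomer_ratio: tuple = (1, 2)
    ionic_strength: float = 0.01
    pH: float = 7.0
    temperature: float = 1.0
    polyanion_monomer_concentration: float = 5e-3
    box_length: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        m, n = self.polyanion_length, self.oligocation_length
        if m < 1 or n < 1:
            raise InvalidArgumentError("chain lengths must be >= 1")
        num, den = self.monomer_ratio
        total = m * max(self.n_polyanion_chains, 1) * num
        if total % den != 0 or (total // den) % n != 0:
            allowed = _allowed_oligocation_lengths(total // den if total % den == 0 else total)
            raise InvalidArgumentError(
                f"oligocation length n={n} does not divide the {total // den if total % den == 0 else total} "
                f"oligocation monomers implied by m={m} and ratio {num}:{den}; allowed n: {allowed}"
            )

    @property
    def n_oligocations(self) -> int:
        num, den = self.monomer_ratio
        return (self.polyanion_length * max(self.n_polyanion_chains, 1) * num // den) // self.oligocation_length

    def resolved_box_length(self, bond_r0: float = 0.4) -> float:
        if self.box_length is not None:
            return float(self.box_length)
        if self.n_polyanion_chains < 1:
            raise InvalidArgumentError("box_length must be given explicitly when no polyanion is present")
        L = box_length_from_concentration(
            self.polyanion_length * self.n_polyanion_chains, self.polyanion_monomer_concentration
        )
        contour = (self.polyanion_length - 1) * bond_r0
        if L <= contour:
            raise InvalidArgumentError(
                f"box length {L:.2f} nm does not exceed the polyanion contour length {contour:.2f} nm; "
                "lower the polyanion monomer concentration"
            )
        return L


@dataclass
class SystemMeta:
    """Static per-bead bookkeeping shared by all frames of a run."""

    labels: np.ndarray          # (N,) unicode
    valence: np.ndarray         # (N,) int8, valence when ionized (ions: their valence)
    titratable: np.ndarray      # (N,) bool
    pka: np.ndarray             # (N,) float, nan where not titratable
    mol_id: np.ndarray          # (N,) int32
    chain_kind: np.ndarray      # per molecule, unicode
    backbone: np.ndarray        # (N,) bool
    is_ion: np.ndarray          # (N,) bool
    bonds: np.ndarray           # (B,2) int64

    @property
    def n_beads(self) -> int:
        return self.labels.shape[0]

    @property
    def titratable_beads(self) -> np.ndarray:
        return np.flatnonzero(self.titratable)

    @property
    def polyanion_bead_mask(self) -> np.ndarray:
        kinds = self.chain_kind[self.mol_id]
        return kinds == POLYANION

    @property
    def oligocation_mol_ids(self) -> np.ndarray:
        return np.flatnonzero(self.chain_kind == OLIGOCATION)

    def molecule_beads(self, mol: int) -> np.ndarray:
        return np.flatnonzero(self.mol_id == mol)


@dataclass
class SystemState:
    """Dynamic state: coordinates, velocities, ionization and ion bookkeeping."""

    positions: np.ndarray       # (N,3) float64 [nm]
    velocities: np.ndarray      # (N,3) float64
    ionization: np.ndarray      # (n_titratable,) int8
    ion_active: np.ndarray      # (n_ion_beads,) int8 (explicit mode; empty otherwise)
    implicit_cation_count: int
    implicit_anion_count: int
    box_length: float
    meta: SystemMeta

    def bead_charges(self) -> np.ndarray:
        q = self.meta.valence.astype(np.float64).copy()
        tit = self.meta.titratable_beads
        q[tit] *= self.ionization
        if self.ion_active.size:
            ion_idx = np.flatnonzero(self.meta.is_ion)
            q[ion_idx] *= self.ion_active
        return q

    def total_charge(self) -> float:
        return float(
            self.bead_charges().sum()
            + self.implicit_cation_count
            - self.implicit_anion_count
        )

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            ionization=self.ionization.copy(),
            ion_active=self.ion_active.copy(),
            implicit_cation_count=self.implicit_cation_count,
            implicit_anion_count=self.implicit_anion_count,
            box_length=self.box_length,
            meta=self.meta,
        )


def _assemble_meta(chains: list, ion_specs: list) -> SystemMeta:
    """Concatenate chain topologies (and ion beads) into flat per-bead arrays."""
    labels, valence, titratable, pka, mol_id, backbone, is_ion = [], [], [], [], [], [], []
    chain_kind = []
    bonds = []
    offset = 0
    for mol, topo in enumerate(chains):
        chain_kind.append(topo.chain_kind)
        for j, spec in enumerate(topo.beads):
            labels.append(spec.label)
            valence.append(spec.valence_when_ionized)
            titratable.append(spec.is_titratable)
            pka.append(spec.pKa)
            mol_id.append(mol)
            backbone.append(j % 2 == 0)
            is_ion.append(False)
        for a, b in topo.bonds:
            bonds.append((a + offset, b + offset))
        offset += topo.n_beads
    mol = len(chains)
    for label, z in ion_specs:
        chain_kind.append(ION)
        labels.append(label)
        valence.append(z)
        titratable.append(False)
        pka.append(math.nan)
        mol_id.append(mol)
        backbone.append(False)
        is_ion.append(True)
        mol += 1
    return SystemMeta(
        labels=np.array(labels),
        valence=np.array(valence, dtype=np.int8),
        titratable=np.array(titratable, dtype=bool),
        pka=np.array(pka, dtype=float),
        mol_id=np.array(mol_id, dtype=np.int32),
        chain_kind=np.array(chain_kind),
        backbone=np.array(backbone, dtype=bool),
        is_ion=np.array(is_ion, dtype=bool),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
    )


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def _too_close(pos: np.ndarray, existing: np.ndarray, L: float, rmin: float) -> bool:
    if existing.shape[0] == 0:
        return False
    d = _min_image(existing - pos, L)
    return bool((d * d).sum(axis=1).min() < rmin * rmin)


def _place_chain_walk(topo: ChainTopology, L: float, r0: float, rmin: float,
                      taken: list, rng: np.random.Generator, max_tries: int = 2000) -> np.ndarray:
    """Random-walk placement with overlap rejection; regrows on dead ends."""
    existing = np.array(taken, dtype=float).reshape(-1, 3)
    for _ in range(max_tries):
        pos = np.empty((topo.n_beads, 3))
        start = rng.uniform(0.0, L, size=3)
        if _too_close(start, existing, L, rmin):
            continue
        pos[0] = start
        ok = True
        for i in range(1, topo.n_monomers):
            placed = False
            for _ in range(30):
                step = rng.normal(size=3)
                step *= r0 / np.linalg.norm(step)
                cand = pos[2 * (i - 1)] + step
                if not _too_close(cand, existing, L, rmin) and not _too_close(cand, pos[: 2 * i: 2], L, rmin):
                    pos[2 * i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        # pendant side chains
        for i in range(topo.n_monomers):
            placed = False
            for _ in range(30):
                step = rng.normal(size=3)
                step *= r0 / np.linalg.norm(step)
                cand = pos[2 * i] + step
                placed_beads = [pos[0::2]]          # every backbone bead is already placed
                if i > 0:
                    placed_beads.append(pos[1: 2 * i: 2])
                if existing.size:
                    placed_beads.append(existing)
                if not _too_close(cand, np.vstack(placed_beads), L, rmin):
                    pos[2 * i + 1] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise RuntimeError("failed to place chain without overlaps; box too crowded?")


def build_system(comp: SystemComposition, ff, rng: Optional[np.random.Generator] = None) -> SystemState:
    """Build an electroneutral initial configuration.

    One (or ``n_polyanion_chains``) polyanion chain(s) are laid out as
    straight rods through the box (bonds at rest length, trivially
    self-avoiding; the chain relaxes during warmup); oligocations are grown
    as random walks with overlap rejection at seed-controlled positions.
    Oligocation side chains start at a Bernoulli draw of the ideal
    Henderson-Hasselbalch ionization for ``comp.pH``; implicit or explicit
    small ions then restore exact electroneutrality.
    """
    if rng is None:
        rng = np.random.default_rng(comp.seed)
    specs = default_bead_specs(sigma=ff.sigma)
    L = comp.resolved_box_length(ff.bond_r0)
    r0 = ff.bond_r0
    rmin = 0.85 * ff.sigma

    chains = []
    coords = []
    taken: list = []
    for c in range(comp.n_polyanion_chains):
        topo = build_topology(POLYANION, comp.polyanion_length, (specs["pa_backbone"], specs["pa_side"]))
        chains.append(topo)
        m = comp.polyanion_length
        pos = np.empty((topo.n_beads, 3))
        center = np.full(3, L / 2.0)
        center[1] += c * 2.0
        for i in range(m):
            pos[2 * i] = center + np.array([(i - (m - 1) / 2.0) * r0, 0.0, 0.0])
            pos[2 * i + 1] = pos[2 * i] + np.array([0.0, r0 * (1 if i % 2 == 0 else -1), 0.0])
        coords.append(pos)
        taken.extend(pos.tolist())

    oc_topo = build_topology(OLIGOCATION, comp.oligocation_length, (specs["oc_backbone"], specs["oc_side"]))
    for _ in range(comp.n_oligocations):
        pos = _place_chain_walk(oc_topo, L, r0, rmin, taken, rng)
        chains.append(oc_topo)
        coords.append(pos)
        taken.extend(pos.tolist())

    n_tit = comp.n_oligocations * comp.oligocation_length
    alpha_ideal = 1.0 / (1.0 + 10.0 ** (comp.pH - PKA_LYSINE))
    ionization = (rng.random(n_tit) < alpha_ideal).astype(np.int8)
    n_charged = int(ionization.sum())

    n_pa_monomers = comp.polyanion_length * comp.n_polyanion_chains
    n_salt = int(round(number_density(comp.ionic_strength) * L ** 3))

    explicit = getattr(ff, "electrostatics_mode", "debye_hueckel_implicit_ions") == "coulomb_explicit_ions"
    ion_specs = []
    ion_active = np.zeros(0, dtype=np.int8)
    implicit_cation = implicit_anion = 0
    if explicit:
        # cation pool: polyanion counterions + salt cations (active) plus one
        # inactive slot per initially charged site (future deprotonations)
        n_cat_active = n_pa_monomers + n_salt
        n_cat_pool = n_cat_active + n_charged
        n_an = n_charged + n_salt
        ion_specs = [("Na", +1)] * n_cat_pool + [("Cl", -1)] * n_an
        ion_active = np.concatenate([
            np.ones(n_cat_active, dtype=np.int8),
            np.zeros(n_cat_pool - n_cat_active, dtype=np.int8),
            np.ones(n_an, dtype=np.int8),
        ])
        ion_pos = []
        existing = np.array(taken, dtype=float)
        for _ in ion_specs:
            for _ in range(500):
                cand = rng.uniform(0.0, L, size=3)
                if not _too_close(cand, existing, L, rmin):
                    break
            ion_pos.append(cand)
        coords.append(np.array(ion_pos))
    else:
        implicit_cation = n_pa_monomers + n_salt
        implicit_anion = n_charged + n_salt

    meta = _assemble_meta(chains, ion_specs)
    positions = np.vstack(coords) if coords else np.zeros((0, 3))
    positions = np.mod(positions, L)
    velocities = rng.normal(size=positions.shape)  # k_BT = 1, m = 1

    state = SystemState(
        positions=positions,
        velocities=velocities,
        ionization=ionization,
        ion_active=ion_active,
        implicit_cation_count=implicit_cation,
        implicit_anion_count=implicit_anion,
        box_length=L,
        meta=meta,
    )
    assert abs(state.total_charge()) < 1e-9, "built system must be electroneutral"
    return state
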