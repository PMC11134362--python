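"""Trajectory container and extended-XYZ + sidecar-CSV persistence.

On disk a run is a directory holding ``trajectory.extxyz`` (one frame per
recorded cycle; per-atom columns species, position, charge, ionization
flag, molecule id) and ``frames.csv`` (per-frame scalars: cycle, alpha,
total energy, MC acceptance rate).  Positions round-trip losslessly to
1e-6 nm.  Foreign extended-XYZ files lacking the ionization column are
read with flags defaulted to zero and a logged warning.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .system_model import (ION, OLIGOCATION, PKA_LYSINE, POLYANION,
                           SystemMeta)

logger = logging.getLogger(__name__)

TRAJ_FILE = "trajectory.extxyz"
SCALARS_FILE = "frames.csv"


class TrajectoryParseError(ValueError):
    pass


@dataclass
class Trajectory:
    """Ordered frames of a constant-pH / Langevin run."""

    meta: SystemMeta
    box_length: float
    positions: np.ndarray        # (F, N, 3)
    charges: np.ndarray          # (F, N)
    ionization: np.ndarray       # (F, n_titratable)
    scalars: pd.DataFrame
    info: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a run directory (extended-XYZ + per-frame scalar CSV)."""
    if traj.n_frames == 0:
        raise TrajectoryParseError("refusing to write an empty trajectory")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    L = traj.box_length
    meta = traj.meta
    lattice = f'Lattice="{L:.6f} 0.0 0.0 0.0 {L:.6f} 0.0 0.0 0.0 {L:.6f}"'
    props = "Properties=species:S:1:pos:R:3:charge:R:1:ionized:I:1:mol:I:1"
    info_str = " ".join(f"{k}={v}" for k, v in traj.info.items()
                        if isinstance(v, (int, float, str)) and " " not in str(v))
    tit = meta.titratable_beads
    with open(out / TRAJ_FILE, "w") as fh:
        for f in range(traj.n_frames):
            ion_flags = np.zeros(meta.n_beads, dtype=np.int64)
            ion_flags[tit] = traj.ionization[f]
            cyc = int(traj.scalars["cycle"].iloc[f]) if "cycle" in traj.scalars else f
            fh.write(f"{meta.n_beads}\n")
            fh.write(f"{lattice} {props} cycle={cyc} {info_str}\n".rstrip() + "\n")
            pos = traj.positions[f]
            q = traj.charges[f]
            for a in range(meta.n_beads):
                fh.write(
                    f"{meta.labels[a]} {pos[a, 0]:.6f} {pos[a, 1]:.6f} {pos[a, 2]:.6f} "
                    f"{q[a]:.4f} {ion_flags[a]} {meta.mol_id[a]}\n"
                )
    traj.scalars.to_csv(out / SCALARS_FILE, index=False)
    return out


_LABEL_INFO = {
    # label -> (valence_when_ionized, titratable, pKa, backbone, kind)
    "MB": (0, False, math.nan, True, POLYANION),
    "MS": (-1, False, math.nan, False, POLYANION),
    "LB": (0, False, math.nan, True, OLIGOCATION),
    "LS": (+1, True, PKA_LYSINE, False, OLIGOCATION),
    "Na": (+1, False, math.nan, False, ION),
    "Cl": (-1, False, math.nan, False, ION),
}


def _meta_from_columns(labels, mol_ids) -> SystemMeta:
    labels = np.asarray(labels)
    mol_ids = np.asarray(mol_ids, dtype=np.int32)
    n = labels.shape[0]
    valence = np.zeros(n, dtype=np.int8)
    titratable = np.zeros(n, dtype=bool)
    pka = np.full(n, math.nan)
    backbone = np.zeros(n, dtype=bool)
    is_ion = np.zeros(n, dtype=bool)
    kind_by_mol: dict = {}
    for a in range(n):
        z, tit, pk, bb, kind = _LABEL_INFO.get(labels[a], (0, False, math.nan, False, ION))
        valence[a] = z
        titratable[a] = tit
        pka[a] = pk
        backbone[a] = bb
        is_ion[a] = kind == ION
        kind_by_mol.setdefault(int(mol_ids[a]), kind)
    n_mol = int(mol_ids.max()) + 1 if n else 0
    chain_kind = np.array([kind_by_mol.get(m, ION) for m in range(n_mol)])
    # bonds: rebuilt from the 2-beads-per-monomer layout of each polymer molecule
    bonds = []
    for m in range(n_mol):
        if chain_kind[m] == ION:
            continue
        idx = np.flatnonzero(mol_ids == m)
        if idx.size < 2 or idx.size % 2:   # foreign file: no 2-bead layout
            continue
        for j in range(0, idx.size, 2):
            bonds.append((idx[j], idx[j + 1]))
            if j > 0:
                bonds.append((idx[j - 2], idx[j]))
    return SystemMeta(
        labels=labels, valence=valence, titratable=titratable, pka=pka,
        mol_id=mol_ids, chain_kind=chain_kind, backbone=backbone,
        is_ion=is_ion, bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
    )


def _parse_comment(line: str):
    lattice = None
    m = re.search(r'Lattice="([^"]+)"', line)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        lattice = vals[0]
    cols = None
    m = re.search(r"Properties=(\S+)", line)
    if m:
        parts = m.group(1).split(":")
        cols = [(parts[i], parts[i + 1], int(parts[i + 2])) for i in range(0, len(parts), 3)]
    info = {}
    for key, val in re.findall(r"(\w+)=([^\s\"]+)", line):
        if key in ("Properties",):
            continue
        try:
            info[key] = int(val) if re.fullmatch(r"-?\d+", val) else float(val)
        except ValueError:
            info[key] = val
    return lattice, cols, info


def read_trajectory(path) -> Trajectory:
    """Read a run directory or a bare extended-XYZ file."""
    p = Path(path)
    xyz = p / TRAJ_FILE if p.is_dir() else p
    scalars_path = (p / SCALARS_FILE) if p.is_dir() else xyz.with_name(SCALARS_FILE)
    if not xyz.exists():
        raise TrajectoryParseError(f"no trajectory file at {xyz}")
    frames_pos, frames_q, frames_ion, cycles = [], [], [], []
    labels = mol_ids = None
    box = None
    info: dict = {}
    warned = False
    with open(xyz) as fh:
        lines = fh.readlines()
    ln = 0
    nline = len(lines)
    while ln < nline:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].strip())
        except ValueError as exc:
            raise TrajectoryParseError(f"line {ln + 1}: expected atom count") from exc
        if ln + 1 + nat >= nline + 1:
            raise TrajectoryParseError(f"line {ln + 1}: truncated frame")
        lattice, cols, finfo = _parse_comment(lines[ln + 1])
        if lattice is not None:
            box = lattice
        if not info:
            info = {k: v for k, v in finfo.items() if k not in ("cycle",)}
        col_names = [c[0] for c in cols] if cols else ["species", "pos"]
        has_ion = "ionized" in col_names
        has_q = "charge" in col_names
        has_mol = "mol" in col_names
        if not has_ion and not warned:
            logger.warning("extended-XYZ %s has no ionization column; flags default to 0", xyz)
            warned = True
        lab, pos, q, ion, mol = [], [], [], [], []
        for a in range(nat):
            parts = lines[ln + 2 + a].split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"line {ln + 3 + a}: malformed atom line")
            lab.append(parts[0])
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            c = 4
            q.append(float(parts[c]) if has_q and len(parts) > c else 0.0)
            c += 1 if has_q else 0
            ion.append(int(parts[c]) if has_ion and len(parts) > c else 0)
            c += 1 if has_ion else 0
            mol.append(int(parts[c]) if has_mol and len(parts) > c else a)
        if labels is None:
            labels, mol_ids = lab, mol
        frames_pos.append(np.array(pos))
        frames_q.append(np.array(q, dtype=np.float32))
        frames_ion.append(np.array(ion, dtype=np.int8))
        cycles.append(finfo.get("cycle", len(cycles)))
        ln += 2 + nat
    if not frames_pos:
        raise TrajectoryParseError(f"{xyz} contains no frames")
    meta = _meta_from_columns(labels, mol_ids)
    tit = meta.titratable_beads
    ionization = np.stack([fi[tit] for fi in frames_ion])
    if scalars_path.exists():
        scalars = pd.read_csv(scalars_path)
    else:
        scalars = pd.DataFrame({"cycle": cycles})
    if box is None:
        raise TrajectoryParseError(f"{xyz}: no Lattice information found")
    return Trajectory(
        meta=meta, box_length=float(box),
        positions=np.stack(frames_pos),
        charges=np.stack(frames_q),
        ionization=ionization,
        scalars=scalars, info=info,
    )
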