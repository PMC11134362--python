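"""Trajectory observables: ionization, condensation, conformation.

The central quantities mirror what one measures for an oligocation /
polyanion mixture: the degree of ionization alpha (ensemble average of the
binary protonation states), the fraction of oligocation molecules whose
centre of mass sits within a threshold distance (default 2 nm) of the
nearest polyanion bead, the per-molecule scatter of ionization versus
distance that resolves the condensed/free two-population structure, the
polyanion end-to-end distance, and a proxy for the local H+ concentration
profile around the polyanion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .system_model import InvalidArgumentError
from .trajectory import Trajectory
from .units import LN10


def _block_sem(series: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error from block averaging (>=10 blocks)."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < n_blocks:
        n_blocks = max(2, n)
    m = n // n_blocks
    if m == 0:
        return float("nan")
    blocks = series[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.std(ddof=1) / math.sqrt(n_blocks))


@dataclass
class TitrationResult:
    pH: np.ndarray
    alpha: np.ndarray
    alpha_se: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pH": self.pH, "alpha": self.alpha, "alpha_se": self.alpha_se})


@dataclass
class CondensationResult:
    fraction: float
    fraction_se: float
    threshold: float
    min_distances: np.ndarray    # (n_frames, n_molecules)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condensed_fraction": [self.fraction],
            "condensed_fraction_se": [self.fraction_se],
            "threshold_nm": [self.threshold],
        })


def degree_of_ionization(frames, n_blocks: int = 10):
    """Mean ionization over sites and frames, with a block-averaged s.e."""
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise InvalidArgumentError("degree_of_ionization needs at least one frame")
    per_frame = arr.mean(axis=1)
    return float(per_frame.mean()), _block_sem(per_frame, n_blocks)


def _mic(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def unwrap_molecule(positions: np.ndarray, beads: np.ndarray, bonds: np.ndarray,
                    L: float) -> np.ndarray:
    """Positions of one molecule made continuous across the periodic box.

    Walks the bond graph from the first bead, shifting each neighbour by the
    minimum image of its bond vector.
    """
    idx = {int(b): k for k, b in enumerate(beads)}
    out = np.empty((beads.size, 3))
    out[0] = positions[beads[0]]
    adj: dict = {k: [] for k in range(beads.size)}
    for a, b in bonds:
        a, b = int(a), int(b)
        if a in idx and b in idx:
            adj[idx[a]].append(idx[b])
            adj[idx[b]].append(idx[a])
    seen = {0}
    stack = [0]
    while stack:
        k = stack.pop()
        for nb in adj[k]:
            if nb not in seen:
                d = _mic(positions[beads[nb]] - positions[beads[k]], L)
                out[nb] = out[k] + d
                seen.add(nb)
                stack.append(nb)
    if len(seen) < beads.size:   # isolated beads (no bonds): wrap relative to first
        for k in range(beads.size):
            if k not in seen:
                out[k] = out[0] + _mic(positions[beads[k]] - positions[beads[0]], L)
    return out


def molecule_com(positions: np.ndarray, beads: np.ndarray, bonds: np.ndarray, L: float) -> np.ndarray:
    return unwrap_molecule(positions, beads, bonds, L).mean(axis=0)


def min_distance_to_polyanion(positions: np.ndarray, meta, L: float, molecule: int) -> float:
    """Minimum-image distance between an oligocation COM and the closest polyanion bead."""
    pa = np.flatnonzero(meta.polyanion_bead_mask)
    if pa.size == 0:
        raise InvalidArgumentError("no polyanion present")
    beads = meta.molecule_beads(molecule)
    com = molecule_com(positions, beads, meta.bonds, L)
    d = _mic(positions[pa] - com[None, :], L)
    return float(np.sqrt((d * d).sum(axis=1).min()))


def molecule_frame_table(traj: Trajectory) -> pd.DataFrame:
    """One row per (frame, oligocation molecule): min distance and per-molecule alpha."""
    meta = traj.meta
    L = traj.box_length
    oc_mols = meta.oligocation_mol_ids
    if np.flatnonzero(meta.polyanion_bead_mask).size == 0:
        raise InvalidArgumentError("no polyanion present")
    tit = meta.titratable_beads
    site_of_bead = {int(b): k for k, b in enumerate(tit)}
    mol_sites = {int(m): np.array([site_of_bead[int(b)] for b in meta.molecule_beads(m)
                                   if int(b) in site_of_bead]) for m in oc_mols}
    rows = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        ion = traj.ionization[f]
        for m in oc_mols:
            dist = min_distance_to_polyanion(pos, meta, L, int(m))
            sites = mol_sites[int(m)]
            alpha = float(ion[sites].mean()) if sites.size else math.nan
            rows.append((f, int(m), dist, alpha))
    return pd.DataFrame(rows, columns=["frame", "molecule", "distance", "alpha"])


def condensed_fraction(traj: Trajectory, threshold: float = 2.0,
                       table: Optional[pd.DataFrame] = None) -> CondensationResult:
    """Fraction of (molecule, frame) pairs with COM-to-polyanion distance < threshold."""
    tab = molecule_frame_table(traj) if table is None else table
    pivot = tab.pivot(index="frame", columns="molecule", values="distance").to_numpy()
    condensed = (pivot < threshold)
    per_frame = condensed.mean(axis=1)
    return CondensationResult(
        fraction=float(per_frame.mean()),
        fraction_se=_block_sem(per_frame),
        threshold=threshold,
        min_distances=pivot,
    )


def distance_resolved_ionization(traj: Trajectory, bins: Optional[np.ndarray] = None,
                                 table: Optional[pd.DataFrame] = None):
    """Binned mean per-molecule alpha and molecule-frame population vs distance.

    Returns ``(profile, scatter)``: the profile has one row per bin (alpha is
    NaN for empty bins), the scatter is the raw per-molecule-per-frame table.
    """
    tab = molecule_frame_table(traj) if table is None else table
    if bins is None:
        bins = np.arange(0.0, traj.box_length / 2.0 + 0.25, 0.25)
    bins = np.asarray(bins, dtype=float)
    which = np.digitize(tab["distance"].to_numpy(), bins) - 1
    n_bins = bins.size - 1
    pop = np.zeros(n_bins, dtype=int)
    alpha = np.full(n_bins, math.nan)
    for b in range(n_bins):
        sel = which == b
        pop[b] = int(sel.sum())
        if pop[b]:
            alpha[b] = float(tab.loc[sel, "alpha"].mean())
    profile = pd.DataFrame({
        "bin_left": bins[:-1], "bin_right": bins[1:],
        "mean_alpha": alpha, "population": pop,
    })
    return profile, tab


def end_to_end(traj: Trajectory, chain: Optional[int] = None):
    """Mean backbone end-to-end distance of the polyanion, with block s.e."""
    meta = traj.meta
    if chain is None:
        pa = np.flatnonzero(meta.chain_kind == "polyanion")
        if pa.size == 0:
            raise InvalidArgumentError("no polyanion present")
        chain = int(pa[0])
    beads = meta.molecule_beads(chain)
    bb = beads[meta.backbone[beads]]
    if bb.size < 2:
        raise InvalidArgumentError("end_to_end needs a chain with >= 2 backbone beads")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        unw = unwrap_molecule(traj.positions[f], beads, meta.bonds, traj.box_length)
        local = {int(b): k for k, b in enumerate(beads)}
        r1 = unw[local[int(bb[0])]]
        r2 = unw[local[int(bb[-1])]]
        vals[f] = float(np.linalg.norm(r2 - r1))
    return float(vals.mean()), _block_sem(vals)


def local_hplus_profile(traj: Trajectory, bins: Optional[np.ndarray] = None,
                        bulk_pH: Optional[float] = None, bjerrum_length: float = 0.71,
                        kappa: float = 0.0, n_probes: int = 2000,
                        seed: int = 0) -> pd.DataFrame:
    """Proxy local H+ concentration around the polyanion (implicit-ion mode).

    Random probe points sample the mean Debye-Hueckel potential psi of the
    polyanion configuration; c_H(r) = 10^(-bulk_pH) exp(-psi) is binned by
    distance to the nearest polyanion bead and reported also as a "local pH"
    = -log10 c_H.
    """
    meta = traj.meta
    L = traj.box_length
    if bulk_pH is None:
        bulk_pH = float(traj.info.get("pH", 7.0))
    if bins is None:
        bins = np.arange(0.0, L / 2.0 + 0.25, 0.25)
    bins = np.asarray(bins, dtype=float)
    pa = np.flatnonzero(meta.polyanion_bead_mask)
    rng = np.random.default_rng(seed)
    dists, boltz = [], []
    frame_ids = rng.integers(traj.n_frames, size=n_probes)
    probes = rng.uniform(0.0, L, size=(n_probes, 3))
    for k in range(n_probes):
        pos = traj.positions[frame_ids[k]]
        q = traj.charges[frame_ids[k]]
        d = _mic(pos[pa] - probes[k][None, :], L)
        r = np.sqrt((d * d).sum(axis=1))
        r = np.maximum(r, 1e-6)
        psi = float((q[pa] * bjerrum_length * np.exp(-kappa * r) / r).sum())
        dists.append(r.min())
        boltz.append(math.exp(-psi))
    dists = np.asarray(dists)
    boltz = np.asarray(boltz)
    which = np.digitize(dists, bins) - 1
    n_bins = bins.size - 1
    ch = np.full(n_bins, math.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            ch[b] = 10.0 ** (-bulk_pH) * boltz[sel].mean()
    return pd.DataFrame({
        "bin_left": bins[:-1], "bin_right": bins[1:],
        "c_h_molar": ch,
        "local_pH": [-math.log10(c) if c and not math.isnan(c) else math.nan for c in ch],
    })


def titration_curve(trajs: Sequence[Trajectory]) -> TitrationResult:
    """Aggregate alpha(pH) from runs at different pH values."""
    pH, a, se = [], [], []
    for t in sorted(trajs, key=lambda t: t.info.get("pH", 0.0)):
        mean, s = degree_of_ionization(t.ionization)
        pH.append(float(t.info.get("pH", math.nan)))
        a.append(mean)
        se.append(s)
    return TitrationResult(np.array(pH), np.array(a), np.array(se))
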