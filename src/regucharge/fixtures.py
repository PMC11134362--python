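"""Synthetic trajectories and titration series with the statistical structure
the analysis assumes.

``generate_mixture_trajectory`` emulates the two-population structure of an
oligocation / polyanion mixture: each molecule-frame is condensed (near the
polyanion, highly ionized) with probability f or free (far away, weakly
ionized), with distances drawn from configurable laws and per-site
ionization Bernoulli at the population's alpha.  A straight polyanion sits
at the box centre so minimum-distance computations are exact by
construction.  The on-disk format is identical to simulator output, so the
analysis code cannot distinguish the two.

``generate_titration_series`` / ``fit_titration`` produce and fit noisy
Hill-type sigmoids alpha(pH) = 1/(1 + 10^{s (pH - pKa_eff)}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .system_model import (InvalidArgumentError, OLIGOCATION, POLYANION,
                           _assemble_meta, build_topology, default_bead_specs)
from .trajectory import Trajectory


class FitError(RuntimeError):
    """Raised when titration data show no transition to fit."""


@dataclass(frozen=True)
class MixtureFixtureSpec:
    """Parameters of the condensed/free two-population generator."""

    n_molecules: int = 12
    n_frames: int = 100
    condensed_fraction: float = 0.5
    condensed_range: Tuple[float, float] = (0.3, 1.5)
    free_range: Tuple[float, float] = (8.0, 12.0)
    alpha_condensed: float = 0.95
    alpha_free: float = 0.05
    sites_per_molecule: int = 4
    polyanion_length: int = 48
    box_length: float = 25.2
    threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("condensed_fraction", "alpha_condensed", "alpha_free"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")
        if self.free_range[0] <= self.threshold:
            raise InvalidArgumentError(
                "impossible geometry: the free-population distance law reaches "
                f"inside the condensation threshold ({self.free_range[0]} <= {self.threshold} nm)"
            )
        if self.condensed_range[1] >= self.threshold:
            raise InvalidArgumentError(
                "impossible geometry: the condensed distance law exceeds the threshold"
            )
        if self.free_range[1] >= self.box_length / 2.0:
            raise InvalidArgumentError("free distance law must stay within L/2")


def generate_mixture_trajectory(spec: MixtureFixtureSpec) -> Trajectory:
    """Two-population synthetic trajectory (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    specs = default_bead_specs()
    r0 = 0.4
    L = spec.box_length
    m = spec.polyanion_length
    pa_topo = build_topology(POLYANION, m, (specs["pa_backbone"], specs["pa_side"]))
    oc_topo = build_topology(OLIGOCATION, spec.sites_per_molecule,
                             (specs["oc_backbone"], specs["oc_side"]))
    chains = [pa_topo] + [oc_topo] * spec.n_molecules
    meta = _assemble_meta(chains, [])

    pa_pos = np.empty((pa_topo.n_beads, 3))
    center = np.full(3, L / 2.0)
    for i in range(m):
        pa_pos[2 * i] = center + np.array([(i - (m - 1) / 2.0) * r0, 0.0, 0.0])
        pa_pos[2 * i + 1] = pa_pos[2 * i]   # side bead on top: distances stay exact
    n_beads = meta.n_beads
    tit = meta.titratable_beads
    F = spec.n_frames
    positions = np.empty((F, n_beads, 3))
    ionization = np.empty((F, tit.size), dtype=np.int8)
    charges = np.zeros((F, n_beads), dtype=np.float32)
    sigma_cluster = 1e-4   # molecules are near-point clusters: COM error << bin width
    for f in range(F):
        positions[f, : pa_topo.n_beads] = pa_pos
        off = pa_topo.n_beads
        for mol in range(spec.n_molecules):
            condensed = rng.random() < spec.condensed_fraction
            lo, hi = spec.condensed_range if condensed else spec.free_range
            d = rng.uniform(lo, hi)
            # perpendicular offset from a random interior backbone bead: the
            # chosen bead is then exactly the nearest polyanion bead
            bead = 2 * int(rng.integers(1, m - 1))
            theta = rng.uniform(0.0, 2 * math.pi)
            offset = np.array([0.0, d * math.cos(theta), d * math.sin(theta)])
            com = pa_pos[bead] + offset
            nb = oc_topo.n_beads
            cluster = com[None, :] + rng.normal(scale=sigma_cluster, size=(nb, 3))
            cluster -= cluster.mean(axis=0) - com
            positions[f, off: off + nb] = cluster
            alpha = spec.alpha_condensed if condensed else spec.alpha_free
            site0 = mol * spec.sites_per_molecule
            ionization[f, site0: site0 + spec.sites_per_molecule] = (
                rng.random(spec.sites_per_molecule) < alpha
            ).astype(np.int8)
            off += nb
        q = meta.valence.astype(np.float32)
        q[tit] *= ionization[f]
        charges[f] = q
    scalars = pd.DataFrame({
        "cycle": np.arange(F),
        "alpha": ionization.mean(axis=1),
        "energy": np.zeros(F),
        "acceptance": np.ones(F),
    })
    return Trajectory(meta=meta, box_length=L, positions=positions,
                      charges=charges, ionization=ionization, scalars=scalars,
                      info={"synthetic": "mixture", "seed": spec.seed})


def hill_curve(pH: np.ndarray, pka_eff: float, slope: float) -> np.ndarray:
    """alpha(pH) = 1/(1 + 10^{slope (pH - pKa_eff)}) (slope 1 = ideal base HH)."""
    return 1.0 / (1.0 + 10.0 ** (slope * (np.asarray(pH, dtype=float) - pka_eff)))


def generate_titration_series(pka_eff: float, hill_slope: float, pH_grid,
                              noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Noisy Hill-type titration series on a pH grid."""
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    pH = np.asarray(pH_grid, dtype=float)
    alpha = hill_curve(pH, pka_eff, hill_slope)
    if noise_sd > 0:
        alpha = np.clip(alpha + rng.normal(scale=noise_sd, size=pH.size), 0.0, 1.0)
    return pd.DataFrame({"pH": pH, "alpha": alpha})


def fit_titration(table: pd.DataFrame) -> Tuple[float, float]:
    """Least-squares Hill fit; returns (pKa_eff, hill_slope).

    pKa_eff is the pH at which the fitted curve crosses alpha = 0.5.  Raises
    :class:`FitError` when the data contain no transition in range.
    """
    pH = np.asarray(table["pH"], dtype=float)
    alpha = np.asarray(table["alpha"], dtype=float)
    if pH.size < 4:
        raise InvalidArgumentError("fit_titration needs >= 4 points")
    if alpha.max() < 0.55 or alpha.min() > 0.45:
        raise FitError("no ionization transition within the pH range")
    mid_guess = float(pH[np.argmin(np.abs(alpha - 0.5))])
    try:
        popt, _ = curve_fit(hill_curve, pH, alpha, p0=[mid_guess, 1.0], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"titration fit did not converge: {exc}") from exc
    pka, slope = float(popt[0]), float(popt[1])
    if slope <= 0:
        raise FitError("fitted slope is non-positive: no base-like transition")
    return pka, slope
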