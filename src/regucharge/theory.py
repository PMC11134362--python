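"""Analytic reference formulas and an exact titration enumeration oracle.

Conventions.  For a weak base the "ionized" state is the protonated,
charged one; z = +1 is the valence of the ionized form (z = -1 mirrors the
formulas for acids, whose ionized form is deprotonated).  The free-energy
cost of ionizing one site is

    Delta G / k_BT = z ln10 (pH - pKa) + z e psi / k_BT,

ideal Henderson-Hasselbalch plus the electrostatic work of creating the
charge ze at local potential psi, so that

    alpha = 1 / (1 + exp(Delta G / k_BT)).

Setting alpha = 1/2 gives the effective pKa,
pKa_eff = pKa - (e psi / k_BT)/ln10, for either sign of z: an attractive
environment (psi < 0 for a base near a polyanion) raises pKa_eff, the
self-repulsion of an isolated polybase (psi > 0) lowers it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .system_model import InvalidArgumentError
from .units import LN10


@dataclass(frozen=True)
class MeanFieldContext:
    """Inputs of the mean-field ionization formula.

    ``psi_reduced`` is the local electrostatic potential expressed as the
    reduced energy e*psi/k_BT of an elementary charge in it.
    """

    pKa: float
    z: int
    psi_reduced: float
    pH: float

    def __post_init__(self) -> None:
        if self.z not in (-1, 1):
            raise InvalidArgumentError("z must be -1 or +1")


def alpha_mean_field(ctx: MeanFieldContext) -> float:
    """Henderson-Hasselbalch degree of ionization with an electrostatic shift."""
    dg = ctx.z * (LN10 * (ctx.pH - ctx.pKa) + ctx.psi_reduced)
    return 1.0 / (1.0 + math.exp(dg)) if dg < 500 else 0.0


def pka_eff(pKa: float, z: int, psi_reduced: float) -> float:
    """Effective pKa (pH of half-ionization) of a site at local potential psi.

    pKa_eff = pKa - (e psi/k_BT)/ln10 for either z; ``z`` is validated and
    kept in the signature because the direction of the alpha shift (up or
    down in pH) is what flips with the sign of z.
    """
    if z not in (-1, 1):
        raise InvalidArgumentError("z must be -1 or +1")
    return pKa - psi_reduced / LN10


def manning_parameter(charge_spacing: float, bjerrum_length: float, counterion_valence: int = 1):
    """Manning parameter xi = lambda_B / b and the condensation criterion.

    Condensation of z-valent counterions is expected when xi exceeds 1/z
    (one elementary charge per Bjerrum length for monovalent ions; the
    threshold charge density is z-times lower for z-valent ions).
    """
    if charge_spacing <= 0:
        raise InvalidArgumentError("charge spacing must be positive")
    xi = bjerrum_length / charge_spacing
    return xi, xi > 1.0 / counterion_valence


def counterion_release_entropy(z: int) -> float:
    """T*DeltaS in k_BT gained when a z-valent ion displaces z monovalent ones: z - 1."""
    if not isinstance(z, (int, np.integer)) or z < 1:
        raise InvalidArgumentError("z must be an integer >= 1")
    return float(z - 1)


def exact_titration(n_sites: int, pair_energies: np.ndarray, pH: float, pKa: float) -> float:
    """Exact alpha by summation over all 2^N ionization microstates.

    The statistical weight of microstate s (s_i = 1 meaning ionized, i.e.
    protonated for a base) is exp(-U(s) - ln10 (pH - pKa) sum_i s_i) with
    U(s) = sum_{i<j} u_ij s_i s_j the pair interaction among ionized sites
    in k_BT.  Serves as the independent oracle for the constant-pH sampler.
    """
    if n_sites < 1:
        raise InvalidArgumentError("n_sites must be >= 1")
    if n_sites > 12:
        raise InvalidArgumentError("exact enumeration limited to n_sites <= 12")
    u = np.asarray(pair_energies, dtype=float)
    if u.shape != (n_sites, n_sites):
        raise InvalidArgumentError("pair_energies must be (N, N)")
    if not np.allclose(u, u.T):
        raise InvalidArgumentError("pair_energies must be symmetric")
    mu = LN10 * (pH - pKa)
    zsum = 0.0
    nsum = 0.0
    for code in range(1 << n_sites):
        s = np.array([(code >> i) & 1 for i in range(n_sites)], dtype=float)
        energy = 0.5 * s @ u @ s - 0.5 * (np.diag(u) * s * s).sum()
        w = math.exp(-energy - mu * s.sum())
        zsum += w
        nsum += w * s.sum()
    return nsum / (zsum * n_sites)
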