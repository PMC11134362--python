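"""Reduced units and physical constants.

The model works in reduced units: energies in units of k_BT (k_BT == 1),
lengths in nanometres, masses equal to one.  Electrostatics enter through
the Bjerrum length, lambda_B ~ 0.71 nm in water at 298 K, i.e. the
separation at which two elementary charges interact with exactly k_BT.
"""

from __future__ import annotations

import numpy as np

#: Bjerrum length of water at 298 K [nm]
BJERRUM_WATER_NM: float = 0.71

#: Avogadro's number expressed per nm^3 per (mol/L):  1 mol/L = 0.602214 nm^-3
NA_PER_NM3_PER_MOLAR: float = 0.602214076

LN10: float = float(np.log(10.0))


def number_density(conc_molar: float) -> float:
    """Particles per nm^3 at a molar concentration."""
    return conc_molar * NA_PER_NM3_PER_MOLAR


def kappa_from_ionic_strength(ionic_strength: float, bjerrum_length: float = BJERRUM_WATER_NM) -> float:
    """Inverse Debye screening length [1/nm] for a 1:1 electrolyte.

    kappa^2 = 8 pi lambda_B N_A I, with I in mol/L converted to nm^-3.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    return float(np.sqrt(8.0 * np.pi * bjerrum_length * number_density(ionic_strength)))


def box_length_from_concentration(n_monomers: int, conc_molar: float) -> float:
    """Cubic box edge [nm] holding ``n_monomers`` at a monomer molarity."""
    if conc_molar <= 0:
        raise ValueError("concentration must be positive")
    return float((n_monomers / number_density(conc_molar)) ** (1.0 / 3.0))
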