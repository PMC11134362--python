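"""Shared fixtures: small systems, force fields, and cached simulation runs."""

from __future__ import annotations

import numpy as np
import pytest

import regucharge as rc
from regucharge.system_model import PKA_LYSINE


@pytest.fixture(scope="session")
def dh_ff():
    """Study-condition force field: DH implicit ions at I = 0.01 M."""
    return rc.ForceField.from_ionic_strength(0.01)


@pytest.fixture(scope="session")
def ideal_ff():
    """Electrostatics disabled (lambda_B = 0): the ideal-gas titration limit."""
    return rc.ForceField(bjerrum_length=0.0, kappa=0.0)


def single_oligocation_state(n: int, pH: float, ff, seed: int = 0, box: float = 18.0):
    """One oligocation chain, no polyanion, in a cubic box."""
    comp = rc.SystemComposition(
        polyanion_length=n, oligocation_length=n, n_polyanion_chains=0,
        monomer_ratio=(1, 1), pH=pH, box_length=box, seed=seed,
    )
    rng = np.random.default_rng(seed)
    return rc.build_system(comp, ff, rng=rng), rng


def paper_composition(n: int, pH: float, seed: int = 0) -> rc.SystemComposition:
    """Study conditions: m = 48 polyanion + oligocations at 1:2 monomer ratio."""
    return rc.SystemComposition(oligocation_length=n, pH=pH, seed=seed)


_RUN_CACHE: dict = {}


def paper_run(n: int, pH: float, seed: int = 1, cycles: int = 3000, warmup: int = 800):
    """Cached constant-pH/LD run of the full oligocation + polyanion system."""
    key = (n, round(pH, 3), seed, cycles, warmup)
    if key not in _RUN_CACHE:
        ff = rc.ForceField.from_ionic_strength(0.01)
        comp = paper_composition(n, pH, seed)
        rng = np.random.default_rng(seed)
        state = rc.build_system(comp, ff, rng=rng)
        integ = rc.IntegratorParams()
        cph = rc.CpHParams(pH=pH, seed=seed)
        _RUN_CACHE[key] = rc.run_cph_ld(state, ff, integ, cph,
                                        n_cycles=cycles, warmup_cycles=warmup, rng=rng)
    return _RUN_CACHE[key]


def free_oligocation_run(n: int, pH: float, seed: int = 1,
                         cycles: int = 2500, warmup: int = 500):
    """Cached run of a single oligocation without polyanion (DH interactions on)."""
    key = ("free", n, round(pH, 3), seed, cycles, warmup)
    if key not in _RUN_CACHE:
        ff = rc.ForceField.from_ionic_strength(0.01)
        state, rng = single_oligocation_state(n, pH, ff, seed=seed)
        integ = rc.IntegratorParams()
        cph = rc.CpHParams(pH=pH, ld_steps_per_cycle=50, seed=seed)
        _RUN_CACHE[key] = rc.run_cph_ld(state, ff, integ, cph,
                                        n_cycles=cycles, warmup_cycles=warmup, rng=rng)
    return _RUN_CACHE[key]


def hh_alpha(pH: float, pKa: float = PKA_LYSINE) -> float:
    """Ideal Henderson-Hasselbalch ionization of a base."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))
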