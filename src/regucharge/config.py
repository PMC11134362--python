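"""Single structured config file (TOML) for composition, force field and sampling.

Every model default is representable here; `default_config` returns the
study conditions used throughout: m = 48 polyanion, 1:2 oligocation to
polyanion monomer ratio, I = 0.01 M, pKa = 10.68, Debye-Hueckel implicit
ions.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional

from .cph import CpHParams
from .energetics import ForceField
from .langevin import IntegratorParams
from .system_model import PKA_LYSINE, SystemComposition
from .units import kappa_from_ionic_strength


def default_config() -> dict:
    return {
        "composition": {
            "polyanion_length": 48,
            "oligocation_length": 8,
            "n_polyanion_chains": 1,
            "monomer_ratio": [1, 2],
            "ionic_strength": 0.01,
            "polyanion_monomer_concentration": 5e-3,
            "box_length": 0.0,            # 0 -> derived from concentration
        },
        "forcefield": {
            "wca_epsilon": 1.0,
            "sigma": 0.35,
            "bond_k": 400.0,
            "bond_r0": 0.4,
            "bjerrum_length": 0.71,
            "electrostatics_mode": "debye_hueckel_implicit_ions",
            "dh_cutoff_factor": 4.0,
            "ewald_accuracy": 1e-5,
        },
        "sampling": {
            "pKa": PKA_LYSINE,
            "dt": 0.005,
            "gamma": 1.0,
            "ld_steps_per_cycle": 100,
            "moves_per_cycle": 0,         # 0 -> one move per titratable site
            "n_cycles": 6000,
            "warmup_cycles": 1000,
        },
    }


def load_config(path) -> dict:
    cfg = default_config()
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values)
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)


def dump_config(cfg: dict, path) -> None:
    lines = []
    for section, values in cfg.items():
        lines.append(f"[{section}]")
        for k, v in values.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def composition_from_config(cfg: dict, pH: float, seed: int = 0) -> SystemComposition:
    c = cfg["composition"]
    return SystemComposition(
        polyanion_length=int(c["polyanion_length"]),
        oligocation_length=int(c["oligocation_length"]),
        n_polyanion_chains=int(c["n_polyanion_chains"]),
        monomer_ratio=tuple(c["monomer_ratio"]),
        ionic_strength=float(c["ionic_strength"]),
        pH=pH,
        polyanion_monomer_concentration=float(c["polyanion_monomer_concentration"]),
        box_length=float(c["box_length"]) or None,
        seed=seed,
    )


def forcefield_from_config(cfg: dict) -> ForceField:
    f = cfg["forcefield"]
    kappa = kappa_from_ionic_strength(float(cfg["composition"]["ionic_strength"]),
                                      float(f["bjerrum_length"]))
    return ForceField(
        wca_epsilon=float(f["wca_epsilon"]),
        sigma=float(f["sigma"]),
        bond_k=float(f["bond_k"]),
        bond_r0=float(f["bond_r0"]),
        bjerrum_length=float(f["bjerrum_length"]),
        electrostatics_mode=f["electrostatics_mode"],
        kappa=kappa,
        dh_cutoff_factor=float(f["dh_cutoff_factor"]),
        ewald_accuracy=float(f.get("ewald_accuracy", 1e-5)),
    )


def sampling_from_config(cfg: dict, pH: float, seed: int = 0):
    s = cfg["sampling"]
    integ = IntegratorParams(dt=float(s["dt"]), gamma=float(s["gamma"]), seed=seed)
    cph = CpHParams(
        pH=pH, pKa=float(s["pKa"]),
        moves_per_cycle=int(s["moves_per_cycle"]) or None,
        ld_steps_per_cycle=int(s["ld_steps_per_cycle"]),
        seed=seed,
    )
    return integ, cph, int(s["n_cycles"]), int(s["warmup_cycles"])
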