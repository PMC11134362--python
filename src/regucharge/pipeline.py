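"""pH-sweep orchestration: build -> sample -> analyze per (pH, seed),
aggregated observable tables and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (composition_from_config, default_config,
                     forcefield_from_config, sampling_from_config)
from .cph import run_cph_ld
from .observables import (condensed_fraction, degree_of_ionization, end_to_end,
                          molecule_frame_table)
from .system_model import build_system
from .trajectory import Trajectory, write_trajectory

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunManifest:
    config: dict
    seeds: list
    code_version: str = __version__
    runs: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config, "seeds": self.seeds,
            "code_version": self.code_version, "runs": self.runs,
            "outputs": self.outputs,
        }, indent=2, default=str))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], seeds=d["seeds"],
                   code_version=d["code_version"], runs=d["runs"],
                   outputs=d["outputs"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_single(cfg: dict, pH: float, seed: int,
               out_dir=None, n_cycles: Optional[int] = None,
               warmup_cycles: Optional[int] = None) -> Trajectory:
    """One build -> constant-pH/LD run at a single (pH, seed)."""
    comp = composition_from_config(cfg, pH=pH, seed=seed)
    ff = forcefield_from_config(cfg)
    integ, cph, nc, wc = sampling_from_config(cfg, pH=pH, seed=seed)
    n_cycles = n_cycles or nc
    warmup_cycles = warmup_cycles if warmup_cycles is not None else wc
    rng = np.random.default_rng(seed)
    state = build_system(comp, ff, rng=rng)
    traj = run_cph_ld(state, ff, integ, cph, n_cycles, warmup_cycles, rng=rng)
    if out_dir is not None:
        write_trajectory(traj, out_dir)
    return traj


def analyze_run(traj: Trajectory, threshold: float = 2.0) -> dict:
    """Scalar observables of one run."""
    alpha, alpha_se = degree_of_ionization(traj.ionization)
    row = {"alpha": alpha, "alpha_se": alpha_se}
    if traj.meta.polyanion_bead_mask.any():
        tab = molecule_frame_table(traj)
        cond = condensed_fraction(traj, threshold=threshold, table=tab)
        ree, ree_se = end_to_end(traj)
        row.update({
            "condensed_fraction": cond.fraction,
            "condensed_fraction_se": cond.fraction_se,
            "end_to_end": ree,
            "end_to_end_se": ree_se,
        })
    return row


def sweep(cfg: Optional[dict], pH_list: Sequence[float], seeds: Sequence[int],
          out_dir=None, threshold: float = 2.0,
          n_cycles: Optional[int] = None, warmup_cycles: Optional[int] = None,
          write_trajectories: bool = False):
    """Run the full pipeline over a pH grid and seeds.

    Returns ``(manifest, tables)`` where ``tables`` maps observable names to
    aggregated per-pH DataFrames (across-seed mean and s.e.).  A failing
    (pH, seed) point is recorded in the manifest and the sweep continues.
    """
    cfg = cfg or default_config()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seeds=list(map(int, seeds)))
    rows = []
    for pH in pH_list:
        for seed in seeds:
            run_dir = None
            if out is not None and write_trajectories:
                run_dir = out / f"pH{pH:g}_seed{seed}"
            entry = {"pH": float(pH), "seed": int(seed), "dir": str(run_dir) if run_dir else None}
            try:
                traj = run_single(cfg, pH=float(pH), seed=int(seed), out_dir=run_dir,
                                  n_cycles=n_cycles, warmup_cycles=warmup_cycles)
                row = {"pH": float(pH), "seed": int(seed), **analyze_run(traj, threshold)}
                rows.append(row)
                entry["status"] = "ok"
                if run_dir is not None:
                    entry["checksums"] = {p.name: _sha256(p) for p in sorted(run_dir.iterdir())}
            except Exception as exc:  # record and continue remaining points
                logger.error("sweep point pH=%s seed=%s failed: %s", pH, seed, exc)
                entry["status"] = f"failed: {exc}"
                entry["traceback"] = traceback.format_exc()
            manifest.runs.append(entry)
    per_run = pd.DataFrame(rows)
    tables = {"per_run": per_run}
    if not per_run.empty:
        aggs = {}
        for col in ("alpha", "condensed_fraction", "end_to_end"):
            if col in per_run:
                g = per_run.groupby("pH")[col]
                aggs[col] = pd.DataFrame({
                    f"{col}_mean": g.mean(),
                    f"{col}_se": g.sem().fillna(0.0),
                }).reset_index()
        tables.update(aggs)
    if out is not None:
        for name, tab in tables.items():
            p = out / f"{name}.csv"
            tab.to_csv(p, index=False)
            manifest.outputs[name] = {"path": str(p), "sha256": _sha256(p)}
        manifest.to_json(out / "manifest.json")
    return manifest, tables
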