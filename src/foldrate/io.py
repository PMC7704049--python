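"""File formats: PDB snapshots, TSV tables, condition grids, run manifests.

All tabular outputs are TSV with headers, UTF-8, "." decimal.  PDB input is
reduced to CA traces (standard residues, altloc "A" preferred); a
multi-model PDB yields one snapshot per model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .contacts import ContactMap, ContactParams, NativeStructure, SubstructureDecomposition
from .kinetics import StateTrajectory
from .thermo import EnsembleTable, SamplingCondition

__all__ = [
    "read_snapshot_pdb",
    "read_native_structure",
    "write_ca_pdb",
    "write_contact_map",
    "read_contact_map",
    "write_trajectories",
    "read_trajectories",
    "write_ensemble",
    "read_ensemble",
    "write_conditions",
    "read_conditions",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_snapshot_pdb(path) -> List[np.ndarray]:
    """Per-model CA coordinate arrays from a PDB file.

    Only CA atoms of standard (non-hetero) residues are used; where
    alternate locations exist, altloc "A" (or blank) is preferred.  Residues
    are renumbered 0-based and contiguous; gaps in author numbering produce
    a warning, not an error.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("snap", str(path))
    models = []
    for model in structure:
        coords = []
        last_resseq = None
        gap = False
        for chain in model:
            for res in chain:
                if res.id[0] != " ":
                    continue  # hetero / water
                if "CA" not in res:
                    continue
                atom = res["CA"]
                if atom.is_disordered():
                    try:
                        atom = atom.disordered_get("A")
                    except KeyError:
                        atom = atom.disordered_get_list()[0]
                if last_resseq is not None and res.id[1] != last_resseq + 1:
                    gap = True
                last_resseq = res.id[1]
                coords.append(atom.coord)
        if not coords:
            raise ValueError(f"no CA atoms found in {path}")
        if gap:
            warnings.warn(
                f"chain breaks in {path}; residues renumbered contiguously",
                stacklevel=2,
            )
        models.append(np.asarray(coords, dtype=float))
    return models


def read_native_structure(path) -> NativeStructure:
    """First model of a PDB file as a NativeStructure."""
    return NativeStructure(read_snapshot_pdb(path)[0], source=str(path))


def write_ca_pdb(path, models: Sequence[np.ndarray]) -> None:
    """Write CA traces as a (multi-model) PDB file; coordinates to 1e-3 A."""
    lines = []
    multi = len(models) > 1
    for m, coords in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i, (x, y, z) in enumerate(coords):
            lines.append(
                f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def write_contact_map(
    path, cmap: ContactMap, decomposition: Optional[SubstructureDecomposition] = None
) -> None:
    """TSV `i  j  substructure` (dash for unassigned contacts)."""
    label_of = {}
    if decomposition is not None:
        for sub in decomposition.substructures:
            for pair in sub.contacts:
                label_of[pair] = sub.label
    rows = [(i, j, label_of.get((i, j), "-")) for i, j in sorted(cmap.pairs)]
    pd.DataFrame(rows, columns=["i", "j", "substructure"]).to_csv(
        path, sep="\t", index=False
    )


def read_contact_map(path, params: Optional[ContactParams] = None) -> Tuple[ContactMap, Dict[str, frozenset]]:
    df = pd.read_csv(path, sep="\t")
    pairs = frozenset((int(r.i), int(r.j)) for r in df.itertuples())
    groups: Dict[str, set] = {}
    for r in df.itertuples():
        if r.substructure != "-":
            groups.setdefault(str(r.substructure), set()).add((int(r.i), int(r.j)))
    return (
        ContactMap(pairs, params or ContactParams()),
        {k: frozenset(v) for k, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Trajectories and ensembles
# ---------------------------------------------------------------------------

def write_trajectories(path, trajs: Sequence[StateTrajectory]) -> None:
    """TSV `trajectory_id  temperature  mc_step  config`."""
    rows = []
    for t in trajs:
        for k, lab in enumerate(t.labels):
            rows.append((t.trajectory_id, t.T, int(k * t.dt), lab))
    pd.DataFrame(
        rows, columns=["trajectory_id", "temperature", "mc_step", "config"]
    ).to_csv(path, sep="\t", index=False)


def read_trajectories(path) -> List[StateTrajectory]:
    """Parse a trajectory TSV; the snapshot interval must be constant within
    each trajectory (inferred from consecutive mc_step differences)."""
    df = pd.read_csv(path, sep="\t", dtype={"config": str})
    trajs = []
    for (tid, T), grp in df.groupby(["trajectory_id", "temperature"], sort=False):
        grp = grp.sort_values("mc_step")
        steps = grp["mc_step"].to_numpy()
        diffs = np.diff(steps)
        if len(diffs) == 0:
            raise ValueError(f"trajectory {tid!r} has a single snapshot")
        if not np.all(diffs == diffs[0]):
            raise ValueError(
                f"trajectory {tid!r} has a non-constant snapshot interval"
            )
        trajs.append(
            StateTrajectory(
                trajectory_id=str(tid),
                T=float(T),
                dt=float(diffs[0]),
                labels=tuple(grp["config"].astype(str)),
            )
        )
    return trajs


def write_ensemble(path, table: EnsembleTable) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def read_ensemble(
    path, conditions: Dict[str, SamplingCondition], burn_in: float = 0.125
) -> EnsembleTable:
    df = pd.read_csv(path, sep="\t", dtype={"config": str, "condition_id": str})
    return EnsembleTable(rows=df, conditions=conditions, burn_in=burn_in)


def write_conditions(path, conditions: Sequence[SamplingCondition]) -> None:
    data = [
        {"id": c.condition_id, "T": c.T, "S": c.S, "k_bias": c.k_bias}
        for c in conditions
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_conditions(path) -> Dict[str, SamplingCondition]:
    data = yaml.safe_load(Path(path).read_text())
    out = {}
    for entry in data:
        cid = str(entry["id"])
        out[cid] = SamplingCondition(
            T=float(entry["T"]),
            S=float(entry.get("S", 0.0)),
            k_bias=float(entry.get("k_bias", 0.0)),
            condition_id=cid,
        )
    return out


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI invocation."""

    command: str
    config: Dict = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    version: str = ""
    started: float = field(default_factory=time.time)

    def add_input(self, path) -> None:
        p = Path(path)
        if p.is_file():
            self.inputs[str(p)] = _sha256(p)

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["elapsed_s"] = time.time() - self.started
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
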