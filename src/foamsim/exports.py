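"""File exports: cycle time series (CSV), lattices (legacy VTK, CSV), manifests.

All writers are deterministic: a fixed run configuration and seed reproduce
byte-identical files.  Floats are printed with 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from foamsim.config import RunConfig, config_hash, dump_config

__all__ = ["export_timeseries", "export_lattice", "export_lattice_csv",
           "write_manifest"]

_FMT = "%.9g"


def export_timeseries(result, path) -> Path:
    """Write a CycleResult history as CSV.

    Column order is fixed: ``t_s,T_K,z,eps_total,eps_S,eps_viscous,sigma_Pa,
    step_id``; one row per recorded time point (number of steps + 1).
    """
    df = result.data
    if len(df) == 0:
        raise ValueError("empty cycle result")
    path = Path(path)
    cols = ["t_s", "T_K", "z", "eps_total", "eps_S", "eps_viscous", "sigma_Pa",
            "step_id"]
    with open(path, "w", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        for row in df[cols].itertuples(index=False):
            vals = [_FMT % v for v in row[:-1]] + [str(int(row[-1]))]
            fh.write(",".join(vals) + "\n")
    return path


def export_lattice(lattice, path, displacements: np.ndarray | None = None) -> Path:
    """Write a lattice (optionally deformed) as legacy ASCII VTK POLYDATA.

    ``displacements`` is a flat per-dof vector (6 per node, translations
    first) or an (n_nodes, 3) array added to the node coordinates.
    """
    nodes = np.asarray(lattice.nodes, dtype=float)
    edges = np.asarray(lattice.ligaments)
    if displacements is not None:
        disp = np.asarray(displacements, dtype=float)
        if disp.ndim == 1:
            disp = disp.reshape(-1, 6)[:, :3]
        nodes = nodes + disp
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("foamsim open-cell lattice\n")
        fh.write("ASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for xyz in nodes:
            fh.write(" ".join(_FMT % c for c in xyz) + "\n")
        fh.write(f"LINES {len(edges)} {3 * len(edges)}\n")
        for i, j in edges:
            fh.write(f"2 {int(i)} {int(j)}\n")
    return path


def export_lattice_csv(lattice, node_path, edge_path) -> tuple[Path, Path]:
    """Plain CSV node and edge tables for a lattice."""
    node_path, edge_path = Path(node_path), Path(edge_path)
    with open(node_path, "w", newline="") as fh:
        fh.write("node_id,x_m,y_m,z_m\n")
        for i, xyz in enumerate(lattice.nodes):
            fh.write(f"{i}," + ",".join(_FMT % c for c in xyz) + "\n")
    with open(edge_path, "w", newline="") as fh:
        fh.write("ligament_id,node_i,node_j,length_m\n")
        lengths = lattice.ligament_lengths()
        for k, ((i, j), L) in enumerate(zip(lattice.ligaments, lengths)):
            fh.write(f"{k},{int(i)},{int(j)},{_FMT % L}\n")
    return node_path, edge_path


def write_manifest(path, cfg: RunConfig, seed: int, version: str,
                   outputs: list | None = None) -> Path:
    """Reproducibility manifest: config hash + dump, seed, package version."""
    path = Path(path)
    manifest = {
        "foamsim_version": version,
        "seed": int(seed),
        "config_sha256": config_hash(cfg),
        "config_toml": dump_config(cfg),
        "outputs": [str(o) for o in (outputs or [])],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
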