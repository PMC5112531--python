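"""File interfaces: profile CSVs, YAML configs, legacy-VTK frame export."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mechanics.mesh import BilayerMesh
from .mechanics.solver import SimConfig, SimResult


def save_profiles(result: SimResult, path: str | Path) -> None:
    """Write the recorded top-surface profiles as tidy CSV
    (frame, time, g, x, height)."""
    rows = []
    for i in range(len(result.times)):
        rows.append(pd.DataFrame({
            "frame": i, "time": result.times[i], "g": result.g[i],
            "x": result.top_x[i], "height": result.top_h[i]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def load_profile(path: str | Path, frame: int = -1):
    """Read one frame's (x, height) profile back from a profile CSV."""
    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    sel = df[df["frame"] == frames[frame]]
    return sel["x"].to_numpy(), sel["height"].to_numpy()


def load_config(path: str | Path) -> SimConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return SimConfig(**data)


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=True)


def write_vtk(mesh: BilayerMesh, x: np.ndarray, path: str | Path,
              cell_data: dict | None = None) -> None:
    """Write a deformed mesh frame as a legacy-ASCII VTK unstructured grid.

    ``cell_data`` maps names to per-element scalar arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    pts = np.column_stack([x, np.zeros(len(x))]) if x.shape[1] == 2 else x
    npe = mesh.elements.shape[1]
    ctype = 9 if npe == 4 else 12  # VTK_QUAD / VTK_HEXAHEDRON
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nbilayer growth frame\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        np.savetxt(f, pts, fmt="%.9g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (npe + 1)}\n")
        np.savetxt(f, np.column_stack(
            [np.full(mesh.n_elements, npe), mesh.elements]), fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, ctype), fmt="%d")
        data = {"layer": mesh.layer.astype(float),
                "special": mesh.special.astype(float)}
        data.update(cell_data or {})
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in data.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.9g")
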