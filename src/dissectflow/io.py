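"""Snapshot and table output: HDF5 flow snapshots, legacy-VTK grid export,
CSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .grid import MaskedGrid
from .solver import FlowField

__all__ = ["save_snapshot", "load_snapshot", "export_vtk"]


def save_snapshot(path: str | Path, grid: MaskedGrid, field: FlowField,
                  **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=field.u)
        f.create_dataset("v", data=field.v)
        f.create_dataset("p", data=field.p)
        f.create_dataset("mask", data=grid.fluid.astype(np.uint8))
        f.create_dataset("lumen", data=grid.lumen_label)
        f.attrs["time"] = field.time
        f.attrs["spacing_mm"] = grid.spacing
        for k, v in attrs.items():
            if v is not None:
                f.attrs[k] = v


def load_snapshot(path: str | Path) -> tuple[FlowField, dict]:
    with h5py.File(path, "r") as f:
        fld = FlowField(float(f.attrs["time"]), f["u"][...], f["v"][...],
                        f["p"][...])
        attrs = dict(f.attrs)
    return fld, attrs


def export_vtk(path: str | Path, grid: MaskedGrid,
               field: Optional[FlowField] = None) -> None:
    """Legacy ASCII VTK structured-points file with the fluid mask, lumen
    labels and, when a field is given, cell-center pressure and velocity."""
    nx, ny = grid.nx, grid.ny
    h = grid.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        "dissectflow masked grid",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 2",
        "ORIGIN 0 0 0",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {nx * ny}",
    ]

    def scalar(name, arr, fmt="%d"):
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(fmt % v for v in arr[:, j]) for j in range(ny))

    scalar("mask", grid.fluid.astype(int))
    scalar("lumen", grid.lumen_label.astype(int))
    if field is not None:
        scalar("pressure", field.p, fmt="%.6g")
        uc = 0.5 * (field.u[:-1] + field.u[1:])
        vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])
        scalar("u", uc, fmt="%.6g")
        scalar("v", vc, fmt="%.6g")
    Path(path).write_text("\n".join(lines) + "\n")
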