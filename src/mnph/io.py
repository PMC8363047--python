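"""Config loading and field/table export.

Configs are YAML mappings validated against a known-key schema by the
pipeline driver.  Volumetric fields are exported as legacy-ASCII VTK
structured points (cell data), readable by ParaView and friends.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .tissue import VoxelGrid


class ConfigError(ValueError):
    """Raised when a run configuration contains unknown or invalid keys."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    """JSON run manifest echoing every resolved parameter."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_vtk_cells(path: str | Path, grid: VoxelGrid,
                    arrays: Mapping[str, np.ndarray]) -> None:
    """Write per-voxel arrays on a grid as a legacy-ASCII VTK file.

    Each array must match the grid shape; NaNs (exterior) are written as
    -1e30 so viewers can threshold them away.
    """
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "mnph voxel fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} "
        f"{grid.origin[2]:.9g}",
        f"SPACING {grid.spacing:.9g} {grid.spacing:.9g} {grid.spacing:.9g}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in arrays.items():
        if arr.shape != grid.shape:
            raise ValueError(f"array {name!r} does not match grid shape")
        flat = np.asarray(arr, dtype=float).ravel(order="F")
        flat = np.where(np.isfinite(flat), flat, -1e30)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")
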