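"""Coefficient contour maps: back-mapping PLS coefficients onto the grid.

The display quantity is the standard CoMFA STDEV*COEFF product: each retained
descriptor column contributes its regression coefficient times its standard
deviation over the training compounds, placed at its grid point (dropped
columns carry zero).  Points in the upper percentile tail of the nonzero
values mark regions where more field (bulk, or positive potential) favors
activity; the lower tail marks unfavorable regions.  Grids are exported as
Gaussian cube or OpenDX files for any standard molecular viewer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fields import DescriptorMatrix, GridSpec
from .pls import PlsModel

__all__ = [
    "ContourSet",
    "coefficient_grid",
    "contour_regions",
    "export_contours",
    "write_cube",
    "read_cube",
    "write_dx",
    "read_dx",
    "contour_summary",
]

BOHR_PER_ANGSTROM = 1.8897259886


@dataclass
class ContourSet:
    field_type: str  # steric | electrostatic
    values: np.ndarray  # per-grid-point STDEV*COEFF, zeros at dropped points
    favorable_mask: np.ndarray
    unfavorable_mask: np.ndarray
    thresholds: tuple[float, float]  # (low percentile, high percentile)


def coefficient_grid(
    model: PlsModel,
    descriptors: DescriptorMatrix,
    X_train: np.ndarray,
    field_type: str,
) -> np.ndarray:
    """STDEV*COEFF value at every grid point for one field type."""
    values = np.zeros(descriptors.grid.n_points)
    stds = np.asarray(X_train, dtype=float).std(axis=0)
    any_of_type = False
    for j, (ftype, point) in enumerate(descriptors.columns):
        if ftype != field_type:
            continue
        any_of_type = True
        values[point] = model.coefficients[j] * stds[j]
    if not any_of_type:
        raise ValueError(f"no retained {field_type} columns in the descriptor matrix")
    return values


def contour_regions(
    values: np.ndarray, low_pct: float = 20.0, high_pct: float = 80.0
) -> tuple[np.ndarray, np.ndarray]:
    """Masks of favorable (upper tail) and unfavorable (lower tail) points.

    Percentiles are taken over the nonzero values only, so dropped (zero)
    points never enter either mask.  All-zero input yields two empty masks.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    values = np.asarray(values, dtype=float)
    nonzero = values != 0
    if not nonzero.any():
        empty = np.zeros(values.shape, dtype=bool)
        return empty, empty.copy()
    lo = np.percentile(values[nonzero], low_pct)
    hi = np.percentile(values[nonzero], high_pct)
    favorable = (values > hi) & nonzero
    unfavorable = (values < lo) & nonzero
    return favorable, unfavorable


def build_contour_set(
    model: PlsModel,
    descriptors: DescriptorMatrix,
    X_train: np.ndarray,
    field_type: str,
    low_pct: float = 20.0,
    high_pct: float = 80.0,
) -> ContourSet:
    values = coefficient_grid(model, descriptors, X_train, field_type)
    fav, unfav = contour_regions(values, low_pct, high_pct)
    return ContourSet(field_type, values, fav, unfav, (low_pct, high_pct))


def _grid_reshaped(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Internal x-fastest flat order -> (nx, ny, nz) array."""
    nx, ny, nz = grid.dims
    return values.reshape(nz, ny, nx).transpose(2, 1, 0)


def write_cube(values: np.ndarray, grid: GridSpec, path) -> None:
    """Gaussian cube file (lengths in Bohr; canonical z-fastest value order).

    A single placeholder carbon at the grid origin satisfies readers that
    insist on an atom block.
    """
    nx, ny, nz = grid.dims
    b = BOHR_PER_ANGSTROM
    ox, oy, oz = (v * b for v in grid.origin)
    step = grid.spacing * b
    arr = _grid_reshaped(np.asarray(values, dtype=float), grid)
    with open(path, "w") as fh:
        fh.write("triazqsar coefficient grid\nSTDEV*COEFF values\n")
        fh.write(f"{1:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        fh.write(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}\n")
        fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}\n")
        fh.write(f"{6:5d}{0.0:12.6f}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        flat = arr.ravel()  # x slowest, z fastest
        for start in range(0, flat.size, 6):
            fh.write("".join(f"{v:13.5e}" for v in flat[start : start + 6]) + "\n")


def read_cube(path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        lines = fh.read().split("\n")
    natoms = int(lines[2].split()[0])
    origin = tuple(float(v) / BOHR_PER_ANGSTROM for v in lines[2].split()[1:4])
    dims = []
    spacing = None
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(int(parts[0]))
        step = float(parts[1 + k]) / BOHR_PER_ANGSTROM
        if spacing is None:
            spacing = step
    nx, ny, nz = dims
    data = []
    for line in lines[6 + natoms :]:
        data.extend(float(v) for v in line.split())
    arr = np.array(data).reshape(nx, ny, nz)
    values = arr.transpose(2, 1, 0).ravel()  # back to x-fastest flat order
    grid = GridSpec(origin=origin, spacing=float(spacing), dims=(nx, ny, nz))
    return values, grid


def write_dx(values: np.ndarray, grid: GridSpec, path) -> None:
    """OpenDX scalar grid (lengths in Angstrom; z-fastest value order)."""
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    arr = _grid_reshaped(np.asarray(values, dtype=float), grid)
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {s:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {s:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx*ny*nz} data follows\n"
        )
        flat = arr.ravel()
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def read_dx(path) -> tuple[np.ndarray, GridSpec]:
    dims = None
    origin = None
    spacing = None
    data: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("object 1"):
                dims = tuple(int(v) for v in line.split()[-3:])
            elif line.startswith("origin"):
                origin = tuple(float(v) for v in line.split()[1:4])
            elif line.startswith("delta") and spacing is None:
                spacing = float(line.split()[1])
            elif line.startswith("object 3"):
                n_items = int(line.split()[-3])
            elif n_items is not None and len(data) < n_items and line and not line.startswith("attribute"):
                data.extend(float(v) for v in line.split())
    nx, ny, nz = dims
    arr = np.array(data).reshape(nx, ny, nz)
    values = arr.transpose(2, 1, 0).ravel()
    return values, GridSpec(origin=origin, spacing=spacing, dims=dims)


def export_contours(
    contour: ContourSet, grid: GridSpec, path_prefix, fmt: str = "cube"
) -> list[Path]:
    """Write the value grid plus the two masks (as 0/1 grids)."""
    if fmt == "cube":
        writer, ext = write_cube, ".cube"
    elif fmt == "dx":
        writer, ext = write_dx, ".dx"
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'cube' or 'dx')")
    prefix = Path(str(path_prefix))
    written = []
    for suffix, values in [
        ("_values", contour.values),
        ("_favorable", contour.favorable_mask.astype(float)),
        ("_unfavorable", contour.unfavorable_mask.astype(float)),
    ]:
        target = prefix.with_name(prefix.name + suffix + ext)
        writer(values, grid, target)
        written.append(target)
    return written


def contour_summary(contours: Sequence[ContourSet], grid: GridSpec) -> dict:
    """Counts and centroids of the favorable/unfavorable regions per field."""
    pts = grid.points()
    out: dict = {}
    for c in contours:
        entry: dict = {}
        for name, mask in [("favorable", c.favorable_mask), ("unfavorable", c.unfavorable_mask)]:
            count = int(mask.sum())
            entry[name] = {
                "n_points": count,
                "centroid": pts[mask].mean(axis=0).tolist() if count else None,
            }
        out[c.field_type] = entry
    return out


def save_summary(contours: Sequence[ContourSet], grid: GridSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(contour_summary(contours, grid), fh, indent=2)
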