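"""CoMFA-style molecular interaction fields on a common rectangular grid.

Two probe energies are evaluated at every point of an axis-aligned lattice
enclosing the aligned series:

* electrostatic — Coulomb interaction of a +1 e point charge with the atomic
  partial charges under a distance-dependent dielectric eps(r) = r, i.e.
  E(p) = sum_i k q_i / r_ip^2 with k = 332.06 kcal*A/(mol*e^2);
* steric — a 12-6 Lennard-Jones interaction of an sp3-carbon probe
  (R = 1.5 A, eps = 0.105 kcal/mol) with per-element parameters combined by
  Lorentz-Berthelot rules: E(p) = sum_i eps_ij [(R_ij/r_ip)^12 - 2 (R_ij/r_ip)^6].

Both fields are truncated to +/-30 kcal/mol so near-atom singularities cannot
dominate the regression; the truncated, 50/50-weighted grids concatenated per
compound form the descriptor matrix of the PLS stage.

Grid point order is fixed and documented: x fastest, then y, then z
(flat index = ix + nx*iy + nx*ny*iz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .prep import Conformer3D

__all__ = [
    "GridSpec",
    "FieldConfig",
    "FieldBlock",
    "DescriptorMatrix",
    "VDW_PARAMS",
    "make_grid",
    "electrostatic_field",
    "steric_field",
    "truncate_field",
    "compute_field_block",
    "assemble_descriptor_matrix",
]

# Per-element 12-6 parameters (R_min/2 in Angstrom, well depth in kcal/mol),
# UFF-derived: half the homonuclear van der Waals minimum distance and the
# corresponding well depth.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.4430, 0.044),
    "C": (1.9255, 0.105),
    "N": (1.8300, 0.069),
    "O": (1.7500, 0.060),
    "F": (1.6820, 0.050),
    "S": (2.0175, 0.274),
    "Cl": (1.9735, 0.227),
    "Br": (2.0945, 0.251),
    "I": (2.2350, 0.339),
    "P": (2.0735, 0.305),
}


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectangular lattice; point order x fastest, then y, then z."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) coordinates in the documented flat order."""
        nx, ny, nz = self.dims
        ox, oy, oz = self.origin
        xs = ox + self.spacing * np.arange(nx)
        ys = oy + self.spacing * np.arange(ny)
        zs = oz + self.spacing * np.arange(nz)
        ZZ, YY, XX = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.column_stack([XX.ravel(), YY.ravel(), ZZ.ravel()])

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "dims": list(self.dims),
            "point_order": "x fastest, then y, then z",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["origin"]), float(d["spacing"]), tuple(d["dims"]))


@dataclass(frozen=True)
class FieldConfig:
    """Probe and truncation settings of both fields."""

    probe_charge: float = 1.0  # e
    coulomb_constant: float = 332.06  # kcal*A/(mol*e^2)
    steric_probe_radius: float = 1.5  # A
    steric_probe_epsilon: float = 0.105  # kcal/mol (sp3 carbon)
    truncation: float = 30.0  # kcal/mol
    steric_weight: float = 0.5
    electrostatic_weight: float = 0.5
    distance_floor: float = 0.05  # A; truncation makes the exact value irrelevant
    variance_floor: float = 1e-6  # kcal/mol; columns below are dropped

    def __post_init__(self):
        if self.truncation <= 0:
            raise ValueError("truncation must be positive")
        if abs(self.steric_weight + self.electrostatic_weight - 1.0) > 1e-9:
            raise ValueError("field weights must sum to 1")


@dataclass
class FieldBlock:
    """Truncated per-grid-point energies for one compound (one descriptor row)."""

    compound_id: int
    steric: np.ndarray
    electrostatic: np.ndarray


@dataclass
class DescriptorMatrix:
    """Weighted, variance-filtered field descriptors for a compound set.

    ``columns`` retains, per kept column, the field type and flat grid-point
    index so PLS coefficients can be mapped back onto the grid.
    """

    compound_ids: list[int]
    X: np.ndarray  # (n_compounds, n_kept_columns)
    columns: list[tuple[str, int]]
    grid: GridSpec
    config: FieldConfig

    def row_for(self, compound_id: int) -> np.ndarray:
        return self.X[self.compound_ids.index(compound_id)]


def make_grid(
    conformers: Sequence[Conformer3D], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Bounding box of all atoms padded by ``margin``, snapped to the lattice."""
    if not conformers:
        raise ValueError("empty conformer set")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.vstack([c.coords for c in conformers])
    lo = np.floor((coords.min(axis=0) - margin) / spacing) * spacing
    hi = np.ceil((coords.max(axis=0) + margin) / spacing) * spacing
    dims = tuple(int(round((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), dims=dims)


def _distances(conformer: Conformer3D, grid: GridSpec, floor: float) -> np.ndarray:
    """(n_atoms, n_points) interatomic distances, floored near the nuclei."""
    pts = grid.points()
    diff = conformer.coords[:, None, :] - pts[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    return np.maximum(r, floor)


def truncate_field(vector: np.ndarray, limit: float) -> np.ndarray:
    """Elementwise clamp to [-limit, +limit]; idempotent."""
    if limit <= 0:
        raise ValueError("truncation limit must be positive")
    return np.clip(vector, -limit, limit)


def electrostatic_field(
    conformer: Conformer3D,
    grid: GridSpec,
    config: FieldConfig = FieldConfig(),
    truncate: bool = True,
) -> np.ndarray:
    """Coulomb energy of the +1 e probe under eps(r) = r screening.

    Linear in the atomic charges before truncation.
    """
    if conformer.charges is None:
        raise ValueError(f"compound {conformer.compound_id} has no charges")
    r = _distances(conformer, grid, config.distance_floor)
    energy = config.coulomb_constant * config.probe_charge * (
        conformer.charges[:, None] / r**2
    ).sum(axis=0)
    return truncate_field(energy, config.truncation) if truncate else energy


def steric_field(
    conformer: Conformer3D,
    grid: GridSpec,
    config: FieldConfig = FieldConfig(),
    truncate: bool = True,
) -> np.ndarray:
    """12-6 Lennard-Jones energy of the carbon probe against every atom."""
    unknown = sorted(set(conformer.symbols) - set(VDW_PARAMS))
    if unknown:
        raise ValueError(f"unparameterized element(s) {unknown}")
    radii = np.array([VDW_PARAMS[s][0] for s in conformer.symbols])
    eps = np.array([VDW_PARAMS[s][1] for s in conformer.symbols])
    r_ij = radii + config.steric_probe_radius  # Lorentz (arithmetic on radii)
    eps_ij = np.sqrt(eps * config.steric_probe_epsilon)  # Berthelot (geometric)
    r = _distances(conformer, grid, config.distance_floor)
    ratio6 = (r_ij[:, None] / r) ** 6
    energy = (eps_ij[:, None] * (ratio6**2 - 2.0 * ratio6)).sum(axis=0)
    return truncate_field(energy, config.truncation) if truncate else energy


def compute_field_block(
    conformer: Conformer3D, grid: GridSpec, config: FieldConfig = FieldConfig()
) -> FieldBlock:
    return FieldBlock(
        compound_id=conformer.compound_id,
        steric=steric_field(conformer, grid, config),
        electrostatic=electrostatic_field(conformer, grid, config),
    )


def assemble_descriptor_matrix(
    blocks: Sequence[FieldBlock],
    grid: GridSpec,
    config: FieldConfig = FieldConfig(),
    variance_floor: float | None = None,
) -> DescriptorMatrix:
    """Stack weighted [steric | electrostatic] rows and drop flat columns.

    Columns whose standard deviation across compounds falls below the floor
    carry no information and would destabilize centering/scaling in PLS.
    """
    if not blocks:
        raise ValueError("no field blocks")
    n = grid.n_points
    for b in blocks:
        if len(b.steric) != n or len(b.electrostatic) != n:
            raise ValueError(f"grid mismatch for compound {b.compound_id}")
    floor = config.variance_floor if variance_floor is None else variance_floor
    X_full = np.array(
        [
            np.concatenate(
                [config.steric_weight * b.steric, config.electrostatic_weight * b.electrostatic]
            )
            for b in blocks
        ]
    )
    columns_full = [("steric", i) for i in range(n)] + [
        ("electrostatic", i) for i in range(n)
    ]
    keep = X_full.std(axis=0) >= floor
    return DescriptorMatrix(
        compound_ids=[b.compound_id for b in blocks],
        X=X_full[:, keep],
        columns=[c for c, k in zip(columns_full, keep) if k],
        grid=grid,
        config=config,
    )
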