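"""Synthetic descriptor/activity data with a planted field-activity signal.

The generator mimics what the field engine hands to PLS: per-molecule grids of
truncated, spatially correlated energies.  Each molecule is a random linear
mix of a small set of spatially smoothed basis fields (a latent-factor model:
a congeneric series varies along a few structural directions, and its fields
inherit that low intrinsic dimensionality), and a sparse coefficient vector
with a contiguous support region in grid space defines the ground-truth
linear relationship y = X w + eps.  Coefficient recovery, component selection
and contour extraction can then be tested against a known answer without
touching any real structure.  Spatial smoothing (3-point moving average in
3D) gives the columns the short-range correlation of real molecular fields;
i.i.d. columns would make the tests unrealistically easy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.ndimage import uniform_filter

__all__ = ["SyntheticQsar", "generate_synthetic_qsar", "generate_toy_molecules"]


@dataclass
class SyntheticQsar:
    X: np.ndarray  # (n_mol, n_descriptors), clamped to +/-30
    y: np.ndarray
    true_coefficients: np.ndarray
    support: np.ndarray  # indices of the k nonzero coefficients
    grid_dims: tuple[int, int, int]
    noise_sd: float
    seed: int
    n_latent: int = 0


def _contiguous_support(dims: tuple[int, int, int], k: int, rng: np.random.Generator) -> np.ndarray:
    """Grow a connected region of k cells from a random seed cell (BFS order)."""
    nx, ny, nz = dims
    start = (
        int(rng.integers(nx)),
        int(rng.integers(ny)),
        int(rng.integers(nz)),
    )
    chosen: list[tuple[int, int, int]] = [start]
    seen = {start}
    frontier = [start]
    while len(chosen) < k and frontier:
        cell = frontier.pop(0)
        neighbors = []
        for axis in range(3):
            for step in (-1, 1):
                nb = list(cell)
                nb[axis] += step
                if 0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz:
                    neighbors.append(tuple(nb))
        rng.shuffle(neighbors)
        for nb in neighbors:
            if nb not in seen and len(chosen) < k:
                seen.add(nb)
                chosen.append(nb)
                frontier.append(nb)
    if len(chosen) < k:
        raise ValueError(f"cannot place a contiguous support of {k} cells in {dims}")
    # flat index in the x-fastest order used throughout
    return np.array(sorted(ix + nx * iy + nx * ny * iz for ix, iy, iz in chosen))


def generate_synthetic_qsar(
    n_mol: int = 25,
    grid_dims: tuple[int, int, int] = (5, 5, 5),
    k_support: int = 10,
    effect_scale: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    n_latent: int | None = None,
) -> SyntheticQsar:
    """Draw smoothed, clamped pseudo-field descriptors and a planted response.

    Defaults mirror the real modelling problem's shape: 25 molecules on a
    small grid, a 10-point active region, activity noise well below the
    response spread.  ``n_latent`` controls the intrinsic dimensionality of
    the descriptor rows; the default grows with the series size (small series
    explore few structural directions, large series many) and is capped by
    the descriptor count.
    """
    if n_mol < 4:
        raise ValueError("need at least 4 molecules")
    nx, ny, nz = grid_dims
    n_desc = nx * ny * nz
    if k_support > n_desc:
        raise ValueError("support larger than the descriptor count")
    if n_latent is None:
        n_latent = min(n_desc, max(4, n_mol - 10))
    if n_latent < 1:
        raise ValueError("n_latent must be >= 1")
    rng = np.random.default_rng(seed)
    basis = np.empty((n_latent, n_desc))
    for b in range(n_latent):
        raw = rng.normal(size=(nz, ny, nx))
        smooth = uniform_filter(raw, size=3, mode="nearest").ravel()  # x fastest
        basis[b] = smooth / smooth.std()
    loadings = rng.normal(size=(n_mol, n_latent))
    # entry sd ~= 6 kcal/mol, so the +/-30 clamp is a genuine but rare event
    # and the exact low-rank structure survives for the noiseless tests
    X = np.clip((loadings @ basis) * (6.0 / np.sqrt(n_latent)), -30.0, 30.0)
    support = _contiguous_support(grid_dims, k_support, rng)
    w = np.zeros(n_desc)
    w[support] = (
        effect_scale * rng.choice([-1.0, 1.0], size=k_support) * rng.uniform(0.5, 1.5, size=k_support)
    )
    y = X @ w + rng.normal(0.0, noise_sd, size=n_mol)
    return SyntheticQsar(
        X, y, w, support, tuple(grid_dims), float(noise_sd), int(seed), int(n_latent)
    )


# Substituents for the toy series: small rigid groups on a benzene core.
_TOY_GROUPS = ["F", "Cl", "Br", "C", "O", "N", "C#N", "OC"]


def generate_toy_molecules(n: int, seed: int = 0) -> list[tuple[int, Chem.Mol]]:
    """Small rigid benzene derivatives for fast end-to-end smoke runs.

    Returns (id, molecule) pairs; every member shares the benzene scaffold.
    Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    combos = [""]  # bare benzene first
    for g1 in _TOY_GROUPS:
        combos.append(g1)
    for g1 in _TOY_GROUPS:
        for g2 in _TOY_GROUPS:
            combos.append((g1, g2))
    if n > len(combos):
        raise ValueError(f"at most {len(combos)} distinct toy molecules available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    mols: list[tuple[int, Chem.Mol]] = []
    for rank, idx in enumerate(order[:n], start=1):
        combo = combos[idx]
        if combo == "":
            smiles = "c1ccccc1"
        elif isinstance(combo, str):
            smiles = f"c1ccc({combo})cc1"
        else:
            smiles = f"c1cc({combo[0]})ccc1{combo[1]}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise RuntimeError(f"toy SMILES failed: {smiles}")
        mols.append((rank, mol))
    return mols
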