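"""3D conformer generation, partial charges and common-scaffold alignment.

Every library member shares nine rigid heavy atoms: the aromatic triazine
ring, the two exocyclic nitrogens (NH2 and anilino NH) and the carbon of the
C6-aryl ring attached to the triazine.  One minimum-energy conformer is built
per compound (multi-start ETKDG embedding + MMFF94 minimization, UFF when MMFF
lacks parameters), Gasteiger-Marsili or MMFF charges are assigned, and the set
is rigidly superposed on those scaffold atoms by least-squares (Kabsch)
fitting onto a reference compound — by default the most potent member of the
series, compound 101.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Conformer3D",
    "AlignmentResult",
    "SCAFFOLD_SMARTS",
    "embed_minimize",
    "assign_charges",
    "kabsch_transform",
    "align_to_reference",
    "write_aligned_sdf",
    "read_aligned_sdf",
]

# Nine shared scaffold heavy atoms, in a fixed match order:
# NH2 nitrogen, then the six triazine ring atoms, the C6-aryl attachment
# carbon, and the anilino NH nitrogen.
SCAFFOLD_SMARTS = "[NX3;H2]-c1nc(-[#6])nc(-[NX3;H1])n1"
_SCAFFOLD_QUERY = Chem.MolFromSmarts(SCAFFOLD_SMARTS)


@dataclass
class Conformer3D:
    """A single minimized 3D conformer with optional per-atom charges."""

    compound_id: int
    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    charges: np.ndarray | None = None  # elementary charge units
    energy: float | None = None  # kcal/mol (force-field)
    mol: Chem.Mol | None = field(default=None, repr=False)

    def with_coords(self, coords: np.ndarray) -> "Conformer3D":
        new = Conformer3D(
            compound_id=self.compound_id,
            symbols=list(self.symbols),
            coords=np.asarray(coords, dtype=float),
            charges=None if self.charges is None else self.charges.copy(),
            energy=self.energy,
            mol=self.mol,
        )
        return new


@dataclass
class AlignmentResult:
    conformers: list[Conformer3D]
    reference_id: int
    scaffold_atom_map: dict[int, list[int]]
    scaffold_rmsd: dict[int, float]


def _conformer_from_mol(mol: Chem.Mol, conf_id: int, compound_id: int,
                        energy: float | None) -> Conformer3D:
    conf = mol.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=float)
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    single = Chem.Mol(mol)
    single.RemoveAllConformers()
    new_conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        new_conf.SetAtomPosition(i, xyz.tolist())
    single.AddConformer(new_conf, assignId=True)
    return Conformer3D(compound_id, symbols, coords, energy=energy, mol=single)


def embed_minimize(
    mol: Chem.Mol,
    compound_id: int = 0,
    seed: int = 2020,
    n_starts: int = 20,
) -> Conformer3D:
    """Lowest-energy conformer among ``n_starts`` embeddings.

    Each ETKDG embedding is locally minimized with MMFF94 (UFF if the molecule
    is outside MMFF's parameterization) and the arg-min by force-field energy
    is returned.  Deterministic for a fixed seed (single-threaded embedding).
    """
    work = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(work, numConfs=int(n_starts), params=params)
    if not conf_ids:
        raise RuntimeError(f"conformer embedding failed for compound {compound_id}")
    if AllChem.MMFFHasAllMoleculeParams(work):
        results = AllChem.MMFFOptimizeMoleculeConfs(work, numThreads=1, maxIters=2000)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(work, numThreads=1, maxIters=2000)
    energies = [e for _converged, e in results]
    best = int(np.argmin(energies))
    return _conformer_from_mol(work, list(conf_ids)[best], compound_id, energies[best])


def assign_charges(conformer: Conformer3D, scheme: str = "gasteiger") -> Conformer3D:
    """Attach per-atom partial charges (sums to the net formal charge)."""
    if conformer.mol is None:
        raise ValueError("conformer carries no molecule to charge")
    mol = conformer.mol
    if scheme == "gasteiger":
        AllChem.ComputeGasteigerCharges(mol)
        charges = np.array(
            [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()], dtype=float
        )
    elif scheme == "mmff":
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise ValueError(
                f"MMFF parameterization failed for compound {conformer.compound_id}"
            )
        charges = np.array(
            [props.GetMMFFPartialCharge(i) for i in range(mol.GetNumAtoms())],
            dtype=float,
        )
    else:
        raise ValueError(f"unknown charge scheme {scheme!r}")
    if not np.all(np.isfinite(charges)):
        raise ValueError(
            f"non-finite charge for compound {conformer.compound_id} ({scheme})"
        )
    conformer.charges = charges
    return conformer


def scaffold_match(mol: Chem.Mol, scaffold_smarts: str | None = None) -> list[int]:
    """Indices of the shared scaffold atoms, in SMARTS match order."""
    query = (
        _SCAFFOLD_QUERY
        if scaffold_smarts is None
        else Chem.MolFromSmarts(scaffold_smarts)
    )
    if query is None:
        raise ValueError(f"invalid scaffold SMARTS {scaffold_smarts!r}")
    match = mol.GetSubstructMatch(query)
    if not match:
        raise ValueError("shared scaffold not found")
    return list(match)


def kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid (rotation + translation) mapping of mobile onto target.

    Returns (R, t) with ``mobile @ R.T + t`` minimizing RMSD to ``target``.
    Proper rotation only (reflections are excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def align_to_reference(
    conformers: Sequence[Conformer3D],
    reference_id: int | None = None,
    scaffold_smarts: str | None = None,
) -> AlignmentResult:
    """Superpose every conformer's scaffold atoms onto the reference's.

    ``reference_id`` defaults to the first conformer; the pipeline passes the
    most active compound of the series.  ``scaffold_smarts`` overrides the
    triazine-diamine scaffold for other congeneric sets (e.g. the toy benzene
    series).
    """
    if not conformers:
        raise ValueError("empty conformer set")
    by_id = {c.compound_id: c for c in conformers}
    if reference_id is None:
        reference_id = conformers[0].compound_id
    if reference_id not in by_id:
        raise ValueError(f"reference compound {reference_id} not in the set")

    atom_map: dict[int, list[int]] = {}
    for conf in conformers:
        if conf.mol is None:
            raise ValueError(f"compound {conf.compound_id} has no molecule graph")
        atom_map[conf.compound_id] = scaffold_match(conf.mol, scaffold_smarts)

    ref = by_id[reference_id]
    ref_scaffold = ref.coords[atom_map[reference_id]]

    aligned: list[Conformer3D] = []
    rmsds: dict[int, float] = {}
    for conf in conformers:
        mobile = conf.coords[atom_map[conf.compound_id]]
        R, t = kabsch_transform(mobile, ref_scaffold)
        new_coords = conf.coords @ R.T + t
        moved = conf.with_coords(new_coords)
        if moved.mol is not None:
            moved.mol = Chem.Mol(conf.mol)
            mol_conf = moved.mol.GetConformer()
            for i, xyz in enumerate(new_coords):
                mol_conf.SetAtomPosition(i, xyz.tolist())
        delta = new_coords[atom_map[conf.compound_id]] - ref_scaffold
        rmsds[conf.compound_id] = float(np.sqrt((delta**2).sum(axis=1).mean()))
        aligned.append(moved)
    return AlignmentResult(aligned, reference_id, atom_map, rmsds)


def write_aligned_sdf(conformers: Sequence[Conformer3D], path) -> None:
    """Multi-record SDF with charges and energy stored as properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for conf in conformers:
            if conf.mol is None:
                raise ValueError(f"compound {conf.compound_id} has no molecule graph")
            mol = Chem.Mol(conf.mol)
            mol.SetProp("_Name", str(conf.compound_id))
            mol.SetIntProp("compound_id", conf.compound_id)
            if conf.energy is not None:
                mol.SetDoubleProp("ff_energy_kcal", conf.energy)
            if conf.charges is not None:
                mol.SetProp(
                    "partial_charges", " ".join(f"{q:.6f}" for q in conf.charges)
                )
            writer.write(mol)
    finally:
        writer.close()


def read_aligned_sdf(path) -> list[Conformer3D]:
    out: list[Conformer3D] = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=False):
        if mol is None:
            raise ValueError(f"unreadable SDF record in {path}")
        cid = mol.GetIntProp("compound_id")
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = None
        if mol.HasProp("partial_charges"):
            charges = np.array(
                [float(x) for x in mol.GetProp("partial_charges").split()]
            )
        energy = mol.GetDoubleProp("ff_energy_kcal") if mol.HasProp("ff_energy_kcal") else None
        out.append(Conformer3D(cid, symbols, coords, charges, energy, mol))
    return out
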