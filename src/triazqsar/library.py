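"""Combinatorial enumeration of the 6,N2-diaryl-1,3,5-triazine-2,4-diamine library.

The library is a congeneric series on a fixed scaffold: a fully aromatic
1,3,5-triazine carrying an exocyclic NH2 at C4, an N-aryl amine at C2 and an
aryl group at C6.  Each member is defined by two substituent tokens, R1 (the
C6 aryl) and R2 (the N2 aryl), written the way medicinal chemists abbreviate
them ("4-MeOC6H4", "2-Thienyl", ...).  This module maps tokens to attachable
fragments, assembles and sanitizes the molecules with RDKit, and provides the
structure-level oracles (Hill formula, elemental mass percentages) used to
validate the assembly against combustion-analysis figures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

__all__ = [
    "SubstituentSpec",
    "CompoundRecord",
    "SUBSTITUENTS",
    "parse_library_table",
    "assemble_structure",
    "molecular_formula",
    "elemental_composition",
    "build_library",
    "load_table1",
    "write_structures",
    "read_structures",
]

# Scaffold: 2-amino-4-(N-aryl-amino)-6-aryl-1,3,5-triazine.  {r1} is spliced in
# at C6 and {r2} on the anilino nitrogen; fragments open their ring with digit
# 9 (8 for a second ring) so closures never collide with the triazine's.
SCAFFOLD_TEMPLATE = "Nc1nc({r1})nc(N{r2})n1"


@dataclass(frozen=True)
class SubstituentSpec:
    """One R-group token and its attachable fragment.

    ``fragment`` is a SMILES piece whose first atom is the attachment point,
    valid when spliced into a branch of the scaffold template.
    """

    token: str
    fragment: str
    ring_kind: str  # phenyl | thienyl | pyridyl


def _phenyl(token: str, fragment: str) -> SubstituentSpec:
    return SubstituentSpec(token, fragment, "phenyl")


# Token vocabulary of the substituent table.  Regiochemistry follows the token:
# the fragment's first (attachment) atom is ring position 1, so e.g. the ortho
# substituent sits on the ring atom adjacent to it.
SUBSTITUENTS: dict[str, SubstituentSpec] = {
    s.token: s
    for s in [
        _phenyl("Ph", "c9ccccc9"),
        _phenyl("2-FC6H4", "c9ccccc9F"),
        _phenyl("3-FC6H4", "c9cc(F)ccc9"),
        _phenyl("4-FC6H4", "c9ccc(F)cc9"),
        _phenyl("2-ClC6H4", "c9ccccc9Cl"),
        _phenyl("3-ClC6H4", "c9cc(Cl)ccc9"),
        _phenyl("4-ClC6H4", "c9ccc(Cl)cc9"),
        _phenyl("4-BrC6H4", "c9ccc(Br)cc9"),
        _phenyl("3-MeC6H4", "c9cc(C)ccc9"),
        _phenyl("4-MeC6H4", "c9ccc(C)cc9"),
        _phenyl("2-MeOC6H4", "c9ccccc9OC"),
        _phenyl("4-MeOC6H4", "c9ccc(OC)cc9"),
        _phenyl("4-CF3OC6H4", "c9ccc(OC(F)(F)F)cc9"),
        _phenyl("4-CF3C6H4", "c9ccc(C(F)(F)F)cc9"),
        _phenyl("4-iPrC6H4", "c9ccc(C(C)C)cc9"),
        _phenyl("4-tBuC6H4", "c9ccc(C(C)(C)C)cc9"),
        _phenyl("4-Me2NC6H4", "c9ccc(N(C)C)cc9"),
        _phenyl("4-BnOC6H4", "c9ccc(OCc8ccccc8)cc9"),
        SubstituentSpec("2-Thienyl", "c9cccs9", "thienyl"),
        SubstituentSpec("3-Pyridyl", "c9cccnc9", "pyridyl"),
    ]
}

# IUPAC standard atomic weights (conventional values), enough significant
# figures to reproduce 2-decimal combustion-analysis percentages.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.90447,
    "P": 30.973762,
}


@dataclass
class CompoundRecord:
    """One library member: id, its two substituents and the assembled structure."""

    id: int
    r1: SubstituentSpec
    r2: SubstituentSpec
    smiles: str | None = None
    formula: str | None = None
    mw: float | None = None
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)


class UnknownSubstituentError(KeyError):
    pass


def parse_library_table(rows: Iterable[tuple[int, str, str]]) -> list[CompoundRecord]:
    """Turn (id, r1_token, r2_token) rows into compound stubs.

    Unknown tokens and duplicate ids raise instead of being skipped, so a
    transcription error in the substituent table cannot silently shrink the
    library.
    """
    records: list[CompoundRecord] = []
    seen: set[int] = set()
    for row_no, (cid, r1_token, r2_token) in enumerate(rows, start=1):
        cid = int(cid)
        if cid in seen:
            raise ValueError(f"duplicate compound id {cid} (row {row_no})")
        seen.add(cid)
        for token in (r1_token, r2_token):
            if token not in SUBSTITUENTS:
                raise UnknownSubstituentError(
                    f"unknown substituent token {token!r} in row {row_no} (id {cid})"
                )
        records.append(
            CompoundRecord(id=cid, r1=SUBSTITUENTS[r1_token], r2=SUBSTITUENTS[r2_token])
        )
    if not records:
        raise ValueError("empty library table")
    return records


def assemble_structure(r1: SubstituentSpec, r2: SubstituentSpec) -> Chem.Mol:
    """Attach R1 at the triazine C6 aryl position and R2 on the anilino N."""
    smiles = SCAFFOLD_TEMPLATE.format(r1=r1.fragment, r2=r2.fragment)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(
            f"assembly produced an invalid structure for ({r1.token}, {r2.token})"
        )
    Chem.SanitizeMol(mol)
    return mol


def molecular_formula(mol: Chem.Mol) -> str:
    """Hill-order molecular formula (C, H, then alphabetical)."""
    return rdMolDescriptors.CalcMolFormula(mol)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = match.end()
        counts[match.group(1)] = counts.get(match.group(1), 0) + int(match.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def elemental_composition(formula: str) -> dict[str, float]:
    """Mass percent of each element; sums to 100 by construction.

    This is the oracle for combustion ("Anal. calcd") figures: round to two
    decimals to compare with printed C/H/N percentages.
    """
    counts = parse_formula(formula)
    unknown = set(counts) - set(ATOMIC_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown element symbol(s) {sorted(unknown)} in {formula!r}")
    total = sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    return {el: 100.0 * ATOMIC_WEIGHTS[el] * n / total for el, n in counts.items()}


def load_packaged_table(name: str, **kwargs) -> pd.DataFrame:
    """Read one of the packaged TSV fixtures by file name."""
    with resources.files("triazqsar.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t", **kwargs)


def load_table1(path=None) -> pd.DataFrame:
    """Packaged substituent/viability table (one row per library member)."""
    if path is not None:
        return pd.read_csv(path, sep="\t")
    return load_packaged_table("table1_viability.tsv")


def build_library(table: pd.DataFrame | None = None) -> list[CompoundRecord]:
    """Enumerate the full library: parse tokens, assemble, canonicalize.

    Populates smiles (canonical), Hill formula and molecular weight on every
    record.
    """
    if table is None:
        table = load_table1()
    rows = list(zip(table["compound_id"], table["r1_token"], table["r2_token"]))
    records = parse_library_table(rows)
    for rec in records:
        mol = assemble_structure(rec.r1, rec.r2)
        rec.mol = mol
        rec.smiles = Chem.MolToSmiles(mol)
        rec.formula = molecular_formula(mol)
        rec.mw = Descriptors.MolWt(mol)
    return records


def write_structures(records: Sequence[CompoundRecord], path, fmt: str = "smi") -> None:
    """Write the library as a SMILES list (``smiles<tab>id``) or V2000 SDF."""
    path = str(path)
    if fmt == "smi":
        with open(path, "w") as handle:
            for rec in records:
                handle.write(f"{rec.smiles}\t{rec.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(path)
        try:
            for rec in records:
                mol = rec.mol if rec.mol is not None else Chem.MolFromSmiles(rec.smiles)
                mol = Chem.Mol(mol)
                mol.SetProp("_Name", str(rec.id))
                mol.SetIntProp("compound_id", rec.id)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'smi' or 'sdf')")


def read_structures(path, fmt: str = "smi") -> list[tuple[int, str]]:
    """Round-trip reader: returns (id, canonical smiles) pairs."""
    path = str(path)
    out: list[tuple[int, str]] = []
    if fmt == "smi":
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                smiles, cid = line.split()
                out.append((int(cid), Chem.CanonSmiles(smiles)))
    elif fmt == "sdf":
        for mol in Chem.SDMolSupplier(path):
            if mol is None:
                raise ValueError(f"unreadable SDF record in {path}")
            out.append((mol.GetIntProp("compound_id"), Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'smi' or 'sdf')")
    return out
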