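"""Core molecular model: a light graph of atoms and bonds plus the
perception utilities every other module consumes.

The graph keeps hydrogens implicit (each heavy atom carries its hydrogen
count); explicit hydrogen coordinates are materialized only inside the
coordinate builder. RDKit is the single chemistry engine behind parsing,
canonicalization, aromaticity and InChI, so fragment keys produced at
library-build time and at query time always live in the same dialect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Hybridization",
    "StereoParity",
    "BondOrder",
    "Atom",
    "Bond",
    "MolecularGraph",
    "ParseError",
    "parse_smiles",
    "read_smiles_file",
    "canonical_smiles",
    "canonical_atom_order",
    "perceive_hybridization",
    "inchikey",
    "to_rdkit",
    "from_rdkit",
    "read_sdf",
    "write_sdf",
]


class ParseError(ValueError):
    """Raised when a SMILES or SDF record cannot be interpreted."""


class Hybridization(enum.Enum):
    SP = "sp"
    SP2 = "sp2"
    SP3 = "sp3"
    OTHER = "other"


class StereoParity(enum.Enum):
    NONE = "none"
    CLOCKWISE = "clockwise"
    COUNTERCLOCKWISE = "counterclockwise"


class BondOrder(enum.Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


_RDKIT_BOND = {
    BondOrder.SINGLE: Chem.BondType.SINGLE,
    BondOrder.DOUBLE: Chem.BondType.DOUBLE,
    BondOrder.TRIPLE: Chem.BondType.TRIPLE,
    BondOrder.AROMATIC: Chem.BondType.AROMATIC,
}
_FROM_RDKIT_BOND = {v: k for k, v in _RDKIT_BOND.items()}

_CHIRAL_TAG = {
    StereoParity.NONE: Chem.ChiralType.CHI_UNSPECIFIED,
    StereoParity.CLOCKWISE: Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    StereoParity.COUNTERCLOCKWISE: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
}
_FROM_CHIRAL_TAG = {v: k for k, v in _CHIRAL_TAG.items()}


@dataclass
class Atom:
    """One heavy atom. ``num_h`` is the implicit hydrogen count and
    ``coords`` (Angstrom) is present only once the atom has been placed."""

    element: str
    formal_charge: int = 0
    is_aromatic: bool = False
    num_h: int = 0
    stereo_parity: StereoParity = StereoParity.NONE
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
                raise ValueError(f"bad coordinates for atom {self.element}")


@dataclass
class Bond:
    a: int
    b: int
    order: BondOrder = BondOrder.SINGLE
    in_ring: bool = False
    rotatable: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("bond endpoints must differ")

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a


class MolecularGraph:
    """A connected molecule: ordered heavy atoms, bonds, optional 3D coords.

    The graph retains the RDKit molecule it was derived from (sans
    conformer) so that canonicalization, substructure matching and stereo
    bookkeeping all run on one consistent chemistry object.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Sequence[Bond],
        source_id: Optional[str] = None,
        _rdkit: Optional[Chem.Mol] = None,
    ) -> None:
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.source_id = source_id
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise ValueError(f"bond ({b.a},{b.b}) indexes beyond {n} atoms")
        self._adj: list[list[int]] = [[] for _ in range(n)]
        self._bond_idx: dict[tuple[int, int], int] = {}
        for bi, b in enumerate(self.bonds):
            self._adj[b.a].append(b.b)
            self._adj[b.b].append(b.a)
            self._bond_idx[(min(b.a, b.b), max(b.a, b.b))] = bi
        for nb in self._adj:
            nb.sort()
        self._rdkit_cache = _rdkit

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_coords(self) -> bool:
        return self.n_atoms > 0 and all(a.coords is not None for a in self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        return self._adj[idx]

    def degree(self, idx: int) -> int:
        return len(self._adj[idx])

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        bi = self._bond_idx.get((min(i, j), max(i, j)))
        return None if bi is None else self.bonds[bi]

    def bond_index(self, i: int, j: int) -> Optional[int]:
        return self._bond_idx.get((min(i, j), max(i, j)))

    def coords_array(self) -> np.ndarray:
        if not self.has_coords:
            raise ValueError("molecule has no complete coordinate set")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, source_id: Optional[str] = None) -> "MolecularGraph":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularGraph(atoms, [replace(b) for b in self.bonds],
                              source_id or self.source_id, _rdkit=self._rdkit_cache)

    # -- RDKit bridge ----------------------------------------------------
    def rdkit(self) -> Chem.Mol:
        """The backing RDKit molecule (heavy atoms, no conformer)."""
        if self._rdkit_cache is None:
            self._rdkit_cache = _build_rdkit(self)
        return self._rdkit_cache


def _build_rdkit(mol: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetIsAromatic(a.is_aromatic)
        ra.SetChiralTag(_CHIRAL_TAG[a.stereo_parity])
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.a, b.b, _RDKIT_BOND[b.order])
        rw.GetBondBetweenAtoms(b.a, b.b).SetIsAromatic(b.order is BondOrder.AROMATIC)
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    return m


def from_rdkit(rdmol: Chem.Mol, source_id: Optional[str] = None) -> MolecularGraph:
    """Convert an RDKit molecule (explicit hydrogens folded away, stereo
    perceived from 3D when a conformer is present) into a MolecularGraph."""
    m = Chem.Mol(rdmol)
    if m.GetNumConformers() > 0:
        Chem.AssignStereochemistryFrom3D(m)
    m = rdmolops.RemoveHs(m)
    Chem.AssignStereochemistry(m, cleanIt=True, force=True)
    conf = m.GetConformer() if m.GetNumConformers() > 0 else None
    atoms = []
    for a in m.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            coords = np.array([p.x, p.y, p.z])
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                is_aromatic=a.GetIsAromatic(),
                num_h=a.GetTotalNumHs(),
                stereo_parity=_FROM_CHIRAL_TAG.get(a.GetChiralTag(), StereoParity.NONE),
                coords=coords,
            )
        )
    bonds = []
    for b in m.GetBonds():
        bonds.append(
            Bond(
                a=b.GetBeginAtomIdx(),
                b=b.GetEndAtomIdx(),
                order=_FROM_RDKIT_BOND.get(b.GetBondType(), BondOrder.SINGLE),
                in_ring=b.IsInRing(),
            )
        )
    name = source_id
    if name is None and m.HasProp("_Name"):
        name = m.GetProp("_Name") or None
    bare = Chem.Mol(m)
    bare.RemoveAllConformers()
    return MolecularGraph(atoms, bonds, source_id=name, _rdkit=bare)


def to_rdkit(mol: MolecularGraph, with_coords: bool = False) -> Chem.Mol:
    """RDKit molecule for *mol*; attaches a conformer when requested."""
    m = Chem.Mol(mol.rdkit())
    if with_coords:
        conf = Chem.Conformer(mol.n_atoms)
        for i, a in enumerate(mol.atoms):
            if a.coords is None:
                raise ValueError(f"atom {i} has no coordinates")
            conf.SetAtomPosition(i, [float(x) for x in a.coords])
        conf.Set3D(True)
        m.RemoveAllConformers()
        m.AddConformer(conf, assignId=True)
    return m


# -- parsing and canonical forms ----------------------------------------

def parse_smiles(smiles: str, name: Optional[str] = None) -> MolecularGraph:
    """Parse one SMILES string into a connected MolecularGraph.

    Stereo annotations are preserved; multi-component inputs are rejected
    because every downstream operation assumes a connected graph.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"could not parse SMILES: {smiles!r}")
    if len(rdmolops.GetMolFrags(rdmol)) != 1:
        raise ParseError(f"multi-component SMILES not supported: {smiles!r}")
    return from_rdkit(rdmol, source_id=name)


def read_smiles_file(path) -> Iterator[MolecularGraph]:
    """Iterate molecules from a file of one SMILES per line, with an
    optional whitespace-separated name. Blank lines are skipped."""
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"line{ln}"
        yield parse_smiles(smiles, name=name)


def canonical_smiles(mol: MolecularGraph) -> str:
    """Canonical isomeric SMILES; invariant under input atom reordering."""
    return Chem.MolToSmiles(mol.rdkit())


def canonical_atom_order(mol: MolecularGraph) -> tuple[str, list[int]]:
    """Canonical SMILES plus the atom order it implies.

    Returns ``(smiles, order)`` where ``order[k]`` is the graph atom index
    sitting at position *k* of the canonical string (the atom order a fresh
    parse of that string would produce). This is what lets stored template
    coordinates — serialized in canonical order — be mapped back onto the
    atoms of any query molecule with the same key.
    """
    m = Chem.Mol(mol.rdkit())
    smi = Chem.MolToSmiles(m)
    order = list(
        map(int, m.GetProp("_smilesAtomOutputOrder").strip("[]").rstrip(",").split(","))
    )
    return smi, order


def perceive_hybridization(mol: MolecularGraph, atom_idx: int) -> Hybridization:
    """Hybridization from the graph alone (no coordinate dependence).

    sp: a triple bond, or two or more double bonds (cumulene-like).
    sp2: aromatic, or exactly one double bond.
    sp3: any other bonding pattern on a common organic element.
    """
    atom = mol.atoms[atom_idx]
    n_double = n_triple = 0
    for j in mol.neighbors(atom_idx):
        order = mol.bond_between(atom_idx, j).order
        if order is BondOrder.DOUBLE:
            n_double += 1
        elif order is BondOrder.TRIPLE:
            n_triple += 1
    if n_triple >= 1 or n_double >= 2:
        return Hybridization.SP
    if atom.is_aromatic or n_double == 1:
        return Hybridization.SP2
    if atom.element in _SP3_ELEMENTS:
        return Hybridization.SP3
    return Hybridization.OTHER


_SP3_ELEMENTS = frozenset(
    {"C", "N", "O", "S", "P", "B", "Si", "Se", "F", "Cl", "Br", "I", "As", "Te"}
)


def inchikey(mol: MolecularGraph) -> str:
    """Standard 27-character InChIKey.

    When the molecule carries 3D coordinates, stereochemistry is perceived
    from them first, so the key reflects the built geometry rather than any
    declared annotation.
    """
    if mol.has_coords:
        m = to_rdkit(mol, with_coords=True)
        Chem.AssignStereochemistryFrom3D(m)
    else:
        m = mol.rdkit()
    key = Chem.MolToInchiKey(m)
    if not key:
        raise RuntimeError(f"InChIKey generation failed for {canonical_smiles(mol)}")
    return key


# -- SDF I/O -------------------------------------------------------------

def read_sdf(path) -> Iterator[MolecularGraph]:
    """Iterate 3D molecules from an SDF (V2000) file.

    Records that fail sanitization are skipped; hydrogens are folded into
    heavy-atom counts and stereo is perceived from the coordinates.
    """
    if Path(path).stat().st_size == 0:
        return
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            continue
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"record{i}"
        yield from_rdkit(rdmol, source_id=name or f"record{i}")


def write_sdf(mols: Iterable[MolecularGraph], path) -> int:
    """Write molecules (heavy atoms + coordinates) as SDF V2000; returns
    the number of records written."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    n = 0
    try:
        for mol in mols:
            m = to_rdkit(mol, with_coords=True)
            m.SetProp("_Name", mol.source_id or f"mol{n}")
            writer.write(m)
            n += 1
    finally:
        writer.close()
    return n
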