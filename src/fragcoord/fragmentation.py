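"""Cutting molecules at rotatable bonds into rigid fragments.

A fragment is a maximal connected substructure with no rotatable bonds;
because it is rigid, a single stored geometry suffices to place all of its
atoms at once. Both the library builder and the query pipeline go through
exactly these functions, so fragment keys always agree between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdmolops

from .chem import BondOrder, MolecularGraph, from_rdkit

__all__ = [
    "FragmentMatch",
    "find_rotatable_bonds",
    "fragment_molecule",
    "fragment_key",
    "fragment_subgraph",
    "DEFAULT_MIN_ATOMS",
]

DEFAULT_MIN_ATOMS = 5

_AMIDE_SMARTS = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")


@dataclass
class FragmentMatch:
    """One rigid fragment of a parent molecule.

    ``atom_indices`` are parent heavy-atom indices (ascending) inducing a
    connected subgraph; ``key`` is its canonical SMILES with severed bonds
    capped by implicit hydrogens; ``key_to_parent[k]`` is the parent atom
    at canonical-order position *k*. Fragments of fewer than ``min_atoms``
    heavy atoms are not library material and fall to the rule-based
    builder (``library_eligible`` False).
    """

    atom_indices: list[int]
    key: str = ""
    key_to_parent: list[int] = field(default_factory=list)
    library_eligible: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


def find_rotatable_bonds(mol: MolecularGraph, amide_rotatable: bool = False) -> set[int]:
    """Indices of rotatable bonds: single-order, acyclic, both endpoints of
    heavy degree >= 2, and (by default) not an amide C-N bond.

    Amide C(=O)-N bonds have strong planar conjugation, so the default
    keeps them inside fragments; pass ``amide_rotatable=True`` to cut them
    anyway for sensitivity analysis.
    """
    amide_pairs: set[frozenset[int]] = set()
    if not amide_rotatable:
        for n_idx, c_idx, _o in mol.rdkit().GetSubstructMatches(_AMIDE_SMARTS):
            amide_pairs.add(frozenset((n_idx, c_idx)))
    out: set[int] = set()
    for bi, bond in enumerate(mol.bonds):
        if bond.order is not BondOrder.SINGLE or bond.in_ring:
            continue
        if mol.degree(bond.a) < 2 or mol.degree(bond.b) < 2:
            continue
        if frozenset((bond.a, bond.b)) in amide_pairs:
            continue
        out.add(bi)
    return out


def fragment_molecule(
    mol: MolecularGraph,
    min_atoms: int = DEFAULT_MIN_ATOMS,
    amide_rotatable: bool = False,
) -> list[FragmentMatch]:
    """Partition the heavy atoms into rigid fragments.

    Deletes every rotatable bond and returns the connected components in
    order of their smallest atom index, each with its canonical key and
    canonical-order-to-parent mapping. ``min_atoms`` counts heavy atoms.
    """
    rot = find_rotatable_bonds(mol, amide_rotatable=amide_rotatable)
    for bi, b in enumerate(mol.bonds):
        b.rotatable = bi in rot
    # connected components of the graph minus rotatable bonds
    parent = list(range(mol.n_atoms))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for bi, b in enumerate(mol.bonds):
        if bi not in rot:
            ra, rb = find(b.a), find(b.b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    comps: dict[int, list[int]] = {}
    for i in range(mol.n_atoms):
        comps.setdefault(find(i), []).append(i)
    matches = []
    for root in sorted(comps, key=lambda r: min(comps[r])):
        idx = sorted(comps[root])
        key, mapping = fragment_key(mol, idx)
        matches.append(
            FragmentMatch(
                atom_indices=idx,
                key=key,
                key_to_parent=mapping,
                library_eligible=len(idx) >= min_atoms,
            )
        )
    return matches


def _capped_fragment_rdkit(mol: MolecularGraph, atom_indices) -> tuple[Chem.Mol, list[int]]:
    """RDKit molecule of the induced subgraph with severed bonds capped by
    hydrogens; returns the molecule and the kept parent indices in the
    order they appear as its atoms."""
    idx = set(atom_indices)
    parent_rd = mol.rdkit()
    rw = Chem.RWMol(parent_rd)
    n_heavy = rw.GetNumAtoms()
    # a cut that removes a double bond's reference atom leaves its cis/trans
    # undefined: the hydrogen cap carries no stereo label, so drop it (on
    # both the library and the query side, keeping keys consistent)
    for bond in rw.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREONONE:
            continue
        refs = list(bond.GetStereoAtoms())
        ends = {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()}
        if not ends <= idx or any(r not in idx for r in refs):
            bond.SetStereo(Chem.BondStereo.STEREONONE)
            for end in ends:
                for nb_bond in rw.GetAtomWithIdx(end).GetBonds():
                    nb_bond.SetBondDir(Chem.BondDir.NONE)
    for bond in parent_rd.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for inside, outside in ((i, j), (j, i)):
            if inside in idx and outside not in idx:
                h = rw.AddAtom(Chem.Atom(1))
                rw.AddBond(inside, h, Chem.BondType.SINGLE)
    for a in sorted(set(range(n_heavy)) - idx, reverse=True):
        rw.RemoveAtom(a)
    sub = rw.GetMol()
    Chem.SanitizeMol(sub)
    sub = rdmolops.RemoveHs(sub)
    # a cut next to a declared center can demote it to a non-stereocenter
    Chem.AssignStereochemistry(sub, cleanIt=True, force=True)
    return sub, sorted(idx)


def fragment_key(mol: MolecularGraph, atom_indices) -> tuple[str, list[int]]:
    """Canonical SMILES key of an induced connected subgraph.

    Severed bonds become implicit hydrogens (no attachment-point dummies),
    so a fragment's key is the plain canonical SMILES of the standalone
    molecule it depicts. Also returns ``mapping`` with ``mapping[k]`` = the
    parent atom index at canonical-order position *k*.
    """
    if not atom_indices:
        raise ValueError("empty fragment")
    sub, kept = _capped_fragment_rdkit(mol, atom_indices)
    smi = Chem.MolToSmiles(sub)
    order = list(
        map(int, sub.GetProp("_smilesAtomOutputOrder").strip("[]").rstrip(",").split(","))
    )
    mapping = [kept[o] for o in order]
    return smi, mapping


def fragment_subgraph(mol: MolecularGraph, atom_indices) -> tuple[MolecularGraph, list[int]]:
    """The induced, hydrogen-capped subgraph as a standalone MolecularGraph
    (used for generic-ring SMARTS matching); returns it plus the parent
    atom index for each of its atoms."""
    sub, kept = _capped_fragment_rdkit(mol, atom_indices)
    return from_rdkit(sub), kept
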