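"""The coordinate generator: stitch rigid fragment templates and
rule-placed atoms into a full 3D structure.

The query molecule is traversed in depth-first order from atom 0
(neighbors visited in ascending input index). When the current atom
belongs to a fragment whose geometry was found in the library (exact key
match) or in the generic-ring tier, the whole template is committed in
one rigid motion: the template is rotated so the attachment atom's open
valence points back along the new bond, translated so the new bond gets
its ideal length, and spun about the bond axis to an anti (180 deg)
torsion against the already-built part. Atoms matching nothing are
connected one by one at ideal bond lengths along idealized hybridization
directions, again with anti torsions. Nothing in the build path is
random, so identical input and library give bit-identical output.

After all heavy atoms are placed, ring-closure bonds (bonds never
traversed during placement) are measured and over-stretched ones
flagged, hydrogens are placed on the remaining open valences, and
declared stereochemistry is enforced against the built geometry.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import (
    BondOrder,
    Hybridization,
    MolecularGraph,
    parse_smiles,
    perceive_hybridization,
    to_rdkit,
)
from .fragmentation import DEFAULT_MIN_ATOMS, fragment_molecule, fragment_subgraph
from .geometry import (
    dihedral_deg,
    rotation_about_axis,
    rotation_aligning,
    unit,
)
from .library import FragmentLibrary, GenericRingTemplate, lookup_generic_ring

logger = logging.getLogger(__name__)

__all__ = [
    "Provenance",
    "WorkingMolecule",
    "BuildReport",
    "COVALENT_RADII",
    "BOND_ORDER_FACTOR",
    "ideal_bond_length",
    "open_valence_directions",
    "place_fragment",
    "place_atom_rule_based",
    "close_rings",
    "place_hydrogens",
    "enforce_stereo",
    "generate_coordinates",
    "generate_batch",
]

# Single-bond covalent radii (Angstrom); pairwise sums give ideal single
# bond lengths. Higher orders scale the single-bond length by a fixed
# factor chosen to reproduce benzene ~1.39, ethene ~1.32, ethyne ~1.19 A
# from the carbon radius.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22, "Ga": 1.22, "Ge": 1.20, "As": 1.19,
    "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Cd": 1.44, "In": 1.42, "Sn": 1.39, "Sb": 1.39,
    "Te": 1.38, "I": 1.39, "Xe": 1.40,
}

BOND_ORDER_FACTOR: dict[BondOrder, float] = {
    BondOrder.SINGLE: 1.0,
    BondOrder.AROMATIC: 0.915,
    BondOrder.DOUBLE: 0.87,
    BondOrder.TRIPLE: 0.78,
}

_TET = 109.47122063449069  # arccos(-1/3), the tetrahedral angle
LONG_CLOSURE_FACTOR = 1.5


class Provenance(enum.Enum):
    FRAGMENT_EXACT = "fragment_exact"
    FRAGMENT_GENERIC = "fragment_generic"
    RULE = "rule"


def ideal_bond_length(elem_a: str, elem_b: str, order: BondOrder = BondOrder.SINGLE) -> float:
    """Ideal length in Angstrom: sum of single-bond covalent radii scaled
    by the bond-order factor. Symmetric in its element arguments."""
    try:
        ra, rb = COVALENT_RADII[elem_a], COVALENT_RADII[elem_b]
    except KeyError as exc:
        raise ValueError(f"no covalent radius for element {exc.args[0]!r}") from None
    return (ra + rb) * BOND_ORDER_FACTOR[order]


@dataclass
class WorkingMolecule:
    """Partially built molecule: committed heavy-atom coordinates, their
    provenance, and hydrogens once placed."""

    graph: MolecularGraph
    coords: dict[int, np.ndarray] = field(default_factory=dict)
    placed: set[int] = field(default_factory=set)
    provenance: dict[int, Provenance] = field(default_factory=dict)
    used_bonds: set[int] = field(default_factory=set)
    h_coords: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def commit(self, idx: int, xyz: np.ndarray, prov: Provenance) -> None:
        if idx in self.placed:
            raise ValueError(f"atom {idx} is already placed")
        self.coords[idx] = np.asarray(xyz, dtype=float)
        self.placed.add(idx)
        self.provenance[idx] = prov


@dataclass
class BuildReport:
    """What the builder did and where the geometry is known to be weak."""

    n_fragment_atoms: int = 0
    n_rule_atoms: int = 0
    n_fragments_placed: int = 0
    long_closure_bonds: list[tuple[tuple[int, int], float, float]] = field(default_factory=list)
    stereo_corrections: int = 0
    uncorrectable_stereo: list[str] = field(default_factory=list)
    provenance: dict[int, Provenance] = field(default_factory=dict)


# -- idealized valence directions ----------------------------------------

_CANONICAL_DIRS = {
    Hybridization.SP: np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
    Hybridization.SP2: np.array(
        [
            [0.0, 0.0, 1.0],
            [math.sin(math.radians(120.0)), 0.0, math.cos(math.radians(120.0))],
            [-math.sin(math.radians(120.0)), 0.0, math.cos(math.radians(120.0))],
        ]
    ),
    Hybridization.SP3: np.array(
        [
            [0.0, 0.0, 1.0],
            [2.0 * math.sqrt(2.0) / 3.0, 0.0, -1.0 / 3.0],
            [-math.sqrt(2.0) / 3.0, math.sqrt(2.0 / 3.0), -1.0 / 3.0],
            [-math.sqrt(2.0) / 3.0, -math.sqrt(2.0 / 3.0), -1.0 / 3.0],
        ]
    ),
}
_STERIC_COUNT = {Hybridization.SP: 2, Hybridization.SP2: 3, Hybridization.SP3: 4,
                 Hybridization.OTHER: 4}


def _aux_perpendicular(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to u (global +x, or +y
    when u is nearly parallel to x)."""
    probe = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(unit(u), probe))) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    return unit(probe - np.dot(probe, unit(u)) * unit(u))


def ideal_directions(hyb: Hybridization, known: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Unit directions completing an idealized valence shell.

    ``known`` are unit vectors toward already-placed substituents; the
    return value holds the remaining directions of a linear (sp, 180 deg),
    trigonal-planar (sp2, 120 deg) or tetrahedral (sp3, 109.47 deg) shell,
    deterministically oriented. Unhandled hybridizations fall back to the
    tetrahedral shell.
    """
    if hyb not in _CANONICAL_DIRS:
        hyb = Hybridization.SP3
    total = _STERIC_COUNT[hyb]
    known = [unit(k) for k in known]
    n_open = total - len(known)
    if n_open <= 0:
        return []
    if not known:
        return [d.copy() for d in _CANONICAL_DIRS[hyb]]
    if hyb is Hybridization.SP:
        return [-known[0]]
    if len(known) == 1:
        u = known[0]
        p = _aux_perpendicular(u)
        q = np.cross(u, p)
        theta = math.radians(120.0 if hyb is Hybridization.SP2 else _TET)
        phis = [0.0, math.pi] if hyb is Hybridization.SP2 else [0.0, 2 * math.pi / 3, 4 * math.pi / 3]
        return [
            math.cos(theta) * u + math.sin(theta) * (math.cos(phi) * p + math.sin(phi) * q)
            for phi in phis
        ]
    if len(known) == 2:
        u, v = known
        s = u + v
        if np.linalg.norm(s) < 1e-6:
            # nearly linear pair: any perpendicular completes the shell
            b = _aux_perpendicular(u)
        else:
            b = -unit(s)
        if hyb is Hybridization.SP2:
            return [b]
        cr = np.cross(u, v)
        n = unit(cr) if np.linalg.norm(cr) > 1e-6 else _aux_perpendicular(b)
        bu = float(np.dot(b, u))
        cos_t = math.cos(math.radians(_TET))
        ca = np.clip(cos_t / bu, -1.0, 1.0) if abs(bu) > 1e-9 else 0.0
        sa = math.sqrt(max(1.0 - ca * ca, 0.0))
        return [unit(ca * b + sa * n), unit(ca * b - sa * n)]
    # three known (sp3): the single remaining tetrahedral direction
    s = known[0] + known[1] + known[2]
    if np.linalg.norm(s) < 1e-6:
        return [unit(np.cross(known[0], known[1]))] if np.linalg.norm(np.cross(known[0], known[1])) > 1e-6 else [np.array([0.0, 0.0, 1.0])]
    return [-unit(s)]


def open_valence_directions(work: WorkingMolecule, atom_idx: int) -> list[np.ndarray]:
    """Idealized unit directions of the unfilled valences of a placed atom,
    given the positions of its already-placed neighbors and hydrogens."""
    if atom_idx not in work.placed:
        raise ValueError(f"atom {atom_idx} is not placed yet")
    origin = work.coords[atom_idx]
    known = [
        unit(work.coords[j] - origin)
        for j in work.graph.neighbors(atom_idx)
        if j in work.placed
    ]
    known += [unit(h - origin) for h in work.h_coords.get(atom_idx, [])]
    hyb = perceive_hybridization(work.graph, atom_idx)
    return ideal_directions(hyb, known)


# -- torsion bookkeeping --------------------------------------------------

def _torsion_refs(work: WorkingMolecule, anchor: int, exclude: int) -> Optional[tuple[int, int]]:
    """Reference pair (m, k) for the anti-torsion rule: m is the
    highest-index placed neighbor of *anchor* (excluding the new atom),
    k the highest-index placed neighbor of m excluding *anchor*."""
    ms = [j for j in work.graph.neighbors(anchor) if j in work.placed and j != exclude]
    if not ms:
        return None
    m = max(ms)
    ks = [j for j in work.graph.neighbors(m) if j in work.placed and j != anchor]
    if not ks:
        return None
    return m, max(ks)


def _pick_direction(
    work: WorkingMolecule, anchor: int, new_atom: int, dirs: list[np.ndarray]
) -> np.ndarray:
    """Choose (and, where the azimuth is free, rotate) an open valence
    direction at *anchor* so the torsion k-m-anchor-new comes out anti."""
    refs = _torsion_refs(work, anchor, new_atom)
    if refs is None or not dirs:
        return dirs[0]
    m, k = refs
    pa, pm, pk = work.coords[anchor], work.coords[m], work.coords[k]
    hyb = perceive_hybridization(work.graph, anchor)
    n_known = sum(1 for j in work.graph.neighbors(anchor) if j in work.placed) + len(
        work.h_coords.get(anchor, [])
    )
    if hyb is Hybridization.SP3 and n_known == 1:
        # free azimuth about the anchor-m bond: rotate to exact anti
        axis = pa - pm
        d = dirs[0]
        tau = dihedral_deg(pk, pm, pa, pa + d)
        for delta in (180.0 - tau, tau - 180.0):
            cand = rotation_about_axis(axis, math.radians(delta)) @ d
            if abs(abs(dihedral_deg(pk, pm, pa, pa + cand)) - 180.0) < 1e-6:
                return unit(cand)
        return unit(d)
    # discrete candidates: pick the most anti, ties to the first
    best, best_dev = dirs[0], float("inf")
    for d in dirs:
        tau = dihedral_deg(pk, pm, pa, pa + d)
        dev = abs(abs(tau) - 180.0)
        if dev < best_dev - 1e-9:
            best, best_dev = d, dev
    return best


# -- placement ------------------------------------------------------------

def place_atom_rule_based(
    work: WorkingMolecule, atom_idx: int, parent: Optional[int] = None
) -> None:
    """Place one atom at ideal bond length along an open valence direction
    of a placed neighbor, preferring an anti torsion to the already-built
    chain. The very first atom of a molecule goes to the origin."""
    if atom_idx in work.placed:
        return
    placed_nb = [j for j in work.graph.neighbors(atom_idx) if j in work.placed]
    if not placed_nb:
        work.commit(atom_idx, np.zeros(3), Provenance.RULE)
        return
    anchor = parent if parent in placed_nb else min(placed_nb)
    dirs = open_valence_directions(work, anchor)
    if not dirs:
        # valence shell exhausted (hypervalent or perception mismatch):
        # fall back to the direction away from the placed neighborhood
        logger.debug("atom %d: anchor %d has no open valence", atom_idx, anchor)
        nb_pos = [work.coords[j] for j in work.graph.neighbors(anchor) if j in work.placed]
        away = work.coords[anchor] - np.mean(nb_pos, axis=0)
        d = unit(away) if np.linalg.norm(away) > 1e-6 else np.array([0.0, 0.0, 1.0])
    else:
        d = _pick_direction(work, anchor, atom_idx, dirs)
    bond = work.graph.bond_between(anchor, atom_idx)
    length = ideal_bond_length(
        work.graph.atoms[anchor].element, work.graph.atoms[atom_idx].element, bond.order
    )
    work.commit(atom_idx, work.coords[anchor] + length * d, Provenance.RULE)
    work.used_bonds.add(work.graph.bond_index(anchor, atom_idx))


def place_fragment(
    work: WorkingMolecule,
    template_coords: np.ndarray,
    member_atoms: Sequence[int],
    provenance: Provenance,
    anchor: Optional[tuple[int, int]] = None,
) -> None:
    """Commit a whole fragment template with one rigid motion.

    ``template_coords[r]`` belongs to query atom ``member_atoms[r]``.
    With ``anchor=(p, q)`` (p placed, q a member bonded to p), q is set at
    ideal bond length from p along one of p's open valence directions, the
    template is rotated so q's own open valence points back at p, and the
    remaining spin about the p-q axis is fixed by the anti-torsion rule.
    Without an anchor (first placement) the template is translated so its
    lowest-index member sits at the origin.
    """
    template_coords = np.asarray(template_coords, dtype=float)
    members = list(member_atoms)
    row_of = {a: r for r, a in enumerate(members)}
    if any(a in work.placed for a in members):
        raise ValueError("fragment placement overlaps already-placed atoms")
    if anchor is None:
        first = min(members)
        shifted = template_coords - template_coords[row_of[first]]
        for a in members:
            work.commit(a, shifted[row_of[a]], provenance)
        _mark_internal_bonds(work, members)
        return

    p, q = anchor
    if p not in work.placed or q not in row_of:
        raise ValueError(f"bad anchor ({p}, {q}) for fragment placement")
    dirs = open_valence_directions(work, p)
    if not dirs:
        raise ValueError(f"anchor atom {p} has no open valence direction")
    d = _pick_direction(work, p, q, dirs)
    bond = work.graph.bond_between(p, q)
    length = ideal_bond_length(
        work.graph.atoms[p].element, work.graph.atoms[q].element, bond.order
    )
    target_q = work.coords[p] + length * d

    # attachment direction of q inside the template frame
    t_q = template_coords[row_of[q]]
    member_nbrs = sorted(j for j in work.graph.neighbors(q) if j in row_of)
    known = [unit(template_coords[row_of[j]] - t_q) for j in member_nbrs]
    hyb = perceive_hybridization(work.graph, q)
    open_dirs = ideal_directions(hyb, known)
    a_t = open_dirs[0] if open_dirs else np.array([0.0, 0.0, 1.0])

    rot = rotation_aligning(a_t, -d)
    placed = target_q + (template_coords - t_q) @ rot.T

    # spin about the new bond axis to an anti inter-fragment torsion
    refs = _torsion_refs(work, p, q)
    if refs is not None and member_nbrs:
        m, _k = refs
        s = member_nbrs[0]
        tau = dihedral_deg(work.coords[m], work.coords[p], target_q, placed[row_of[s]])
        axis = target_q - work.coords[p]
        for delta in (180.0 - tau, tau - 180.0):
            spin = rotation_about_axis(axis, math.radians(delta))
            cand = target_q + (placed - target_q) @ spin.T
            if abs(abs(dihedral_deg(work.coords[m], work.coords[p], target_q,
                                    cand[row_of[s]])) - 180.0) < 1e-6:
                placed = cand
                break
    for a in members:
        work.commit(a, placed[row_of[a]], provenance)
    _mark_internal_bonds(work, members)
    work.used_bonds.add(work.graph.bond_index(p, q))


def _mark_internal_bonds(work: WorkingMolecule, members: Sequence[int]) -> None:
    mset = set(members)
    for bi, b in enumerate(work.graph.bonds):
        if b.a in mset and b.b in mset:
            work.used_bonds.add(bi)


def close_rings(work: WorkingMolecule) -> list[tuple[tuple[int, int], float, float]]:
    """Measure every bond never traversed during placement (ring closures
    across fragment or rule boundaries) and flag over-stretched ones.

    A closure longer than 1.5x its ideal length is recorded; it is not
    fixed here — repairing it is the job of a downstream optimizer hook.
    """
    long_bonds = []
    for bi, b in enumerate(work.graph.bonds):
        if bi in work.used_bonds:
            continue
        if b.a not in work.placed or b.b not in work.placed:
            continue
        actual = float(np.linalg.norm(work.coords[b.a] - work.coords[b.b]))
        ideal = ideal_bond_length(
            work.graph.atoms[b.a].element, work.graph.atoms[b.b].element, b.order
        )
        if actual > LONG_CLOSURE_FACTOR * ideal:
            long_bonds.append(((b.a, b.b), actual, ideal))
    return long_bonds


def place_hydrogens(work: WorkingMolecule) -> None:
    """Fill every heavy atom's remaining open valence directions with
    hydrogens at ideal H-X bond lengths."""
    for i in sorted(work.placed):
        n_h = work.graph.atoms[i].num_h
        if n_h == 0:
            continue
        dirs = open_valence_directions(work, i)
        length = ideal_bond_length(work.graph.atoms[i].element, "H", BondOrder.SINGLE)
        hs = work.h_coords.setdefault(i, [])
        for k in range(n_h):
            if k < len(dirs):
                hs.append(work.coords[i] + length * dirs[k])
            else:  # more hydrogens than idealized directions; spread out
                extra = ideal_directions(Hybridization.SP3, [])[k % 4]
                hs.append(work.coords[i] + length * extra)


# -- stereochemistry enforcement ------------------------------------------

def _assemble_with_hydrogens(work: WorkingMolecule) -> tuple[Chem.Mol, np.ndarray, list[int]]:
    """Explicit-hydrogen RDKit molecule + full coordinate array for the
    working molecule. Heavy atoms keep their indices; hydrogens follow in
    heavy-atom order, matching RDKit's AddHs convention."""
    rd = Chem.AddHs(work.graph.rdkit())
    n_heavy = work.graph.n_atoms
    coords = np.zeros((rd.GetNumAtoms(), 3))
    for i in range(n_heavy):
        coords[i] = work.coords[i]
    h_cursor: dict[int, int] = {i: 0 for i in range(n_heavy)}
    for a in rd.GetAtoms():
        if a.GetAtomicNum() != 1:
            continue
        heavy = a.GetNeighbors()[0].GetIdx()
        hs = work.h_coords.get(heavy, [])
        k = h_cursor[heavy]
        coords[a.GetIdx()] = hs[k] if k < len(hs) else coords[heavy] + np.array([0.0, 0.0, 1.0])
        h_cursor[heavy] = k + 1
    return rd, coords, list(range(n_heavy))


def _set_conformer(rd: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    m = Chem.Mol(rd)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i in range(m.GetNumAtoms()):
        conf.SetAtomPosition(i, [float(x) for x in coords[i]])
    conf.Set3D(True)
    m.RemoveAllConformers()
    m.AddConformer(conf, assignId=True)
    return m


def _perceived(rd: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    m = _set_conformer(rd, coords)
    Chem.AssignStereochemistryFrom3D(m)
    return m


def _branch_atoms(rd: Chem.Mol, start: int, blocked: set[int]) -> set[int]:
    """Atoms reachable from *start* without entering *blocked*."""
    seen = {start}
    stack = [start]
    while stack:
        cur = stack.pop()
        for nb in rd.GetAtomWithIdx(cur).GetNeighbors():
            j = nb.GetIdx()
            if j not in seen and j not in blocked:
                seen.add(j)
                stack.append(j)
    return seen


def _reflect(coords: np.ndarray, atoms: set[int], point: np.ndarray, normal: np.ndarray) -> None:
    n = unit(normal)
    for a in atoms:
        v = coords[a] - point
        coords[a] = coords[a] - 2.0 * float(np.dot(v, n)) * n


def _fix_tetrahedral(rd: Chem.Mol, coords: np.ndarray, center: int,
                     declared_centers: set[int]) -> bool:
    """Invert the geometric parity at *center* by swapping its two
    cheapest substituent branches; returns False when ring-locked."""
    c = coords[center]
    nbrs = [a.GetIdx() for a in rd.GetAtomWithIdx(center).GetNeighbors()]
    branches = []
    for nb in nbrs:
        atoms = _branch_atoms(rd, nb, {center})
        has_center = bool((atoms - {nb}) & declared_centers) or (nb in declared_centers)
        branches.append((has_center, len(atoms), nb, atoms))
    branches.sort(key=lambda t: (t[0], t[1], t[2]))
    b1, b2 = branches[0], branches[1]
    d1 = coords[b1[2]] - c
    d2 = coords[b2[2]] - c
    if not (b1[3] & b2[3]) and center not in b1[3] and center not in b2[3]:
        # disjoint acyclic branches: reflect both through the bisector plane
        normal = unit(d1 / np.linalg.norm(d1) - d2 / np.linalg.norm(d2))
        _reflect(coords, b1[3] | b2[3], c, normal)
        return True
    # ring-locked: swap just the two substituent atoms, keeping each at its
    # own bond length (downstream geometry distorts; stereo parity flips)
    u1, u2 = unit(d1), unit(d2)
    l1, l2 = float(np.linalg.norm(d1)), float(np.linalg.norm(d2))
    coords[b1[2]] = c + u2 * l1
    coords[b2[2]] = c + u1 * l2
    return True


def _fix_double_bond(rd: Chem.Mol, coords: np.ndarray, i: int, j: int) -> bool:
    """Flip cis/trans across the double bond i=j by rotating the smaller
    side 180 degrees about the bond axis (or swapping the substituents of
    one end when the bond sits in a ring)."""
    side_i = _branch_atoms(rd, i, {j})
    side_j = _branch_atoms(rd, j, {i})
    axis = coords[j] - coords[i]
    if not (side_i & side_j):
        end, moving = (j, side_j - {j}) if len(side_j) <= len(side_i) else (i, side_i - {i})
        rot = rotation_about_axis(axis, math.pi)
        pivot = coords[end]
        for a in moving:
            coords[a] = pivot + rot @ (coords[a] - pivot)
        return True
    # ring double bond: swap the two substituent positions at one end
    for end, other in ((j, i), (i, j)):
        subs = [a.GetIdx() for a in rd.GetAtomWithIdx(end).GetNeighbors() if a.GetIdx() != other]
        if len(subs) == 2:
            c = coords[end]
            d1, d2 = coords[subs[0]] - c, coords[subs[1]] - c
            l1, l2 = float(np.linalg.norm(d1)), float(np.linalg.norm(d2))
            coords[subs[0]] = c + unit(d2) * l1
            coords[subs[1]] = c + unit(d1) * l2
            return True
    return False


def _bond_stereo_parity(bond: Chem.Bond) -> Optional[tuple[int, int, int, bool]]:
    """(begin, end, stereo-atom pair normalization) of a stereo double
    bond as a comparable tuple: returns (i, j, hash of reference atoms,
    is_cis) or None when unspecified."""
    st = bond.GetStereo()
    if st in (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS):
        cis = True
    elif st in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS):
        cis = False
    else:
        return None
    sa = list(bond.GetStereoAtoms())
    if len(sa) != 2:
        return None
    return bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), sa[0] * 100000 + sa[1], cis


def enforce_stereo(work: WorkingMolecule) -> tuple[int, list[str]]:
    """Compare the built geometry's stereo descriptors with the declared
    ones and correct mismatches in place.

    Tetrahedral centers: geometric parity is read off the 3D coordinates;
    on mismatch the two substituent branches with the fewest downstream
    atoms are swapped (reflected through the local bisector plane, or an
    atom-position swap when the center is ring-locked). Double bonds:
    cis/trans mismatches rotate the smaller branch 180 degrees about the
    bond axis. Returns (number of corrections, uncorrectable log).
    """
    rd, coords, _heavy = _assemble_with_hydrogens(work)
    declared = work.graph.rdkit()
    declared_tags = {
        a.GetIdx(): a.GetChiralTag()
        for a in declared.GetAtoms()
        if a.GetChiralTag()
        in (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    }
    declared_bonds = {}
    for b in declared.GetBonds():
        par = _bond_stereo_parity(b)
        if par is not None:
            declared_bonds[(b.GetBeginAtomIdx(), b.GetEndAtomIdx())] = par
    corrections = 0
    failures: list[str] = []

    for center in sorted(declared_tags):
        probe = _perceived(rd, coords)
        if probe.GetAtomWithIdx(center).GetChiralTag() == declared_tags[center]:
            continue
        if _fix_tetrahedral(rd, coords, center, set(declared_tags)):
            corrections += 1
            probe = _perceived(rd, coords)
            if probe.GetAtomWithIdx(center).GetChiralTag() != declared_tags[center]:
                failures.append(f"tetrahedral center {center} uncorrectable")
        else:
            failures.append(f"tetrahedral center {center} ring-locked")

    for (bi, bj), (di, dj, dref, dcis) in sorted(declared_bonds.items()):
        probe = _perceived(rd, coords)
        pbond = probe.GetBondBetweenAtoms(bi, bj)
        par = _bond_stereo_parity(pbond)
        if par is None:
            failures.append(f"double bond {bi}-{bj} stereo not perceivable")
            continue
        _pi, _pj, pref, pcis = par
        same_ref = pref == dref
        if (pcis == dcis) == same_ref:
            continue
        if _fix_double_bond(rd, coords, bi, bj):
            corrections += 1
            probe = _perceived(rd, coords)
            par2 = _bond_stereo_parity(probe.GetBondBetweenAtoms(bi, bj))
            if par2 is None or ((par2[3] == dcis) != (par2[2] == dref)):
                failures.append(f"double bond {bi}-{bj} uncorrectable")
        else:
            failures.append(f"double bond {bi}-{bj} ring-locked")

    # write corrected coordinates back
    n_heavy = work.graph.n_atoms
    for i in range(n_heavy):
        work.coords[i] = coords[i]
    h_cursor = {i: 0 for i in range(n_heavy)}
    for a in rd.GetAtoms():
        if a.GetAtomicNum() != 1:
            continue
        heavy = a.GetNeighbors()[0].GetIdx()
        k = h_cursor[heavy]
        if heavy in work.h_coords and k < len(work.h_coords[heavy]):
            work.h_coords[heavy][k] = coords[a.GetIdx()]
        h_cursor[heavy] = k + 1
    for msg in failures:
        logger.info("stereo: %s", msg)
    return corrections, failures


# -- orchestration --------------------------------------------------------

@dataclass
class _PlacementGroup:
    member_atoms: list[int]
    template_coords: np.ndarray
    provenance: Provenance
    done: bool = False


def _plan_fragments(
    mol: MolecularGraph,
    lib: Optional[FragmentLibrary],
    templates: Optional[Sequence[GenericRingTemplate]],
    min_atoms: int,
) -> tuple[list[_PlacementGroup], dict[int, int]]:
    groups: list[_PlacementGroup] = []
    atom_to_group: dict[int, int] = {}
    for fr in fragment_molecule(mol, min_atoms=min_atoms):
        group = None
        if fr.library_eligible and lib is not None:
            rec = lib.lookup(fr.key)
            if rec is not None and rec.n_atoms == fr.n_atoms:
                group = _PlacementGroup(
                    member_atoms=list(fr.key_to_parent),
                    template_coords=rec.coords,
                    provenance=Provenance.FRAGMENT_EXACT,
                )
        if group is None and templates:
            sub, kept = fragment_subgraph(mol, fr.atom_indices)
            hit = lookup_generic_ring(templates, sub)
            if hit is not None:
                tmpl, match = hit
                group = _PlacementGroup(
                    member_atoms=[kept[m] for m in match],
                    template_coords=tmpl.coords,
                    provenance=Provenance.FRAGMENT_GENERIC,
                )
        if group is not None:
            gi = len(groups)
            groups.append(group)
            for a in group.member_atoms:
                atom_to_group[a] = gi
    return groups, atom_to_group


def _dfs_order(mol: MolecularGraph) -> list[tuple[int, Optional[int]]]:
    """Depth-first (atom, parent) pre-order from atom 0, neighbors in
    ascending input index."""
    order: list[tuple[int, Optional[int]]] = []
    seen: set[int] = set()
    stack: list[tuple[int, Optional[int]]] = [(0, None)]
    while stack:
        atom, par = stack.pop()
        if atom in seen:
            continue
        seen.add(atom)
        order.append((atom, par))
        for nb in reversed(mol.neighbors(atom)):
            if nb not in seen:
                stack.append((nb, atom))
    return order


def generate_coordinates(
    query: str | MolecularGraph,
    lib: Optional[FragmentLibrary] = None,
    templates: Optional[Sequence[GenericRingTemplate]] = None,
    min_atoms: int = DEFAULT_MIN_ATOMS,
) -> tuple[MolecularGraph, BuildReport]:
    """Generate 3D coordinates for a SMILES string or parsed molecule.

    Pipeline: fragment at rotatable bonds; look each fragment up in the
    library (exact canonical-SMILES key) and then the generic-ring tier;
    traverse atoms depth-first, committing whole fragment templates
    rigidly and rule-placing everything else; measure ring closures;
    place hydrogens; enforce declared stereochemistry. Deterministic:
    identical input and library give bit-identical coordinates.
    """
    mol = parse_smiles(query) if isinstance(query, str) else query
    groups, atom_to_group = _plan_fragments(mol, lib, templates, min_atoms)
    work = WorkingMolecule(graph=mol)

    for atom, par in _dfs_order(mol):
        if atom in work.placed:
            continue
        gi = atom_to_group.get(atom)
        if gi is not None and not groups[gi].done:
            group = groups[gi]
            anchor = None
            if par is not None and par in work.placed:
                anchor = (par, atom)
            else:
                placed_nb = [j for j in mol.neighbors(atom) if j in work.placed]
                if placed_nb:
                    anchor = (min(placed_nb), atom)
            place_fragment(
                work, group.template_coords, group.member_atoms,
                group.provenance, anchor=anchor,
            )
            group.done = True
        else:
            place_atom_rule_based(work, atom, parent=par)

    long_bonds = close_rings(work)
    place_hydrogens(work)
    corrections, failures = enforce_stereo(work)

    coords = np.array([work.coords[i] for i in range(mol.n_atoms)])
    out = mol.with_coords(coords)
    n_frag = sum(1 for p in work.provenance.values() if p is not Provenance.RULE)
    report = BuildReport(
        n_fragment_atoms=n_frag,
        n_rule_atoms=mol.n_atoms - n_frag,
        n_fragments_placed=sum(1 for g in groups if g.done),
        long_closure_bonds=long_bonds,
        stereo_corrections=corrections,
        uncorrectable_stereo=failures,
        provenance=dict(work.provenance),
    )
    return out, report


def generate_batch(
    queries,
    lib: Optional[FragmentLibrary] = None,
    templates: Optional[Sequence[GenericRingTemplate]] = None,
    min_atoms: int = DEFAULT_MIN_ATOMS,
):
    """Run :func:`generate_coordinates` over many inputs.

    Yields ``(name, molecule, report, error)`` tuples in input order; a
    failure produces an error record for that molecule, never a batch
    abort.
    """
    for i, q in enumerate(queries):
        if isinstance(q, MolecularGraph):
            name = q.source_id or f"mol{i}"
        else:
            name = f"mol{i}"
        try:
            out, report = generate_coordinates(q, lib=lib, templates=templates,
                                               min_atoms=min_atoms)
            if out.source_id:
                name = out.source_id
            yield name, out, report, None
        except Exception as exc:
            logger.warning("generation failed for %s: %s", name, exc)
            yield name, None, None, str(exc)
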