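"""The rigid-fragment geometry database.

A library maps a fragment's canonical SMILES key to one stored 3D
geometry (the first conformation encountered while mining a corpus).
On disk it is a human-auditable flat file of text records plus a
key-to-byte-offset index, so a lookup seeks straight to its record
without parsing the rest of the file. When an exact key misses, a small
auxiliary tier of generic ring templates (SMARTS patterns with idealized
coordinates) provides approximate ring placement; anything missing both
tiers falls to the rule-based atom-by-atom builder.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import MolecularGraph
from .fragmentation import DEFAULT_MIN_ATOMS, fragment_molecule

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "GenericRingTemplate",
    "build_library",
    "write_library",
    "load_library",
    "lookup_exact",
    "lookup_generic_ring",
    "builtin_ring_templates",
    "load_ring_templates",
]

DEFAULT_MIN_COUNT = 3
_COORD_FMT = "{:.4f}"
_MIN_PAIR_DIST = 0.5  # Angstrom; collapsed geometries are rejected


@dataclass
class Fragment:
    """One stored fragment geometry.

    ``coords[k]`` belongs to the atom at position *k* of the canonical
    atom order of ``key``, which is how template coordinates transfer onto
    any query fragment with the same key.
    """

    key: str
    coords: np.ndarray
    occurrence_count: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"fragment {self.key}: coords must be (n, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


def _collapsed(coords: np.ndarray) -> bool:
    n = len(coords)
    if n < 2:
        return False
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(n, k=1)
    return bool(np.min(d2[iu]) < _MIN_PAIR_DIST**2)


class FragmentLibrary:
    """Exact-key fragment store.

    Either fully in memory (fresh build) or file-backed, where the index
    maps each key to the byte offset of its record in the flat file and
    ``lookup`` seeks directly there.
    """

    def __init__(
        self,
        fragments: Optional[dict[str, Fragment]] = None,
        db_path: Optional[Path] = None,
        index: Optional[dict[str, int]] = None,
    ) -> None:
        self._mem = fragments
        self.db_path = Path(db_path) if db_path is not None else None
        self.index = index if index is not None else (
            {k: -1 for k in fragments} if fragments else {}
        )

    @property
    def n_fragments(self) -> int:
        return len(self.index)

    def keys(self):
        return self.index.keys()

    def __contains__(self, key: str) -> bool:
        return key in self.index

    def lookup(self, key: str) -> Optional[Fragment]:
        """Exact lookup; a miss is None, not an error."""
        if key not in self.index:
            return None
        if self._mem is not None:
            return self._mem[key]
        with open(self.db_path, "r") as fh:
            fh.seek(self.index[key])
            frag = _read_record(fh, offset=self.index[key])
        if frag.key != key:
            raise IOError(
                f"index corruption: offset {self.index[key]} holds {frag.key!r}, "
                f"expected {key!r}"
            )
        return frag

    def lookup_linear(self, key: str) -> Optional[Fragment]:
        """Full linear scan of the flat file, ignoring the index. Slower
        but must agree with ``lookup`` for every key (tested oracle)."""
        if self._mem is not None:
            return self._mem.get(key)
        with open(self.db_path, "r") as fh:
            while True:
                offset = fh.tell()
                line = fh.readline()
                if not line:
                    return None
                if not line.strip():
                    continue
                fh.seek(offset)
                frag = _read_record(fh, offset=offset)
                if frag.key == key:
                    return frag

    def fragments(self) -> Iterable[Fragment]:
        for key in self.index:
            yield self.lookup(key)


def build_library(
    corpus: Iterable[MolecularGraph],
    min_atoms: int = DEFAULT_MIN_ATOMS,
    min_count: int = DEFAULT_MIN_COUNT,
    count_per_molecule: bool = False,
    amide_rotatable: bool = False,
) -> FragmentLibrary:
    """Mine a corpus of 3D molecules into a fragment library.

    Every library-eligible fragment occurrence (>= ``min_atoms`` heavy
    atoms) is counted; a fragment enters the library iff its total count
    reaches ``min_count``. The stored geometry is always the first
    occurrence in corpus stream order; later conformations of the same key
    are only counted. With ``count_per_molecule`` a key counts at most
    once per molecule (the default counts every occurrence).
    """
    counts: dict[str, int] = {}
    first_coords: dict[str, np.ndarray] = {}
    for mol in corpus:
        if not mol.has_coords:
            logger.warning("skipping corpus molecule %s: no 3D coordinates", mol.source_id)
            continue
        try:
            frags = fragment_molecule(mol, min_atoms=min_atoms, amide_rotatable=amide_rotatable)
        except Exception as exc:  # pragma: no cover - corpus robustness
            logger.warning("skipping corpus molecule %s: %s", mol.source_id, exc)
            continue
        seen_here: set[str] = set()
        for fr in frags:
            if not fr.library_eligible:
                continue
            if count_per_molecule and fr.key in seen_here:
                continue
            seen_here.add(fr.key)
            counts[fr.key] = counts.get(fr.key, 0) + 1
            if fr.key not in first_coords:
                coords = np.array(
                    [mol.atoms[p].coords for p in fr.key_to_parent], dtype=float
                )
                if _collapsed(coords):
                    logger.warning(
                        "fragment %s in %s has collapsed geometry; not stored",
                        fr.key, mol.source_id,
                    )
                else:
                    first_coords[fr.key] = coords
    fragments = {
        key: Fragment(key=key, coords=first_coords[key], occurrence_count=counts[key])
        for key in first_coords
        if counts[key] >= min_count
    }
    return FragmentLibrary(fragments=fragments)


# -- serialization -------------------------------------------------------
#
# Record format (text, blank-line separated):
#   <canonical_smiles> <n_atoms> <occurrence_count>
#   <element> <x> <y> <z>        (n_atoms lines, 4 decimal places)
# Index file: "<canonical_smiles>\t<byte_offset>" per line.

def write_library(lib: FragmentLibrary, db_path, index_path) -> None:
    """Serialize to the flat file + index pair. Round trips bit-exactly at
    the stored 4-decimal coordinate precision."""
    db_path, index_path = Path(db_path), Path(index_path)
    offsets: dict[str, int] = {}
    with open(db_path, "w") as fh:
        for key in sorted(lib.keys()):
            frag = lib.lookup(key)
            elements = _key_elements(key)
            offsets[key] = fh.tell()
            fh.write(f"{frag.key} {frag.n_atoms} {frag.occurrence_count}\n")
            for el, xyz in zip(elements, frag.coords):
                fh.write(
                    f"{el} "
                    + " ".join(_COORD_FMT.format(v) for v in xyz)
                    + "\n"
                )
            fh.write("\n")
    with open(index_path, "w") as fh:
        for key, off in offsets.items():
            fh.write(f"{key}\t{off}\n")


def _key_elements(key: str) -> list[str]:
    """Element symbols of a key in its canonical atom order (the order a
    parse of the key yields, which is the storage order)."""
    m = Chem.MolFromSmiles(key)
    if m is None:
        raise ValueError(f"unparsable fragment key: {key!r}")
    return [a.GetSymbol() for a in m.GetAtoms()]


def _read_record(fh: io.TextIOBase, offset: int = -1) -> Fragment:
    header = fh.readline()
    parts = header.split()
    if len(parts) != 3:
        raise IOError(f"malformed record header at byte {offset}: {header!r}")
    key, n_s, count_s = parts
    try:
        n, count = int(n_s), int(count_s)
    except ValueError:
        raise IOError(f"malformed record header at byte {offset}: {header!r}")
    coords = np.empty((n, 3), dtype=float)
    for i in range(n):
        line = fh.readline()
        fields = line.split()
        if len(fields) != 4:
            raise IOError(
                f"malformed coordinate line {i} of record at byte {offset}: {line!r}"
            )
        coords[i] = [float(v) for v in fields[1:]]
    return Fragment(key=key, coords=coords, occurrence_count=count)


def load_library(db_path, index_path=None) -> FragmentLibrary:
    """Load a file-backed library.

    Without an index file (or with ``index_path=None`` pointing at a
    missing file) the flat file is scanned once to rebuild the offsets,
    which yields identical lookup behavior at a one-time linear cost.
    """
    db_path = Path(db_path)
    index: dict[str, int] = {}
    if index_path is not None and Path(index_path).exists():
        for ln, line in enumerate(Path(index_path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                key, off = line.rsplit("\t", 1)
                index[key] = int(off)
            except ValueError:
                raise IOError(f"malformed index line {ln}: {line!r}")
    else:
        with open(db_path, "r") as fh:
            while True:
                offset = fh.tell()
                line = fh.readline()
                if not line:
                    break
                if not line.strip():
                    continue
                fh.seek(offset)
                frag = _read_record(fh, offset=offset)
                index[frag.key] = offset
    return FragmentLibrary(db_path=db_path, index=index)


def lookup_exact(lib: FragmentLibrary, key: str) -> Optional[Fragment]:
    """Functional alias for :meth:`FragmentLibrary.lookup`."""
    return lib.lookup(key)


# -- generic ring templates ----------------------------------------------

@dataclass
class GenericRingTemplate:
    """A SMARTS ring pattern with idealized coordinates aligned to its
    atom order; the approximate-placement tier behind exact lookup."""

    name: str
    smarts: str
    coords: np.ndarray
    pattern: Chem.Mol = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.pattern = Chem.MolFromSmarts(self.smarts)
        if self.pattern is None:
            raise ValueError(f"unparsable SMARTS: {self.smarts!r}")
        if self.pattern.GetNumAtoms() != len(self.coords):
            raise ValueError(
                f"template {self.name}: {self.pattern.GetNumAtoms()} SMARTS atoms "
                f"vs {len(self.coords)} coordinates"
            )


def _regular_polygon(n: int, side: float, pucker: float = 0.0) -> np.ndarray:
    radius = side / (2.0 * math.sin(math.pi / n))
    coords = np.empty((n, 3))
    for k in range(n):
        ang = 2.0 * math.pi * k / n
        coords[k] = (radius * math.cos(ang), radius * math.sin(ang),
                     pucker * (-1.0) ** k)
    return coords


def _chair_hexagon(bond: float = 1.54, angle_deg: float = 111.0) -> np.ndarray:
    """Cyclohexane chair: ring atoms alternate above/below the mean plane
    so that every internal angle equals ``angle_deg``."""
    theta = math.radians(angle_deg)
    r = bond * math.sqrt(2.0 * (1.0 - math.cos(theta)) / 3.0)
    h = math.sqrt(max(bond**2 - r**2, 0.0)) / 2.0
    coords = np.empty((6, 3))
    for k in range(6):
        ang = math.pi * k / 3.0
        coords[k] = (r * math.cos(ang), r * math.sin(ang), h * (-1.0) ** k)
    return coords


def _envelope_pentagon(bond: float = 1.54, flap: float = 0.5) -> np.ndarray:
    """Cyclopentane envelope: four coplanar atoms, atom 0 lifted out of
    plane with its two bond lengths restored to ``bond``."""
    coords = _regular_polygon(5, bond)
    p1 = coords[1]
    reach = bond**2 - p1[1] ** 2 - flap**2
    coords[0] = (p1[0] + math.sqrt(max(reach, 0.01)), 0.0, flap)
    return coords


def _ring_smarts(n: int, aromatic: bool = False) -> str:
    sym = "a" if aromatic else "*"
    link = "" if aromatic else "~"
    body = link.join(sym for _ in range(n - 1))
    return f"{sym}1{link}{body}1"


def builtin_ring_templates() -> list[GenericRingTemplate]:
    """The shipped generic-ring tier, in match-priority order: planar
    aromatic 5/6-rings first, then saturated rings from 3-membered up to
    18-membered crowns (regular polygons with alternating pucker)."""
    templates = [
        GenericRingTemplate("aromatic6", _ring_smarts(6, aromatic=True),
                            _regular_polygon(6, 1.39)),
        GenericRingTemplate("aromatic5", _ring_smarts(5, aromatic=True),
                            _regular_polygon(5, 1.39)),
        GenericRingTemplate("ring3", _ring_smarts(3), _regular_polygon(3, 1.51)),
        GenericRingTemplate("ring4", _ring_smarts(4), _regular_polygon(4, 1.55)),
        GenericRingTemplate("ring5", _ring_smarts(5), _envelope_pentagon()),
        GenericRingTemplate("ring6", _ring_smarts(6), _chair_hexagon()),
    ]
    for n in range(7, 19):
        templates.append(
            GenericRingTemplate(
                f"ring{n}", _ring_smarts(n), _regular_polygon(n, 1.54, pucker=0.25)
            )
        )
    return templates


def load_ring_templates(path) -> list[GenericRingTemplate]:
    """Load an external template file: records of ``<name> <smarts>`` then
    one ``<x> <y> <z>`` line per SMARTS atom, blank-line separated."""
    templates = []
    block: list[str] = []
    for line in Path(path).read_text().splitlines() + [""]:
        if line.strip():
            block.append(line)
            continue
        if not block:
            continue
        name, smarts = block[0].split()
        coords = np.array([[float(v) for v in ln.split()] for ln in block[1:]])
        templates.append(GenericRingTemplate(name, smarts, coords))
        block = []
    return templates


def lookup_generic_ring(
    templates: Sequence[GenericRingTemplate], frag_graph: MolecularGraph
) -> Optional[tuple[GenericRingTemplate, list[int]]]:
    """First template (list order) whose SMARTS matches the fragment with
    a match covering *all* of the fragment's ring atoms.

    Returns ``(template, match)`` where ``match[k]`` is the fragment atom
    carrying template coordinate row *k*; elements always stay those of
    the query. Fragment atoms outside the match (e.g. exocyclic
    substituents) are left for the rule-based builder. Every ring bond of
    the fragment must be realized by a template bond, so e.g. a fused
    bicyclic never passes itself off as its perimeter macrocycle. None on
    miss.
    """
    ring_bonds = [(b.a, b.b) for b in frag_graph.bonds if b.in_ring]
    if not ring_bonds:
        return None
    ring_atoms = {a for pair in ring_bonds for a in pair}
    rd = frag_graph.rdkit()
    for tmpl in templates:
        tmpl_bonds = {
            frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in tmpl.pattern.GetBonds()
        }
        for match in rd.GetSubstructMatches(tmpl.pattern, uniquify=True, maxMatches=256):
            if not ring_atoms.issubset(match):
                continue
            pos = {a: k for k, a in enumerate(match)}
            if all(
                frozenset((pos[a], pos[b])) in tmpl_bonds for a, b in ring_bonds
            ):
                return tmpl, list(match)
    return None
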