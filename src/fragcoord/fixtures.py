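"""Deterministic toy corpora and stereo test inputs.

Geometries are hard-coded analytic constructions (regular polygons,
ideal chairs, planar sp2 frames) rather than toolkit-embedded
conformers, so they serve as engine-independent ground truth for the
library builder and the evaluation metrics. Coordinates are listed in
the atom order of each fixture's SMILES string.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .chem import MolecularGraph, inchikey, parse_smiles, write_sdf

__all__ = [
    "FIXTURE_NAMES",
    "idealized_geometry",
    "build_fixture_corpus",
    "stereo_suite",
]


def _polygon(n: int, side: float, pucker: float = 0.0) -> np.ndarray:
    r = side / (2.0 * math.sin(math.pi / n))
    return np.array(
        [
            (r * math.cos(2 * math.pi * k / n), r * math.sin(2 * math.pi * k / n),
             pucker * (-1.0) ** k)
            for k in range(n)
        ]
    )


def _chair(bond: float = 1.54, angle: float = 111.0) -> np.ndarray:
    theta = math.radians(angle)
    r = bond * math.sqrt(2.0 * (1.0 - math.cos(theta)) / 3.0)
    h = math.sqrt(bond**2 - r**2) / 2.0
    return np.array(
        [(r * math.cos(math.pi * k / 3), r * math.sin(math.pi * k / 3),
          h * (-1.0) ** k) for k in range(6)]
    )


def _envelope(bond: float = 1.54, flap: float = 0.5) -> np.ndarray:
    coords = _polygon(5, bond)
    p1y = coords[1][1]
    coords[0] = (coords[1][0] + math.sqrt(bond**2 - p1y**2 - flap**2), 0.0, flap)
    return coords


def _zigzag(n: int, bond: float = 1.53, angle: float = 111.0) -> np.ndarray:
    """Planar all-anti chain with the given internal angle: every torsion
    is exactly 180 degrees."""
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1] = (bond, 0.0, 0.0)
    sign = 1.0
    for k in range(2, n):
        back = coords[k - 2] - coords[k - 1]
        u = back / np.linalg.norm(back)
        perp = np.array([-u[1], u[0], 0.0]) * sign
        theta = math.radians(angle)
        coords[k] = coords[k - 1] + bond * (math.cos(theta) * u + math.sin(theta) * perp)
        sign = -sign
    return coords


def _naphthalene(bond: float = 1.40) -> np.ndarray:
    """Two fused regular hexagons sharing the C3-C8 edge, in the atom
    order of 'c1ccc2ccccc2c1'."""
    half = bond / 2.0
    cx = bond * math.sqrt(3.0) / 2.0  # distance from shared edge to ring center
    left, right = np.array([-cx, 0.0, 0.0]), np.array([cx, 0.0, 0.0])

    def vert(center, deg):
        a = math.radians(deg)
        return center + bond * np.array([math.cos(a), math.sin(a), 0.0])

    return np.array(
        [
            vert(left, 210), vert(left, 150), vert(left, 90), vert(left, 30),
            vert(right, 90), vert(right, 30), vert(right, -30), vert(right, -90),
            vert(right, -150), vert(left, -90),
        ]
    )


def _biphenyl(ring_bond: float = 1.39, link: float = 1.48) -> np.ndarray:
    """Two coplanar benzene rings joined by a single bond, in the atom
    order of 'c1ccccc1-c1ccccc1' (atom 5 bonds atom 6)."""
    c1 = np.array([-(link / 2 + ring_bond), 0.0, 0.0])
    c2 = -c1

    def vert(center, deg):
        a = math.radians(deg)
        return center + ring_bond * np.array([math.cos(a), math.sin(a), 0.0])

    ring1 = [vert(c1, d) for d in (300, 240, 180, 120, 60, 0)]      # atoms 0..5
    ring2 = [vert(c2, d) for d in (180, 120, 60, 0, -60, -120)]     # atoms 6..11
    return np.array(ring1 + ring2)


def _trans_2_butene() -> np.ndarray:
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([1.33, 0.0, 0.0])
    m0 = c1 + 1.50 * np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])
    m3 = c2 + 1.50 * np.array([-math.cos(math.radians(120)), -math.sin(math.radians(120)), 0.0])
    return np.array([m0, c1, c2, m3])


def _tetrahedral_center() -> np.ndarray:
    """Bromochlorofluoromethane with the halogens on ideal tetrahedral
    directions; the parity realized by these coordinates matches the
    declared '[C@H]' of the fixture SMILES (checked by its own test)."""
    t = 1.0 / math.sqrt(3.0)
    dirs = {
        "F": np.array([t, t, t]),
        "Cl": np.array([t, -t, -t]),
        "Br": np.array([-t, t, -t]),
    }
    c = np.zeros(3)
    return np.array([c + 1.33 * dirs["F"], c, c + 1.78 * dirs["Cl"], c + 1.96 * dirs["Br"]])


_FIXTURES: dict[str, tuple[str, "np.ndarray"]] = {}


def _register():
    _FIXTURES.clear()
    _FIXTURES.update(
        {
            "benzene": ("c1ccccc1", _polygon(6, 1.39)),
            "pyridine": ("c1ccncc1", _polygon(6, 1.37)),
            "cyclohexane_chair": ("C1CCCCC1", _chair()),
            "cyclopentane": ("C1CCCC1", _envelope()),
            "naphthalene": ("c1ccc2ccccc2c1", _naphthalene()),
            "biphenyl": ("c1ccccc1-c1ccccc1", _biphenyl()),
            "butane_anti": ("CCCC", _zigzag(4)),
            "tetrahedral_center": ("F[C@H](Cl)Br", _tetrahedral_center()),
            "trans_2_butene": ("C/C=C/C", _trans_2_butene()),
            "macrocycle_12": ("C1CCCCCCCCCCC1", _polygon(12, 1.54)),
        }
    )


_register()
FIXTURE_NAMES = tuple(_FIXTURES)


def idealized_geometry(name: str) -> MolecularGraph:
    """One fixture molecule with its hard-coded idealized coordinates."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    smiles, coords = _FIXTURES[name]
    mol = parse_smiles(smiles, name=name)
    return mol.with_coords(np.array(coords, dtype=float))


def build_fixture_corpus(
    names=None,
    n_copies: int = 3,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    out=None,
) -> list[MolecularGraph]:
    """Emit each fixture ``n_copies`` times, optionally writing an SDF.

    Gaussian coordinate jitter (``jitter_sigma`` Angstrom, seeded) is
    applied only to copies after the first, so the library's
    first-conformer policy is directly observable: the stored geometry
    must always be the unjittered first copy. Same seed, same bytes.
    """
    if names is None:
        names = FIXTURE_NAMES
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[MolecularGraph] = []
    for name in names:
        base = idealized_geometry(name)
        coords0 = base.coords_array()
        for k in range(n_copies):
            coords = coords0.copy()
            if k > 0 and jitter_sigma > 0.0:
                coords = coords + rng.normal(0.0, jitter_sigma, size=coords.shape)
            corpus.append(base.with_coords(coords, source_id=f"{name}_{k}"))
    if out is not None:
        write_sdf(corpus, out)
    return corpus


# Stereo-rich SMILES: R/S centers (single and multiple), cis/trans double
# bonds, ring and ring-fused centers, and a stereogenic macrocycle. Ring
# entries carry exocyclic substituents where possible so mismatched
# parities stay correctable by local substituent swaps.
_STEREO_SMILES = [
    "F[C@H](Cl)Br",
    "F[C@@H](Cl)Br",
    "C[C@H](N)C(=O)O",
    "C[C@@H](N)C(=O)O",
    "C[C@H](O)CC",
    "C[C@@H](O)CC",
    "C[C@H](Cl)CC",
    "C[C@@H](Cl)CC",
    "Cl[C@H](Br)CC",
    "Cl[C@@H](Br)CC",
    "C/C=C/C",
    "C/C=C\\C",
    "F/C=C/F",
    "F/C=C\\F",
    "C/C=C/C=C/C",
    "C/C=C\\C=C/C",
    "C/C=C/Cl",
    "C/C=C\\Cl",
    "C[C@@H](O)[C@@H](C)O",
    "C[C@H](O)[C@@H](C)O",
    "C[C@@H](N)[C@H](O)C",
    "C[C@H](F)[C@H](F)C",
    "N[C@@H](CO)C(=O)O",
    "N[C@@H](Cc1ccccc1)C(=O)O",
    "C/C=C/[C@H](C)O",
    "C/C=C/[C@@H](C)O",
    "C=C[C@H](C)O",
    "C[C@H]1CO1",
    "C[C@@H]1CO1",
    "C[C@H]1CCCC[C@@H]1C",
    "C[C@H]1CCCC[C@H]1C",
    "CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O",
    "C[C@H]1CCCCCCCCCCO1",
    "C[C@@H]1CCCCCCCCCCO1",
]


def stereo_suite() -> list[tuple[str, str]]:
    """(smiles, expected InChIKey) pairs driving the stereo-preservation
    contract; the keys are computed from the declared annotations at
    suite-build time."""
    return [(smi, inchikey(parse_smiles(smi))) for smi in _STEREO_SMILES]
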