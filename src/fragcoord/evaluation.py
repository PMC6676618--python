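"""Metrics for comparing generated geometries against references.

Per molecule: heavy-atom RMSD after optimal rigid superposition (made
symmetry-aware by minimizing over graph automorphisms), mean absolute
bond length / bond angle / torsion errors over all internal coordinates,
the torsion fingerprint deviation (TFD), and a stereochemistry success
flag defined as InChIKey identity between the input and the generated
structure with stereo perceived from its 3D coordinates. Batch
aggregation averages the geometric metrics over stereo-successful
molecules only and reports the success rate separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import TorsionFingerprints

from .chem import MolecularGraph, canonical_smiles, inchikey, parse_smiles, read_sdf, to_rdkit
from .geometry import circular_diff_deg, dihedral_deg, kabsch_rmsd, angle_deg

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeMetrics",
    "BatchReport",
    "align_atom_order",
    "heavy_atom_rmsd",
    "internal_coordinate_errors",
    "torsion_fingerprint_deviation",
    "stereo_success",
    "evaluate_pair",
    "evaluate_batch",
]

MAX_AUTOMORPHISMS = 10_000


class GraphMismatchError(ValueError):
    """Reference and generated molecules are not the same molecular graph."""


def _check_same_graph(ref: MolecularGraph, gen: MolecularGraph) -> None:
    # constitution only: stereo differences are scored by stereo_success,
    # not treated as a graph mismatch
    a = Chem.MolToSmiles(ref.rdkit(), isomericSmiles=False)
    b = Chem.MolToSmiles(gen.rdkit(), isomericSmiles=False)
    if a != b:
        raise GraphMismatchError(f"molecular graphs differ: {a!r} vs {b!r}")


def _isomorphisms(ref: MolecularGraph, gen: MolecularGraph) -> list[tuple[int, ...]]:
    """Graph isomorphisms gen -> ref: each returned tuple m satisfies
    'gen atom k corresponds to ref atom m[k]'. Enumerating all of them
    covers both differing atom orders and molecular symmetry
    (automorphisms), capped at MAX_AUTOMORPHISMS."""
    matches = ref.rdkit().GetSubstructMatches(
        gen.rdkit(), uniquify=False, useChirality=False,
        maxMatches=MAX_AUTOMORPHISMS,
    )
    if len(matches) >= MAX_AUTOMORPHISMS:
        logger.warning(
            "automorphism cap (%d) hit for %s; falling back to identity mapping",
            MAX_AUTOMORPHISMS, canonical_smiles(ref),
        )
        return [tuple(range(ref.n_atoms))]
    if not matches:  # same constitution guaranteed by _check_same_graph
        return [tuple(range(ref.n_atoms))]
    return list(matches)


def _best_mapping(ref: MolecularGraph, gen: MolecularGraph) -> tuple[tuple[int, ...], float]:
    p = ref.coords_array()
    q = gen.coords_array()
    best, best_rmsd = None, np.inf
    for mapping in _isomorphisms(ref, gen):
        r = kabsch_rmsd(p[list(mapping)], q)
        if r < best_rmsd:
            best, best_rmsd = mapping, r
    return best, float(best_rmsd)


def align_atom_order(ref: MolecularGraph, gen: MolecularGraph) -> MolecularGraph:
    """Return *gen*'s coordinates relabeled into *ref*'s atom order, using
    the graph isomorphism that minimizes RMSD. The result carries ref's
    graph, so internal-coordinate and TFD comparisons can assume identical
    ordering."""
    _check_same_graph(ref, gen)
    mapping, _ = _best_mapping(ref, gen)
    coords = np.empty((ref.n_atoms, 3))
    q = gen.coords_array()
    for k, j in enumerate(mapping):
        coords[j] = q[k]
    return ref.with_coords(coords, source_id=gen.source_id or ref.source_id)


def heavy_atom_rmsd(
    ref: MolecularGraph, gen: MolecularGraph, symmetry_aware: bool = True
) -> float:
    """Minimum heavy-atom RMSD over rigid superposition, and (by default)
    over graph isomorphisms, so symmetric rings are not over-penalized and
    differing input atom orders are reconciled.

    The identity-mapping mode (``symmetry_aware=False``) assumes both
    molecules share the same atom order.
    """
    _check_same_graph(ref, gen)
    if not symmetry_aware:
        return kabsch_rmsd(ref.coords_array(), gen.coords_array())
    return _best_mapping(ref, gen)[1]


def _angle_triples(mol: MolecularGraph):
    for j in range(mol.n_atoms):
        nbrs = mol.neighbors(j)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                yield nbrs[x], j, nbrs[y]


def _torsion_quads(mol: MolecularGraph):
    for b in mol.bonds:
        j, k = b.a, b.b
        for i in mol.neighbors(j):
            if i == k:
                continue
            for l in mol.neighbors(k):
                if l == j or l == i:
                    continue
                yield i, j, k, l


def internal_coordinate_errors(
    ref: MolecularGraph, gen: MolecularGraph
) -> tuple[float, float, float]:
    """Mean |Δbond| (Å), mean |Δangle| (deg), mean circular |Δtorsion|
    (deg, mapped to [0, 180]) over all heavy-atom bonds, bonded triples
    and bonded quadruples. Assumes ref and gen share atom order."""
    _check_same_graph(ref, gen)
    pr, pg = ref.coords_array(), gen.coords_array()
    bond_errs = [
        abs(
            float(np.linalg.norm(pr[b.a] - pr[b.b]))
            - float(np.linalg.norm(pg[b.a] - pg[b.b]))
        )
        for b in ref.bonds
    ]
    angle_errs = [
        abs(angle_deg(pr[i], pr[j], pr[k]) - angle_deg(pg[i], pg[j], pg[k]))
        for i, j, k in _angle_triples(ref)
    ]
    torsion_errs = [
        circular_diff_deg(
            dihedral_deg(pr[i], pr[j], pr[k], pr[l]),
            dihedral_deg(pg[i], pg[j], pg[k], pg[l]),
        )
        for i, j, k, l in _torsion_quads(ref)
    ]
    mean = lambda v: float(np.mean(v)) if v else 0.0
    return mean(bond_errs), mean(angle_errs), mean(torsion_errs)


def torsion_fingerprint_deviation(ref: MolecularGraph, gen: MolecularGraph) -> float:
    """Torsion fingerprint deviation in [0, 1]: a hydrogen-free, weighted,
    symmetry-minimized summary of torsional differences. Molecules with no
    scorable torsion are defined as 0."""
    _check_same_graph(ref, gen)
    m1 = to_rdkit(ref, with_coords=True)
    m2 = to_rdkit(gen, with_coords=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfd = TorsionFingerprints.GetTFDBetweenMolecules(m1, m2)
    except (IndexError, ValueError) as exc:
        logger.info("no scorable torsions (%s); TFD defined as 0", exc)
        return 0.0
    return float(np.clip(tfd, 0.0, 1.0))


def stereo_success(input_smiles: str, gen: MolecularGraph) -> bool:
    """True iff the generated structure preserves the declared
    stereochemistry: InChIKey of the input SMILES equals the InChIKey of
    the generated molecule with stereo perceived from its 3D geometry."""
    try:
        return inchikey(parse_smiles(input_smiles)) == inchikey(gen)
    except Exception as exc:
        logger.info("InChIKey comparison failed (%s); counted as failure", exc)
        return False


@dataclass
class MoleculeMetrics:
    name: str
    rmsd: float
    mean_bond_error: float
    mean_angle_error: float
    mean_torsion_error: float
    tfd: float
    stereo_ok: bool


@dataclass
class BatchReport:
    """Per-molecule metrics plus aggregates.

    Geometric means are computed over stereo-successful molecules only;
    ``success_rate`` is the percentage of evaluated molecules whose
    stereochemistry survived. ``include_failures`` recomputes the means
    over every evaluated molecule for sensitivity analysis.
    """

    molecules: list[MoleculeMetrics] = field(default_factory=list)
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def n_evaluated(self) -> int:
        return len(self.molecules)

    @property
    def success_rate(self) -> float:
        if not self.molecules:
            return float("nan")
        return 100.0 * sum(m.stereo_ok for m in self.molecules) / len(self.molecules)

    def means(self, include_failures: bool = False) -> dict[str, float]:
        pool = [m for m in self.molecules if include_failures or m.stereo_ok]
        if not pool:
            return {k: float("nan") for k in
                    ("rmsd", "bond", "angle", "torsion", "tfd")}
        return {
            "rmsd": float(np.mean([m.rmsd for m in pool])),
            "bond": float(np.mean([m.mean_bond_error for m in pool])),
            "angle": float(np.mean([m.mean_angle_error for m in pool])),
            "torsion": float(np.mean([m.mean_torsion_error for m in pool])),
            "tfd": float(np.mean([m.tfd for m in pool])),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": m.name,
                    "rmsd": m.rmsd,
                    "bond": m.mean_bond_error,
                    "angle": m.mean_angle_error,
                    "torsion": m.mean_torsion_error,
                    "tfd": m.tfd,
                    "success": m.stereo_ok,
                }
                for m in self.molecules
            ]
        )

    def summary(self) -> str:
        if not self.molecules:
            return "empty batch: n=0, no means defined"
        mm = self.means()
        lines = [
            f"molecules evaluated: {self.n_evaluated} (failed records: {self.n_failed})",
            f"stereo success: {self.success_rate:.1f}%",
            "means over successful molecules:",
            f"  RMSD (A):     {mm['rmsd']:.3f}",
            f"  bond (A):     {mm['bond']:.3f}",
            f"  angle (deg):  {mm['angle']:.2f}",
            f"  torsion (deg):{mm['torsion']:.1f}",
            f"  TFD:          {mm['tfd']:.3f}",
        ]
        return "\n".join(lines)


def evaluate_pair(
    ref: MolecularGraph,
    gen: MolecularGraph,
    input_smiles: Optional[str] = None,
    symmetry_aware: bool = True,
) -> MoleculeMetrics:
    """All metrics for one reference/generated pair. Stereo success is
    judged against ``input_smiles`` when given, else against the
    reference structure's own InChIKey. The generated molecule's atoms
    are relabeled into the reference order first, so pairs produced from
    different SMILES spellings compare correctly."""
    aligned = align_atom_order(ref, gen)
    bond_e, angle_e, torsion_e = internal_coordinate_errors(ref, aligned)
    if input_smiles is not None:
        ok = stereo_success(input_smiles, gen)
    else:
        try:
            ok = inchikey(ref) == inchikey(gen)
        except Exception:
            ok = False
    return MoleculeMetrics(
        name=ref.source_id or gen.source_id or "",
        rmsd=heavy_atom_rmsd(ref, gen, symmetry_aware=symmetry_aware),
        mean_bond_error=bond_e,
        mean_angle_error=angle_e,
        mean_torsion_error=torsion_e,
        tfd=torsion_fingerprint_deviation(ref, aligned),
        stereo_ok=ok,
    )


def evaluate_batch(
    ref_sdf,
    gen_sdf,
    input_smiles_file=None,
    symmetry_aware: bool = True,
) -> BatchReport:
    """Evaluate paired SDF files record by record.

    Records are matched by name when both sides carry names, falling back
    to file order. Unmatched or mismatched records are reported in the
    batch failure list, never fatal.
    """
    refs = list(read_sdf(ref_sdf))
    gens = list(read_sdf(gen_sdf))
    smiles_by_name: dict[str, str] = {}
    smiles_in_order: list[str] = []
    if input_smiles_file is not None:
        from pathlib import Path

        for ln, line in enumerate(Path(input_smiles_file).read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles_in_order.append(parts[0])
            if len(parts) > 1:
                smiles_by_name[parts[1].strip()] = parts[0]

    gen_by_name = {g.source_id: g for g in gens if g.source_id}
    report = BatchReport()
    for i, ref in enumerate(refs):
        gen = gen_by_name.get(ref.source_id)
        if gen is None:
            gen = gens[i] if i < len(gens) else None
        if gen is None:
            report.n_failed += 1
            report.failures.append(f"{ref.source_id}: no generated record")
            continue
        smiles = smiles_by_name.get(ref.source_id)
        if smiles is None and i < len(smiles_in_order):
            smiles = smiles_in_order[i]
        try:
            report.molecules.append(
                evaluate_pair(ref, gen, input_smiles=smiles, symmetry_aware=symmetry_aware)
            )
        except GraphMismatchError as exc:
            report.n_failed += 1
            report.failures.append(f"{ref.source_id}: {exc}")
    return report
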