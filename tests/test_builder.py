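"""Coordinate generation: bond lengths, valence geometry, stitching,
hydrogens, stereochemistry enforcement, determinism."""

import math

import numpy as np
import pytest

from fragcoord import (
    BondOrder,
    Hybridization,
    Provenance,
    WorkingMolecule,
    canonical_smiles,
    generate_coordinates,
    idealized_geometry,
    ideal_bond_length,
    inchikey,
    open_valence_directions,
    parse_smiles,
    place_hydrogens,
)
from fragcoord.builder import enforce_stereo, ideal_directions, place_atom_rule_based
from fragcoord.geometry import angle_deg, dihedral_deg


class TestIdealBondLength:
    def test_carbon_carbon_single(self):
        assert ideal_bond_length("C", "C", BondOrder.SINGLE) == pytest.approx(1.52)

    def test_carbon_oxygen_single(self):
        assert ideal_bond_length("C", "O", BondOrder.SINGLE) == pytest.approx(1.42)

    @pytest.mark.parametrize("order, expected", [
        (BondOrder.AROMATIC, 1.52 * 0.915),
        (BondOrder.DOUBLE, 1.52 * 0.87),
        (BondOrder.TRIPLE, 1.52 * 0.78),
    ])
    def test_order_scaling(self, order, expected):
        assert ideal_bond_length("C", "C", order) == pytest.approx(expected)

    def test_symmetric_in_elements(self):
        assert ideal_bond_length("C", "N") == ideal_bond_length("N", "C")

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Uuo"):
            ideal_bond_length("C", "Uuo")


class TestIdealDirections:
    def test_sp_one_neighbor_forces_opposite(self):
        dirs = ideal_directions(Hybridization.SP, [np.array([0.0, 0.0, 1.0])])
        assert len(dirs) == 1
        np.testing.assert_allclose(dirs[0], [0, 0, -1], atol=1e-12)

    def test_sp3_fresh_shell_is_tetrahedral(self):
        dirs = ideal_directions(Hybridization.SP3, [])
        assert len(dirs) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                ang = math.degrees(
                    math.acos(np.clip(np.dot(dirs[i], dirs[j]), -1, 1))
                )
                assert ang == pytest.approx(109.47, abs=0.01)

    def test_sp2_completion_is_coplanar_at_120(self):
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])
        (d,) = ideal_directions(Hybridization.SP2, [u, v])
        assert abs(d[2]) < 1e-10  # in plane
        for known in (u, v):
            ang = math.degrees(math.acos(np.clip(np.dot(d, known), -1, 1)))
            assert ang == pytest.approx(120.0, abs=0.01)

    def test_sp3_two_known_completes_tetrahedron(self):
        base = ideal_directions(Hybridization.SP3, [])
        rest = ideal_directions(Hybridization.SP3, base[:2])
        assert len(rest) == 2
        for d in rest:
            for known in base[:2]:
                ang = math.degrees(math.acos(np.clip(np.dot(d, known), -1, 1)))
                assert ang == pytest.approx(109.47, abs=0.01)

    def test_directions_are_unit_norm(self):
        for hyb in (Hybridization.SP, Hybridization.SP2, Hybridization.SP3):
            for d in ideal_directions(hyb, []):
                assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)


class TestRulePlacement:
    def test_first_atom_at_origin(self):
        work = WorkingMolecule(graph=parse_smiles("CC"))
        place_atom_rule_based(work, 0)
        np.testing.assert_array_equal(work.coords[0], np.zeros(3))

    def test_second_atom_at_ideal_length(self):
        work = WorkingMolecule(graph=parse_smiles("CC"))
        place_atom_rule_based(work, 0)
        place_atom_rule_based(work, 1, parent=0)
        assert np.linalg.norm(work.coords[1] - work.coords[0]) == pytest.approx(1.52)

    def test_butane_backbone_is_anti(self):
        mol, _ = generate_coordinates("CCCC")
        c = mol.coords_array()
        assert abs(dihedral_deg(*c)) == pytest.approx(180.0, abs=0.5)

    def test_unplaced_anchor_raises(self):
        work = WorkingMolecule(graph=parse_smiles("CC"))
        with pytest.raises(ValueError):
            open_valence_directions(work, 0)

    def test_hexane_geometry_contract(self):
        mol, report = generate_coordinates("CCCCCC")
        c = mol.coords_array()
        for b in mol.bonds:
            d = np.linalg.norm(c[b.a] - c[b.b])
            assert d == pytest.approx(1.52, abs=1e-3)
        for i in range(3):
            tau = dihedral_deg(c[i], c[i + 1], c[i + 2], c[i + 3])
            assert abs(tau) == pytest.approx(180.0, abs=0.5)
        assert report.n_rule_atoms == 6 and report.n_fragment_atoms == 0


class TestFragmentPlacement:
    def test_benzene_identity_placement(self, fixture_library, ring_templates):
        mol, report = generate_coordinates(
            "c1ccccc1", lib=fixture_library, templates=ring_templates
        )
        assert set(report.provenance.values()) == {Provenance.FRAGMENT_EXACT}
        from fragcoord import heavy_atom_rmsd

        assert heavy_atom_rmsd(idealized_geometry("benzene"), mol) < 1e-4

    def test_rigidity_of_placed_fragment(self, fixture_library, ring_templates):
        ref = idealized_geometry("naphthalene").coords_array()
        mol, _ = generate_coordinates(
            "c1ccc2ccccc2c1", lib=fixture_library, templates=ring_templates
        )
        gen = mol.coords_array()
        # all intra-fragment distances preserved to 1e-6 relative
        for i in range(10):
            for j in range(i + 1, 10):
                dr = np.linalg.norm(ref[i] - ref[j])
                dg = np.linalg.norm(gen[i] - gen[j])
                assert dg == pytest.approx(dr, rel=1e-6)

    def test_biphenyl_stitching(self, fixture_library, ring_templates):
        mol, report = generate_coordinates(
            "c1ccccc1-c1ccccc1", lib=fixture_library, templates=ring_templates
        )
        assert report.n_fragment_atoms == 12
        assert report.n_rule_atoms == 0
        assert report.n_fragments_placed == 2
        c = mol.coords_array()
        link = np.linalg.norm(c[5] - c[6])
        assert link == pytest.approx(ideal_bond_length("C", "C"), abs=1e-3)

    def test_generic_ring_provenance(self, ring_templates):
        mol, report = generate_coordinates("C1CCOCC1", templates=ring_templates)
        ring_provs = {report.provenance[i] for i in range(6)}
        assert ring_provs == {Provenance.FRAGMENT_GENERIC}

    def test_empty_library_falls_back_to_rules(self):
        mol, report = generate_coordinates("c1ccccc1")
        assert set(report.provenance.values()) == {Provenance.RULE}


class TestRingClosure:
    def test_benzene_from_fragment_has_no_long_closures(self, fixture_library,
                                                        ring_templates):
        _, report = generate_coordinates("c1ccccc1", lib=fixture_library,
                                         templates=ring_templates)
        assert report.long_closure_bonds == []

    def test_acyclic_molecule_has_empty_closure_list(self):
        _, report = generate_coordinates("CCOCC")
        assert report.long_closure_bonds == []

    def test_macrocycle_closure_flagged_and_reproducible(self, ring_templates):
        small = [t for t in ring_templates if len(t.coords) <= 6]
        reports = [
            generate_coordinates("C1CCCCCCCCCCC1", templates=small)[1]
            for _ in range(2)
        ]
        assert reports[0].long_closure_bonds == reports[1].long_closure_bonds
        assert len(reports[0].long_closure_bonds) >= 1


class TestHydrogens:
    def _built_h(self, smiles):
        work = WorkingMolecule(graph=parse_smiles(smiles))
        from fragcoord.builder import _dfs_order

        for atom, par in _dfs_order(work.graph):
            place_atom_rule_based(work, atom, parent=par)
        place_hydrogens(work)
        return work

    def test_methane_tetrahedral(self):
        work = self._built_h("C")
        hs = work.h_coords[0]
        assert len(hs) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                ang = angle_deg(hs[i], work.coords[0], hs[j])
                assert ang == pytest.approx(109.47, abs=0.1)

    def test_water_angle(self):
        work = self._built_h("O")
        h1, h2 = work.h_coords[0]
        assert angle_deg(h1, work.coords[0], h2) == pytest.approx(109.47, abs=0.1)

    def test_benzene_hydrogens_in_ring_plane(self, fixture_library, ring_templates):
        mol = parse_smiles("c1ccccc1")
        work = WorkingMolecule(graph=mol)
        from fragcoord.builder import _plan_fragments, place_fragment

        groups, _ = _plan_fragments(mol, fixture_library, ring_templates, 5)
        place_fragment(work, groups[0].template_coords, groups[0].member_atoms,
                       groups[0].provenance)
        place_hydrogens(work)
        ring = np.array([work.coords[i] for i in range(6)])
        normal = np.cross(ring[1] - ring[0], ring[2] - ring[0])
        normal /= np.linalg.norm(normal)
        for i in range(6):
            (h,) = work.h_coords[i]
            assert abs(np.dot(h - ring[0], normal)) < 0.01


class TestStereoEnforcement:
    def test_matching_parity_leaves_coordinates_alone(self):
        _, report = generate_coordinates("CCCC")
        assert report.stereo_corrections == 0

    def test_inverted_center_corrected_to_declared_key(self):
        smi = "F[C@H](Cl)Br"
        mol, report = generate_coordinates(smi)
        assert inchikey(mol) == inchikey(parse_smiles(smi))

    def test_both_enantiomers_buildable(self):
        for smi in ("F[C@H](Cl)Br", "F[C@@H](Cl)Br"):
            mol, _ = generate_coordinates(smi)
            assert inchikey(mol) == inchikey(parse_smiles(smi))

    def test_trans_double_bond_torsion(self):
        mol, _ = generate_coordinates("C/C=C/C")
        c = mol.coords_array()
        assert abs(dihedral_deg(*c)) == pytest.approx(180.0, abs=1.0)
        assert inchikey(mol) == inchikey(parse_smiles("C/C=C/C"))

    def test_cis_double_bond_torsion(self):
        mol, _ = generate_coordinates("C/C=C\\C")
        c = mol.coords_array()
        assert abs(dihedral_deg(*c)) == pytest.approx(0.0, abs=1.0)
        assert inchikey(mol) == inchikey(parse_smiles("C/C=C\\C"))


class TestGenerate:
    def test_graph_preserved(self, fixture_library, ring_templates):
        smi = "CC(=O)Nc1ccccc1O"
        mol, _ = generate_coordinates(smi, lib=fixture_library, templates=ring_templates)
        assert canonical_smiles(mol) == canonical_smiles(parse_smiles(smi))
        assert mol.has_coords

    def test_bit_identical_reruns(self, fixture_library, ring_templates):
        smi = "N[C@@H](Cc1ccccc1)C(=O)O"
        a, _ = generate_coordinates(smi, lib=fixture_library, templates=ring_templates)
        b, _ = generate_coordinates(smi, lib=fixture_library, templates=ring_templates)
        np.testing.assert_array_equal(a.coords_array(), b.coords_array())

    def test_batch_isolates_failures(self, fixture_library):
        from fragcoord import generate_batch

        results = list(generate_batch(["CCO", "not-a-smiles", "CCC"]))
        assert len(results) == 3
        assert results[0][3] is None and results[2][3] is None
        assert results[1][1] is None and results[1][3] is not None
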