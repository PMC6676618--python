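"""Metric suite: RMSD, internal-coordinate errors, TFD, stereo, batches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragcoord import (
    evaluate_batch,
    evaluate_pair,
    heavy_atom_rmsd,
    idealized_geometry,
    inchikey,
    internal_coordinate_errors,
    parse_smiles,
    stereo_success,
    torsion_fingerprint_deviation,
    write_sdf,
)
from fragcoord.evaluation import GraphMismatchError
from fragcoord.geometry import (
    circular_diff_deg,
    dihedral_deg,
    kabsch_rmsd,
    rotation_about_axis,
)


def _rigid(coords, rng):
    rot = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 2 * np.pi))
    return coords @ rot.T + rng.normal(size=3)


class TestRmsd:
    def test_identical_is_zero(self):
        ref = idealized_geometry("benzene")
        assert heavy_atom_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        ref = idealized_geometry("naphthalene")
        rng = np.random.default_rng(3)
        moved = ref.with_coords(_rigid(ref.coords_array(), rng))
        assert heavy_atom_rmsd(ref, moved) < 1e-6

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_invariance_property(self, seed):
        ref = idealized_geometry("cyclohexane_chair")
        rng = np.random.default_rng(seed)
        moved = ref.with_coords(_rigid(ref.coords_array(), rng))
        assert heavy_atom_rmsd(ref, moved, symmetry_aware=False) < 1e-6

    def test_two_point_closed_form(self):
        # collinear pairs at separation 2 vs 4: optimal alignment leaves
        # each point 1.0 from its partner
        p = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        q = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert kabsch_rmsd(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self):
        ref = idealized_geometry("benzene")
        rng = np.random.default_rng(11)
        gen = ref.with_coords(ref.coords_array() + rng.normal(0, 0.2, (6, 3)))
        assert heavy_atom_rmsd(ref, gen) == pytest.approx(
            heavy_atom_rmsd(gen, ref), abs=1e-9
        )

    def test_symmetry_aware_never_worse_than_identity(self):
        ref = idealized_geometry("benzene")
        rng = np.random.default_rng(5)
        for _ in range(10):
            gen = ref.with_coords(ref.coords_array() + rng.normal(0, 0.3, (6, 3)))
            assert heavy_atom_rmsd(ref, gen) <= heavy_atom_rmsd(
                ref, gen, symmetry_aware=False
            ) + 1e-12

    def test_symmetry_rescues_relabeled_ring(self):
        # puckered ring relabeled one step around: the identity mapping
        # pairs each vertex with its neighbor, but a graph automorphism
        # recovers the exact superposition
        ref = idealized_geometry("benzene")
        c = ref.coords_array().copy()
        c[:, 2] += 0.3 * (-1.0) ** np.arange(6)
        puckered = ref.with_coords(c)
        rolled = ref.with_coords(np.roll(c, 1, axis=0))
        assert heavy_atom_rmsd(puckered, rolled, symmetry_aware=False) > 0.5
        assert heavy_atom_rmsd(puckered, rolled) < 1e-9

    def test_graph_mismatch_rejected(self):
        with pytest.raises(GraphMismatchError):
            heavy_atom_rmsd(
                idealized_geometry("benzene"), idealized_geometry("pyridine")
            )


class TestInternalCoordinates:
    def test_identical_is_all_zero(self):
        ref = idealized_geometry("cyclohexane_chair")
        assert internal_coordinate_errors(ref, ref) == (0.0, 0.0, 0.0)

    def test_single_stretched_bond_averages_down(self):
        ref = parse_smiles("CCCCCCCCCCC")  # 11 atoms, 10 bonds
        coords = np.zeros((11, 3))
        coords[:, 0] = np.arange(11) * 1.5
        ref3d = ref.with_coords(coords)
        stretched = coords.copy()
        stretched[10, 0] += 0.1  # terminal atom moved along the bond
        gen = ref.with_coords(stretched)
        bond_e, _, _ = internal_coordinate_errors(ref3d, gen)
        assert bond_e == pytest.approx(0.1 / 10, abs=1e-12)

    def test_torsion_difference_is_circular(self):
        assert circular_diff_deg(170.0, -170.0) == pytest.approx(20.0)
        assert circular_diff_deg(-170.0, 170.0) == pytest.approx(20.0)
        assert circular_diff_deg(10.0, 350.0) == pytest.approx(20.0)

    def test_invariant_under_rigid_motion(self):
        ref = idealized_geometry("cyclopentane")
        rng = np.random.default_rng(8)
        moved = ref.with_coords(_rigid(ref.coords_array(), rng))
        b, a, t = internal_coordinate_errors(ref, moved)
        assert b < 1e-9 and a < 1e-6 and t < 1e-6


class TestTfd:
    def _butane_pair(self):
        anti = idealized_geometry("butane_anti")
        c = anti.coords_array().copy()
        rot = rotation_about_axis(c[2] - c[1], np.pi)
        c[3] = c[2] + rot @ (c[3] - c[2])
        eclipsed = anti.with_coords(c)
        return anti, eclipsed

    def test_identical_is_zero(self):
        anti, _ = self._butane_pair()
        assert torsion_fingerprint_deviation(anti, anti) == 0.0

    def test_anti_vs_eclipsed_is_maximal(self):
        anti, eclipsed = self._butane_pair()
        assert abs(dihedral_deg(*eclipsed.coords_array())) < 1e-6
        assert torsion_fingerprint_deviation(anti, eclipsed) == pytest.approx(1.0)

    def test_bounded_and_rigid_invariant(self):
        anti, eclipsed = self._butane_pair()
        rng = np.random.default_rng(4)
        moved = eclipsed.with_coords(_rigid(eclipsed.coords_array(), rng))
        v1 = torsion_fingerprint_deviation(anti, eclipsed)
        v2 = torsion_fingerprint_deviation(anti, moved)
        assert 0.0 <= v1 <= 1.0
        assert v1 == pytest.approx(v2, abs=1e-6)

    def test_no_torsions_defined_as_zero(self):
        benzene = idealized_geometry("benzene")
        assert torsion_fingerprint_deviation(benzene, benzene) in (0.0,)


class TestStereoSuccess:
    def test_achiral_molecule_succeeds(self):
        assert stereo_success("c1ccccc1", idealized_geometry("benzene"))

    def test_wrong_enantiomer_fails(self):
        built = idealized_geometry("tetrahedral_center")  # realizes F[C@H](Cl)Br
        assert stereo_success("F[C@H](Cl)Br", built)
        assert not stereo_success("F[C@@H](Cl)Br", built)

    def test_trans_geometry_vs_declarations(self):
        built = idealized_geometry("trans_2_butene")
        assert stereo_success("C/C=C/C", built)
        assert not stereo_success("C/C=C\\C", built)


class TestBatch:
    def test_identical_files_all_zero(self, tmp_path):
        mols = [idealized_geometry(n) for n in ("benzene", "cyclohexane_chair")]
        ref, gen = tmp_path / "ref.sdf", tmp_path / "gen.sdf"
        write_sdf(mols, ref)
        write_sdf(mols, gen)
        report = evaluate_batch(ref, gen)
        assert report.success_rate == 100.0
        means = report.means()
        assert means["rmsd"] == pytest.approx(0.0, abs=1e-6)
        assert means["bond"] == pytest.approx(0.0, abs=1e-6)

    def test_means_exclude_stereo_failures(self, tmp_path):
        names = ["benzene", "pyridine", "butane_anti", "tetrahedral_center"]
        refs = [idealized_geometry(n) for n in names]
        gens = [idealized_geometry(n) for n in names]
        # break stereo of the last molecule: swap F and Cl positions
        c = gens[3].coords_array().copy()
        c[[0, 2]] = c[[2, 0]]
        gens[3] = gens[3].with_coords(c)
        ref_p, gen_p = tmp_path / "r.sdf", tmp_path / "g.sdf"
        write_sdf(refs, ref_p)
        write_sdf(gens, gen_p)
        smi = tmp_path / "in.smi"
        smi.write_text(
            "c1ccccc1 benzene\nc1ccncc1 pyridine\nCCCC butane_anti\n"
            "F[C@H](Cl)Br tetrahedral_center\n"
        )
        report = evaluate_batch(ref_p, gen_p, input_smiles_file=smi)
        assert report.n_evaluated == 4
        assert report.success_rate == pytest.approx(75.0)
        # rmsd mean over the 3 successes only: all identical -> 0
        assert report.means()["rmsd"] == pytest.approx(0.0, abs=1e-6)
        assert report.means(include_failures=True)["rmsd"] > 0.1

    def test_empty_batch_flagged(self, tmp_path):
        ref, gen = tmp_path / "r.sdf", tmp_path / "g.sdf"
        write_sdf([], ref)
        write_sdf([], gen)
        report = evaluate_batch(ref, gen)
        assert report.n_evaluated == 0
        assert np.isnan(report.success_rate)
        assert "n=0" in report.summary()

    def test_pair_metrics_container(self):
        ref = idealized_geometry("benzene")
        m = evaluate_pair(ref, ref, input_smiles="c1ccccc1")
        assert m.stereo_ok and m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert 0.0 <= m.tfd <= 1.0
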