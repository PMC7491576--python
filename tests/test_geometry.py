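import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fenmor as fm
from fenmor.errors import DataError, SelectionError
from fenmor.geometry import unwrap_degrees
from fenmor.structure import FENTANYL_SUBSTITUENTS

from conftest import build_system, make_selmap


def two_point_system(pos_a, pos_b):
    return build_system(
        [("N1", 100, "LIG", "L"), ("OD1", 1, "ASP", "A")],
        [[pos_a, pos_b]],
    )


class TestMinHeavyDistance:
    def test_3_4_5_triangle(self):
        s = two_point_system((0, 0, 0), (3, 4, 0))
        assert fm.min_heavy_distance(s, 0, [0], [1]) == pytest.approx(5.0)

    def test_minimum_rule(self):
        s = build_system(
            [("N1", 100, "LIG", "L"), ("OD1", 1, "ASP", "A"),
             ("OD2", 1, "ASP", "A")],
            [[(0, 0, 0), (0, 0, 2), (0, 0, 9)]],
        )
        assert fm.min_heavy_distance(s, 0, [0], [1, 2]) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-10, 10, size=(40, 3))
        rows = [("C%d" % i, 1 + i // 20, "ALA", "A") for i in range(40)]
        s = build_system(rows, [coords])
        a, b = list(range(20)), list(range(20, 40))
        oracle = min(np.linalg.norm(coords[i] - coords[j])
                     for i in a for j in b)
        assert fm.min_heavy_distance(s, 0, a, b) == pytest.approx(oracle)

    def test_symmetry_and_empty_set_error(self):
        s = two_point_system((0, 0, 0), (1, 2, 2))
        assert fm.min_heavy_distance(s, 0, [0], [1]) == \
            fm.min_heavy_distance(s, 0, [1], [0])
        with pytest.raises(SelectionError):
            fm.min_heavy_distance(s, 0, [], [1])


class TestFenH297Distance:
    @pytest.fixture()
    def his_system(self):
        # N1 at origin; NE2 3 A away, ND1 5 A away
        s = build_system(
            [("N1", 100, "LIG", "L"), ("ND1", 1, "HIS", "A"),
             ("NE2", 1, "HIS", "A")],
            [[(0, 0, 0), (5, 0, 0), (0, 3, 0)]],
        )
        selmap = make_selmap(his_Ndelta=1, his_Nepsilon=2)
        return s, selmap

    def test_hid_uses_epsilon_nitrogen(self, his_system):
        s, selmap = his_system
        assert fm.fen_h297_distance(s, 0, selmap, "HID") == pytest.approx(3.0)

    def test_hie_uses_delta_nitrogen(self, his_system):
        s, selmap = his_system
        assert fm.fen_h297_distance(s, 0, selmap, "HIE") == pytest.approx(5.0)

    def test_hip_falls_back_to_epsilon(self, his_system):
        s, selmap = his_system
        assert fm.fen_h297_distance(s, 0, selmap, "HIP") == pytest.approx(3.0)

    def test_unknown_state_rejected(self, his_system):
        s, selmap = his_system
        with pytest.raises(DataError):
            fm.fen_h297_distance(s, 0, selmap, "HISX")


class TestDeltaZ:
    def test_simple_difference(self):
        s = build_system(
            [("N1", 100, "LIG", "L"), ("CA", 1, "ALA", "A")],
            [[(5, 5, 10), (0, 0, 2)]],
        )
        selmap = make_selmap()
        assert fm.delta_z(s, 0, selmap) == pytest.approx(8.0)

    def test_excluded_range_does_not_change_value(self):
        rows = [("N1", 100, "LIG", "L"), ("CA", 5, "ALA", "A"),
                ("CA", 1, "ALA", "A")]  # resid 1 will be excluded
        coords = [[(0, 0, 10), (0, 0, 2), (0, 0, 500)]]
        s = build_system(rows, coords)
        selmap = make_selmap(receptor_com_atoms=np.array([1, 2]),
                             excluded_terminal_residues=((1, 1), (999, 999)))
        assert fm.delta_z(s, 0, selmap) == pytest.approx(8.0)

    def test_matches_atomwise_oracle(self, toy):
        system, _, selmap = toy
        pos = system.positions(3)
        masses = system.atoms["mass"].to_numpy()
        lig = selmap.ligand_heavy
        rec = selmap.receptor_com_retained(system)

        def com_z(idx):
            num = sum(masses[i] * pos[i][2] for i in idx)
            return num / sum(masses[i] for i in idx)

        assert fm.delta_z(system, 3, selmap) == pytest.approx(
            com_z(lig) - com_z(rec), abs=1e-9)


class TestLigandRMSD:
    def test_reference_vs_itself_is_zero(self, toy):
        system, _, selmap = toy
        assert fm.ligand_rmsd(system, 0, 0, selmap) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_translation_of_whole_system_is_zero(self, toy):
        system, _, selmap = toy
        coords = np.concatenate([system.coords[:1],
                                 system.coords[:1] + np.array([3.0, -2.0, 7.0])])
        moved = build_system(
            [(r["name"], r["resid"], r["resname"], r["chain"])
             for _, r in system.atoms.iterrows()], coords)
        assert fm.ligand_rmsd(moved, 1, 0, selmap) == pytest.approx(0.0, abs=1e-6)

    def test_pure_ligand_shift_measures_displacement(self, toy):
        system, _, selmap = toy
        coords = np.concatenate([system.coords[:1], system.coords[:1].copy()])
        coords[1, selmap.ligand_heavy] += np.array([0.0, 0.0, 2.0])
        shifted = build_system(
            [(r["name"], r["resid"], r["resname"], r["chain"])
             for _, r in system.atoms.iterrows()], coords)
        assert fm.ligand_rmsd(shifted, 1, 0, selmap) == pytest.approx(2.0, abs=1e-6)

    def test_invariant_under_rigid_rotation(self, toy):
        system, _, selmap = toy
        R = Rotation.from_euler("zyx", [31, -54, 17], degrees=True).as_matrix()
        coords = np.stack([system.coords[0], system.coords[5] @ R.T + 4.0])
        rotated = build_system(
            [(r["name"], r["resid"], r["resname"], r["chain"])
             for _, r in system.atoms.iterrows()], coords)
        expected = fm.ligand_rmsd(system, 5, 0, selmap)
        assert fm.ligand_rmsd(rotated, 1, 0, selmap) == pytest.approx(
            expected, abs=1e-5)


def dihedral_oracle(p0, p1, p2, p3):
    """Textbook signed dihedral: project the outer bonds onto the plane
    normal to the central bond (IUPAC sign)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))


class TestChi2:
    def chi_system(self, p3, resname="HIS", fourth="ND1"):
        pts = np.array([(0.0, 1.0, 0.0), (0.0, 0.0, 0.0),
                        (1.5, 0.0, 0.0), p3])
        rows = [("CA", 1, resname, "A"), ("CB", 1, resname, "A"),
                ("CG", 1, resname, "A"), (fourth, 1, resname, "A")]
        return build_system(rows, [pts]), pts

    def test_planar_anti_is_180(self):
        s, _ = self.chi_system((2.5, -1.0, 0.0))
        assert abs(fm.chi2(s, 0, 1)) == pytest.approx(180.0)

    def test_mirror_flips_sign(self):
        s, pts = self.chi_system((2.5, -0.5, 0.8))
        mirrored = build_system(
            [("CA", 1, "HIS", "A"), ("CB", 1, "HIS", "A"),
             ("CG", 1, "HIS", "A"), ("ND1", 1, "HIS", "A")],
            [pts * np.array([1.0, 1.0, -1.0])])
        assert fm.chi2(mirrored, 0, 1) == pytest.approx(-fm.chi2(s, 0, 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cross_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((4, 3)) * 2.0
        rows = [("CA", 1, "TRP", "A"), ("CB", 1, "TRP", "A"),
                ("CG", 1, "TRP", "A"), ("CD1", 1, "TRP", "A")]
        s = build_system(rows, [pts])
        # the library kernel runs in single precision; 1e-4 deg is far below
        # any physically meaningful dihedral difference
        assert fm.chi2(s, 0, 1) == pytest.approx(dihedral_oracle(*pts), abs=1e-4)

    def test_missing_atom_raises(self):
        s = build_system([("CA", 1, "HIS", "A"), ("CB", 1, "HIS", "A")],
                         [[(0, 0, 0), (1, 0, 0)]])
        with pytest.raises(SelectionError):
            fm.chi2(s, 0, 1)

    def test_unwrap_is_continuous_through_wrap(self):
        series = [170.0, 178.0, -176.0, -168.0]
        un = unwrap_degrees(series)
        assert np.all(np.abs(np.diff(un)) < 10)


class TestVerticalAngle:
    def axis_system(self, head):
        s = build_system(
            [("N1", 100, "LIG", "L"), ("C13", 100, "LIG", "L"),
             ("CA", 1, "ALA", "A")],
            [[(0, 0, 0), head, (0, 0, -5)]],
        )
        selmap = make_selmap(ligand_axis_head=np.array([1]),
                             receptor_com_atoms=np.array([2]))
        return s, selmap

    @pytest.mark.parametrize("head,expected", [
        ((0, 0, 3), 0.0),
        ((2, 0, 0), 90.0),
        ((0, 1, 1), 45.0),
    ])
    def test_closed_forms(self, head, expected):
        s, selmap = self.axis_system(head)
        assert fm.vertical_angle(s, 0, selmap) == pytest.approx(expected)

    def test_zero_length_axis_raises(self):
        s, selmap = self.axis_system((0, 0, 0))
        with pytest.raises(DataError):
            fm.vertical_angle(s, 0, selmap)


class TestInvariances:
    def test_translation_leaves_descriptors_unchanged(self, toy):
        system, _, selmap = toy
        shift = np.array([11.0, -4.0, 6.0])
        moved = build_system(
            [(r["name"], r["resid"], r["resname"], r["chain"])
             for _, r in system.atoms.iterrows()],
            system.coords[:2] + shift)
        for f in (0, 1):
            assert fm.fen_d147_distance(moved, f, selmap) == pytest.approx(
                fm.fen_d147_distance(system, f, selmap))
            assert fm.delta_z(moved, f, selmap) == pytest.approx(
                fm.delta_z(system, f, selmap))
            assert fm.vertical_angle(moved, f, selmap) == pytest.approx(
                fm.vertical_angle(system, f, selmap))

    def test_rotation_about_z_preserves_distances_and_dz(self, toy):
        system, _, selmap = toy
        R = Rotation.from_euler("z", 73, degrees=True).as_matrix()
        moved = build_system(
            [(r["name"], r["resid"], r["resname"], r["chain"])
             for _, r in system.atoms.iterrows()],
            system.coords[:1] @ R.T)
        assert fm.fen_d147_distance(moved, 0, selmap) == pytest.approx(
            fm.fen_d147_distance(system, 0, selmap))
        assert fm.delta_z(moved, 0, selmap) == pytest.approx(
            fm.delta_z(system, 0, selmap))


class TestComXYPositions:
    def test_receptor_entry_at_origin(self, toy):
        system, _, selmap = toy
        rec = selmap.receptor_com_retained(system)
        out = fm.com_xy_positions(system, [0], {"receptor": rec}, selmap)
        row = out.iloc[0]
        assert np.allclose([row.x, row.y, row.z], 0.0, atol=1e-9)

    def test_identity_frame_with_x_reference(self):
        s = build_system(
            [("CA", 1, "ALA", "A"), ("N1", 100, "LIG", "L")],
            [[(0, 0, 0), (1, 2, 3)]],
        )
        selmap = make_selmap(receptor_com_atoms=np.array([0]),
                             ligand_heavy=np.array([1]))
        out = fm.com_xy_positions(s, [0], {"lig": [1]}, selmap,
                                  reference_vector=(1.0, 0.0, 0.0))
        row = out.iloc[0]
        assert np.allclose([row.x, row.y, row.z], [1, 2, 3], atol=1e-9)

    def test_rotation_about_z_recovers_internal_coordinates(self):
        coords0 = np.array([(0.0, 0.0, 0.0), (2.0, 1.0, 3.0), (1.0, 0.0, 0.0)])
        R = Rotation.from_euler("z", 49, degrees=True).as_matrix()
        rows = [("CA", 1, "ALA", "A"), ("N1", 100, "LIG", "L"),
                ("CB", 1, "ALA", "A")]
        selmap = make_selmap(receptor_com_atoms=np.array([0]),
                             ligand_heavy=np.array([1]))
        out0 = fm.com_xy_positions(build_system(rows, [coords0]), [0],
                                   {"lig": [1]}, selmap,
                                   reference_vector=(0, 2))
        out1 = fm.com_xy_positions(build_system(rows, [coords0 @ R.T]), [0],
                                   {"lig": [1]}, selmap,
                                   reference_vector=(0, 2))
        assert np.allclose(out0[["x", "y", "z"]], out1[["x", "y", "z"]],
                           atol=1e-9)

    def test_degenerate_reference_vector_raises(self, toy):
        system, _, selmap = toy
        with pytest.raises(DataError):
            fm.com_xy_positions(system, [0], {"lig": selmap.ligand_heavy},
                                selmap, reference_vector=(0.0, 0.0, 1.0))
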