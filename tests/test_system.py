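"""Internal-coordinate model: building, kinematics, mutation editing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcgate.geometry import bond_angle, dihedral
from mcgate.system import SegmentSpec, apply_mutation, build_system


def make(seq, seg="A"):
    return build_system([SegmentSpec(seg, tuple((nm, i + 1)
                                                for i, nm in enumerate(seq)))])


class TestBuildSystem:
    def test_minimal_single_residue(self):
        sys_ = make(["ALA"])
        assert len(sys_.residues) == 1
        assert len(sys_.segments) == 1
        assert sys_.n_atoms == 6   # N CA C O H CB

    def test_poly_ala_helix_spec(self):
        sys_ = make(["ALA"] * 10)
        assert len(sys_.residues) == 10
        assert len(sys_.segments) == 1
        # backbone torsions flexible by default: phi/psi per residue + omega
        bb = [v for v in sys_.torsion_vars if v.kind == "bb"]
        assert len(bb) == 10 + 10 + 9

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="XXX"):
            make(["ALA", "XXX"])

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            build_system([SegmentSpec("A", ())])


class TestForwardKinematics:
    def test_all_trans_backbone_dihedrals(self):
        sys_ = make(["ALA"] * 3)
        X = sys_.cartesian
        ai = sys_.atom_index
        phi2 = dihedral(X[ai("A", 1, "C")], X[ai("A", 2, "N")],
                        X[ai("A", 2, "CA")], X[ai("A", 2, "C")])
        assert abs(abs(np.degrees(phi2)) - 180) < 1e-6

    def test_idempotent_rebuild(self, toy_open):
        X0 = toy_open.cartesian.copy()
        toy_open.rebuild(force=True)
        assert np.abs(toy_open.cartesian - X0).max() < 1e-9

    def test_torsion_locality(self):
        """Rotating one chi moves only atoms distal to that torsion."""
        sys_ = make(["LEU"] * 3)
        vi = sys_.residue("A", 2).chi_var_indices[0]   # chi1
        X0 = sys_.cartesian.copy()
        sys_.torsion_values[vi] = np.radians(-60.0)
        sys_.mark_dirty([vi])
        sys_.rebuild()
        moved = np.flatnonzero(
            np.linalg.norm(sys_.cartesian - X0, axis=1) > 1e-9)
        # oracle: downstream of chi1 of residue 2 = its CG/CD atoms only
        expected = {sys_.atom_index("A", 2, nm)
                    for nm in ("CG", "CD1", "CD2")}
        assert set(moved) == expected

    def test_root_translation_is_exact(self, helix10):
        X0 = helix10.cartesian.copy()
        helix10.root_positions[0] += [1.0, 2.0, 3.0]
        helix10.rebuild()
        np.testing.assert_allclose(helix10.cartesian - X0,
                                   np.tile([1.0, 2.0, 3.0], (len(X0), 1)),
                                   atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_geometry_for_random_torsions(self, seed):
        """Bond lengths and angles match templates for any torsions."""
        sys_ = make(["SER", "LEU", "GLN"])
        rng = np.random.default_rng(seed)
        sys_.torsion_values[:] = rng.uniform(-np.pi, np.pi,
                                             len(sys_.torsion_vars))
        sys_.mark_dirty(np.arange(len(sys_.torsion_vars)))
        sys_.rebuild()
        X = sys_.cartesian
        for e in sys_.entries:
            if e.refs is None:
                continue
            d = np.linalg.norm(X[e.atom] - X[e.refs[2]])
            assert abs(d - e.bond) < 1e-6
            ang = bond_angle(X[e.refs[1]], X[e.refs[2]], X[e.atom])
            if e.special != "C0":   # C0 angle is measured vs virtual atom
                assert abs(ang - e.angle) < 1e-6


class TestSetAllTrans:
    def test_arg_all_chi_trans(self):
        sys_ = make(["ARG", "ALA"])
        res = sys_.residue("A", 1)
        for vi in res.chi_var_indices:
            sys_.torsion_values[vi] = np.radians(-60.0)
        sys_.mark_dirty(res.chi_var_indices)
        sys_.set_all_trans([("A", 1)])
        for vi in res.chi_var_indices:
            assert sys_.torsion_values[vi] == pytest.approx(np.pi)

    def test_empty_set_identity(self, helix10):
        X0 = helix10.cartesian.copy()
        helix10.set_all_trans([])
        assert np.array_equal(helix10.cartesian, X0)

    def test_untouched_residues_bit_identical(self):
        sys_ = make(["SER", "SER", "SER"])
        for res in sys_.residues:
            for vi in res.chi_var_indices:
                sys_.torsion_values[vi] = np.radians(60.0)
        sys_.mark_dirty(np.arange(len(sys_.torsion_vars)))
        sys_.rebuild()
        X0 = sys_.cartesian.copy()
        sys_.set_all_trans([("A", 2)])
        untouched = sys_.residue("A", 1).atom_indices
        assert np.array_equal(sys_.cartesian[untouched], X0[untouched])

    def test_residue_outside_system_rejected(self, helix10):
        with pytest.raises(KeyError):
            helix10.set_all_trans([("H", 99)])


class TestApplyMutation:
    def test_gly_to_ser_adds_oxygen_preserves_backbone(self):
        sys_ = make(["ALA", "GLY", "ALA"])
        ca0 = sys_.cartesian[sys_.atom_index("A", 2, "CA")].copy()
        mut = apply_mutation(sys_, ("A", 2), "SER")
        assert mut.residue("A", 2).name == "SER"
        assert "OG" in [str(mut.atom_names[i])
                        for i in mut.residue("A", 2).atom_indices]
        np.testing.assert_allclose(
            mut.cartesian[mut.atom_index("A", 2, "CA")], ca0, atol=1e-9)

    def test_mutation_locality(self):
        sys_ = make(["ALA", "GLY", "ALA"])
        mut = apply_mutation(sys_, ("A", 2), "SER")
        for num in (1, 3):
            old = sys_.cartesian[sys_.residue("A", num).atom_indices]
            new = mut.cartesian[mut.residue("A", num).atom_indices]
            np.testing.assert_allclose(new, old, atol=1e-9)

    def test_arg_to_doubly_protonated_his_charge(self):
        sys_ = make(["ARG", "ALA"])
        mut = apply_mutation(sys_, ("A", 1), "HIS", variant="HIP")
        res = mut.residue("A", 1)
        assert sum(int(mut.formal_charges[i])
                   for i in res.atom_indices) == +1
        assert sum(float(mut.charges[i])
                   for i in res.atom_indices) == pytest.approx(1.0)

    def test_adjacent_cys_disulfide(self):
        sys_ = make(["SER", "CYS", "ARG", "ALA"])
        mut = apply_mutation(sys_, ("A", 3), "CYS",
                             disulfide_partner=("A", 2))
        sg_pairs = [(a, b) for (a, b) in mut.bonds
                    if str(mut.atom_names[a]) == "SG"
                    and str(mut.atom_names[b]) == "SG"]
        assert len(sg_pairs) == 1
        assert mut.residue("A", 2).flexible_bond_angles
        assert mut.residue("A", 3).flexible_bond_angles
        assert ("A", 2) in mut.unpin_calphas
        assert ("A", 3) in mut.unpin_calphas

    def test_unreachable_disulfide_rejected(self):
        sys_ = build_system([
            SegmentSpec("A", (("CYS", 1),)),
            SegmentSpec("B", (("CYS", 1),)),
        ])
        sys_.root_positions[1] = [50.0, 0, 0]
        sys_._canon_dirty = [True, True]
        sys_.rebuild()
        with pytest.raises(ValueError, match="distance"):
            apply_mutation(sys_, ("A", 1), "CYS",
                           disulfide_partner=("B", 1))
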