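"""Contact maps, interaction typing, binning, cross-state comparison."""

import numpy as np
import pytest

from mcgate.contacts import (FIG3_SCHEME, FIG6_SCHEME, BinScheme,
                             ContactRecord, aggregate_net_energy,
                             bin_contacts, compare_states, contact_map)
from mcgate.energy import NonbondedOptions, nonbonded_energy
from mcgate.synthetic import table_fixture
from mcgate.system import SegmentSpec, build_system


@pytest.fixture()
def salt_bridge_pair():
    """ARG and ASP segments posed with a ~2.8 A guanidinium-carboxylate
    contact."""
    sys_ = build_system([
        SegmentSpec("R", (("ARG", 1),), group="alpha1"),
        SegmentSpec("D", (("ASP", 1),), group="beta_subunit"),
    ])
    from mcgate.geometry import euler_to_matrix, matrix_to_euler
    from mcgate.synthetic import _rot_between
    nh = sys_.cartesian[sys_.atom_index("R", 1, "NH1")]
    ne = sys_.cartesian[sys_.atom_index("R", 1, "NE")]
    d = (nh - ne) / np.linalg.norm(nh - ne)
    # rotate the ASP segment so its carboxylate points back along -d (the
    # rest of the residue extends away from the arginine), then translate
    # OD1 onto the 2.8 A H-bonding position
    od = sys_.cartesian[sys_.atom_index("D", 1, "OD1")]
    cg = sys_.cartesian[sys_.atom_index("D", 1, "CG")]
    A = _rot_between((cg - od) / np.linalg.norm(cg - od), d)
    R0 = euler_to_matrix(sys_.root_orientations[1])
    sys_.root_orientations[1] = matrix_to_euler(A @ R0)
    sys_.root_positions[1] = A @ sys_.root_positions[1]
    sys_._canon_dirty = [True, True]
    sys_.rebuild()
    od = sys_.cartesian[sys_.atom_index("D", 1, "OD1")]
    sys_.root_positions[1] += (nh + 2.8 * d) - od
    sys_.rebuild()
    return sys_


class TestContactMap:
    def test_distant_groups_empty(self):
        sys_ = build_system([
            SegmentSpec("A", (("LEU", 1),), group="alpha1"),
            SegmentSpec("B", (("LEU", 1),), group="beta_subunit")])
        sys_.root_positions[1] = [80.0, 0, 0]
        sys_._canon_dirty = [True, True]
        sys_.rebuild()
        assert contact_map(sys_, ["A"], ["B"]) == []

    def test_salt_bridge_detected(self, salt_bridge_pair):
        records = contact_map(salt_bridge_pair, ["R"], ["D"])
        assert len(records) == 1
        rec = records[0]
        assert rec.energy < 0
        assert "salt_bridge" in rec.types
        assert "h_bond" in rec.types     # N-H donates to carboxylate O

    def test_decomposition_identity(self, toy_open):
        ga = {"AID"}
        gb = {"IIS0"}
        records = contact_map(toy_open, ga, gb, presence_floor=0.0)
        ra = set(toy_open.segment("AID").residue_indices)
        rb = set(toy_open.segment("IIS0").residue_indices)
        total = nonbonded_energy(toy_open, NonbondedOptions(cutoff=np.inf),
                                 group_filter=(ra, rb)).total
        assert sum(r.energy for r in records) == pytest.approx(total,
                                                               abs=1e-8)

    def test_overlapping_groups_rejected(self, toy_open):
        with pytest.raises(ValueError):
            contact_map(toy_open, ["AID"], ["AID"])

    def test_symmetry(self, toy_open):
        ab = contact_map(toy_open, ["AID"], ["IIS0"])
        ba = contact_map(toy_open, ["IIS0"], ["AID"])
        assert {r.key for r in ab} == {r.key for r in ba}
        for x, y in zip(sorted(ab, key=lambda r: r.key),
                        sorted(ba, key=lambda r: r.key)):
            assert x.energy == pytest.approx(y.energy, abs=1e-10)


class TestClassification:
    def test_helix_hbond_geometry(self, helix10):
        """O(i)..N(i+4) at ~3 A in an ideal helix classifies as h_bond."""
        from mcgate.contacts import classify_interaction
        rec = ContactRecord(("H", 2), ("H", 6), -1.0, e_lj=-0.4,
                            e_coul=-0.6)
        types = classify_interaction(helix10, rec)
        assert "h_bond" in types

    def test_leucine_pair_hydrophobic_only(self):
        sys_ = build_system([
            SegmentSpec("A", (("LEU", 1),), group="alpha1"),
            SegmentSpec("B", (("LEU", 1),), group="beta_subunit")])
        sys_.root_positions[1] = [7.5, 1.0, 0.0]
        sys_._canon_dirty = [True, True]
        sys_.rebuild()
        records = contact_map(sys_, ["A"], ["B"], presence_floor=0.05)
        assert records
        assert records[0].types == {"hydrophobic"}

    def test_repulsive_iff_positive(self):
        rec = ContactRecord(("A", 1), ("B", 1), +0.4)
        assert FIG3_SCHEME.assign(rec.energy) == "repulsive"


class TestBinning:
    @pytest.mark.parametrize("energy,scheme,label", [
        (-1.0, "fig3", "dotted"),         # weakest displayed bin
        (-5.5, "fig3", "thick"),
        (-5.5, "fig6", "thick"),
        (-0.5, "fig3", "not_shown"),      # display-floor class
        (-0.9, "fig3", "dotted"),         # printed boundary inclusive
        (-1.51, "fig3", "thin"),
        (-3.01, "fig3", "intermediate"),
        (-0.5, "fig6", "thin"),
        (-2.51, "fig6", "intermediate"),
        (-0.3, "fig3", "below_floor"),
        (0.2, "fig6", "repulsive"),
    ])
    def test_boundary_assignment(self, energy, scheme, label):
        sch = FIG3_SCHEME if scheme == "fig3" else FIG6_SCHEME
        assert sch.assign(energy) == label

    def test_every_record_gets_exactly_one_bin(self, toy_open):
        records = contact_map(toy_open, ["AID"], ["beta1", "beta2"],
                              presence_floor=0.0)
        bin_contacts(records, FIG3_SCHEME)
        assert all(r.bin_label is not None for r in records)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(edges=(-5.0, -1.0), labels=("a", "b"),
                      display_floor=0.4)


class TestCompareStates:
    def records(self, state, pairs):
        return [ContactRecord(a, b, -1.0, state_label=state)
                for a, b in pairs]

    def test_shared_and_only_semantics(self):
        maps = {
            "open": self.records("open", [(("AID", 1), ("B", 1)),
                                          (("AID", 2), ("B", 2))]),
            "closed": self.records("closed", [(("AID", 1), ("B", 1)),
                                              (("AID", 3), ("B", 3))]),
        }
        comp = compare_states(maps)
        assert comp.classification[((("AID", 1)), (("B", 1)))] == \
            "shared-all"
        assert comp.classification[((("AID", 2)), (("B", 2)))] == \
            "only-open"
        assert comp.classification[((("AID", 3)), (("B", 3)))] == \
            "only-closed"

    def test_empty_maps(self):
        comp = compare_states({"open": [], "closed": []})
        assert comp.presence == {}

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            compare_states({"open": []})


class TestAggregate:
    def test_fixture_sums(self):
        t4 = table_fixture("table4")
        assert aggregate_net_energy(t4, "G402S", "closed") == -0.75
        assert aggregate_net_energy(t4, "G402S", "open") == -2.72
        assert aggregate_net_energy(t4, "G406R", "closed") == -0.81

    def test_fixture_missing_residue_rejected(self):
        t4 = table_fixture("table4")
        with pytest.raises(KeyError):
            aggregate_net_energy(t4, "G999X", "open")

    def test_record_aggregation(self):
        records = [ContactRecord(("AID", 6), ("IIS0", 5), -2.0,
                                 state_label="open"),
                   ContactRecord(("AID", 6), ("IIS0", 4), -1.25,
                                 state_label="open"),
                   ContactRecord(("AID", 6), ("IIS0", 4), -5.0,
                                 state_label="closed")]
        assert aggregate_net_energy(records, ("AID", 6), "open") == -3.25

    def test_empty_records_zero(self):
        assert aggregate_net_energy([], ("AID", 6), "open") == 0.0
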