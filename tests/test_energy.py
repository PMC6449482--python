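"""Nonbonded energy: closed forms, brute-force oracle, shifting behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcgate.energy import (COULOMB_CONSTANT, NonbondedOptions,
                           nonbonded_energy, nonbonded_energy_forces,
                           pair_energy)
from mcgate.topology import AtomTemplate


def atom(charge=0.0, ionized=False, element="C"):
    return AtomTemplate("X", element, charge, ionized=ionized)


NO_CUT = NonbondedOptions(cutoff=np.inf)


class TestPairEnergy:
    def test_zero_at_cutoff(self):
        opts = NonbondedOptions(cutoff=9.0)
        assert pair_energy(atom(), atom(), 9.0, opts) == pytest.approx(0.0)
        assert pair_energy(atom(), atom(), 12.0, opts) == 0.0

    def test_lj_minimum_closed_form(self):
        """At r = rmin_i + rmin_j the 6-12 well depth is -sqrt(e_i e_j)."""
        a, b = atom(element="C"), atom(element="O")
        r = a.lj_rmin_half + b.lj_rmin_half
        expected = -np.sqrt(a.lj_epsilon * b.lj_epsilon)
        assert pair_energy(a, b, r, NO_CUT) == pytest.approx(expected,
                                                            abs=1e-12)

    def test_ionized_coulomb_closed_form_beyond_cutoff(self):
        """Unit charges at 10 A with eps(r) = 4r: E = 332.06/(4*10*10),
        not truncated despite r > 9 because the pair is ionized."""
        a = atom(charge=1.0, ionized=True, element="N")
        b = atom(charge=1.0, ionized=True, element="N")
        opts = NonbondedOptions(cutoff=9.0, dielectric_slope=4.0)
        got = pair_energy(a, b, 10.0, opts)
        lj = pair_energy(atom(element="N"), atom(element="N"), 10.0, NO_CUT)
        assert got - lj == pytest.approx(COULOMB_CONSTANT / 400.0, rel=1e-12)

    def test_symmetry(self):
        a = atom(charge=0.3, element="N")
        b = atom(charge=-0.5, element="O")
        assert pair_energy(a, b, 3.7, NO_CUT) == pair_energy(b, a, 3.7,
                                                             NO_CUT)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(atom(), atom(), 0.0)

    def test_excluded_separations(self):
        assert pair_energy(atom(), atom(), 1.5, bonded_separation=1) == 0.0
        assert pair_energy(atom(), atom(), 2.4, bonded_separation=2) == 0.0
        full = pair_energy(atom(), atom(), 3.0, NO_CUT,
                           bonded_separation=4)
        scaled = pair_energy(atom(), atom(), 3.0, NO_CUT,
                             bonded_separation=3)
        assert scaled == pytest.approx(0.5 * full)


def brute_force_energy(system, opts):
    """Independent all-pairs double loop (cutoff-free reference)."""
    seps = system.bonded_separations(3)
    X = system.cartesian
    total = 0.0
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            sep = seps.get((i, j))
            if sep is not None and sep <= 2:
                continue
            scale = opts.scale14 if sep == 3 else 1.0
            r = float(np.linalg.norm(X[i] - X[j]))
            eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
            rmin = system.lj_rmin_half[i] + system.lj_rmin_half[j]
            sr6 = (rmin / r) ** 6
            e = eps * (sr6 * sr6 - 2 * sr6)
            e += (COULOMB_CONSTANT * system.charges[i] * system.charges[j]
                  / (opts.dielectric_slope * r * r))
            total += scale * e
    return total


class TestSystemEnergy:
    def test_brute_force_oracle(self, dipeptide):
        assert dipeptide.n_atoms <= 100
        got = nonbonded_energy(dipeptide, NO_CUT).total
        want = brute_force_energy(dipeptide, NO_CUT)
        assert abs(got - want) < 1e-8

    def test_decomposition_identity(self, dipeptide):
        bd = nonbonded_energy(dipeptide, NO_CUT)
        per_pair_sum = sum(v["E_total"] for v in bd.per_pair.values())
        assert abs(per_pair_sum - bd.total) < 1e-8

    def test_group_filter_decomposition(self, dipeptide):
        ga = set(dipeptide.segment("A").residue_indices)
        gb = set(dipeptide.segment("B").residue_indices)
        bd = nonbonded_energy(dipeptide, NO_CUT, group_filter=(ga, gb))
        assert abs(sum(v["E_total"] for v in bd.per_pair.values())
                   - bd.total) < 1e-8
        # every reported pair crosses the groups
        for v in bd.per_pair.values():
            ri, rj = v["residue_indices"]
            assert {ri in ga, ri in gb} == {True, False}

    def test_overlapping_groups_rejected(self, dipeptide):
        ga = set(dipeptide.segment("A").residue_indices)
        with pytest.raises(ValueError):
            nonbonded_energy(dipeptide, NO_CUT, group_filter=(ga, ga))

    def test_shifted_force_continuity_at_cutoff(self):
        """Energy and its derivative vanish at the 9 A cutoff."""
        a = atom(charge=0.4, element="O")
        b = atom(charge=-0.2, element="N")
        opts = NonbondedOptions(cutoff=9.0, shift_mode="shifted_force")
        rc = 9.0
        h = 1e-5
        e_at = pair_energy(a, b, rc - 1e-12, opts)
        assert abs(e_at) < 1e-10
        de = (pair_energy(a, b, rc - h, opts)
              - pair_energy(a, b, rc - 2 * h, opts)) / h
        assert abs(de) < 1e-6

    def test_shifted_energy_mode_zero_at_cutoff_only(self):
        a = atom(charge=0.4, element="O")
        b = atom(charge=-0.2, element="N")
        opts = NonbondedOptions(cutoff=9.0, shift_mode="shifted_energy")
        assert abs(pair_energy(a, b, 9.0 - 1e-12, opts)) < 1e-10
        unshifted = pair_energy(a, b, 5.0, NO_CUT)
        shifted = pair_energy(a, b, 5.0, opts)
        assert shifted == pytest.approx(unshifted
                                        - pair_energy(a, b, 9.0, NO_CUT),
                                        abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_motion_invariance(self, seed):
        from scipy.spatial.transform import Rotation
        from mcgate.system import SegmentSpec, build_system
        sys_ = build_system([SegmentSpec("A", (("GLN", 1), ("LEU", 2)))])
        e0 = nonbonded_energy(sys_, NO_CUT).total
        rng = np.random.default_rng(seed)
        sys_.root_positions[0] += rng.normal(scale=10.0, size=3)
        sys_.root_orientations[0] = Rotation.random(
            rng=rng).as_euler("ZYX")
        sys_.rebuild()
        assert abs(nonbonded_energy(sys_, NO_CUT).total - e0) < 1e-8

    def test_forces_match_numerical_gradient(self, dipeptide):
        opts = NonbondedOptions(cutoff=9.0)
        _, grad = nonbonded_energy_forces(dipeptide, opts)
        X0 = dipeptide.cartesian.copy()
        rng = np.random.default_rng(4)
        for _ in range(5):
            i = int(rng.integers(dipeptide.n_atoms))
            k = int(rng.integers(3))
            h = 1e-6
            for sign in (1, -1):
                dipeptide.cartesian[i, k] = X0[i, k] + sign * h
                if sign == 1:
                    ep, _ = nonbonded_energy_forces(dipeptide, opts)
                else:
                    em, _ = nonbonded_energy_forces(dipeptide, opts)
            dipeptide.cartesian[i, k] = X0[i, k]
            assert grad[i, k] == pytest.approx((ep - em) / (2 * h),
                                               rel=1e-4, abs=1e-6)

    def test_distant_neutral_atoms_zero(self):
        from mcgate.system import SegmentSpec, build_system
        sys_ = build_system([SegmentSpec("A", (("ALA", 1),)),
                             SegmentSpec("B", (("ALA", 1),))])
        sys_.root_positions[1] = [500.0, 0, 0]
        sys_._canon_dirty = [True, True]
        sys_.rebuild()
        bd = nonbonded_energy(sys_, NonbondedOptions(cutoff=9.0))
        inter = [v for k, v in bd.per_pair.items()
                 if k[0][0] != k[1][0]]
        assert sum(v["E_total"] for v in inter) == 0.0
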