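"""Flat-bottom restraints: the pin law, builders, additivity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcgate.restraints import (DistanceRestraint, HelixHBondRestraint,
                               PinRestraint, RestraintSet,
                               make_helix_restraints,
                               make_pins_from_template, pin_energy,
                               restraint_energy)
from mcgate.synthetic import STRAND_PHI, STRAND_PSI, _set_backbone


class TestPinLaw:
    @pytest.mark.parametrize("d", [1.0, 2.0, 2.5])
    def test_flat_bottom_parabola(self, d):
        """Zero on [0, d]; k (dev - d)^2 beyond; continuous at d."""
        k = 10.0
        assert pin_energy(0.0, d, k) == 0.0
        assert pin_energy(0.9 * d, d, k) == 0.0
        assert pin_energy(d, d, k) == 0.0
        for dev in (d + 0.5, d + 1.7):
            assert pin_energy(dev, d, k) == pytest.approx(
                k * (dev - d) ** 2)
        eps = 1e-9
        assert pin_energy(d + eps, d, k) < 1e-15

    def test_default_constants(self):
        assert pin_energy(1.5) == pytest.approx(10.0 * 0.25)  # d=1, k=10

    def test_negative_deviation_rejected(self):
        with pytest.raises(ValueError):
            pin_energy(-0.1)

    @given(st.floats(0.0, 10.0), st.floats(0.1, 3.0), st.floats(0.1, 50.0))
    def test_monotone_outside_window(self, dev, d, k):
        e = pin_energy(dev, d, k)
        assert e >= 0.0
        if dev > d:
            assert pin_energy(dev + 0.1, d, k) > e


class TestBuilders:
    def test_pins_from_template_width(self, helix10):
        sel = [("H", i) for i in range(1, 6)]
        anchors = {k: helix10.cartesian[helix10.atom_index(*k, "CA")]
                   for k in sel}
        pins = make_pins_from_template(helix10, anchors, sel, d=2.5)
        assert len(pins) == 5
        assert all(p.half_width_d == 2.5 for p in pins)

    def test_pins_missing_correspondence(self, helix10):
        with pytest.raises(ValueError, match="orphan|correspondence"):
            make_pins_from_template(helix10, {}, [("H", 1)])

    def test_empty_selection(self, helix10):
        assert make_pins_from_template(helix10, {}, []) == []

    def test_system_at_template_zero_energy(self, helix10):
        sel = [("H", i) for i in range(1, 11)]
        anchors = {k: helix10.cartesian[helix10.atom_index(*k, "CA")]
                   for k in sel}
        pins = make_pins_from_template(helix10, anchors, sel)
        e, _ = restraint_energy(helix10, RestraintSet(pins=pins))
        assert e == 0.0

    def test_helix_restraint_pair_count(self, helix10):
        hr = make_helix_restraints(helix10, "H", range(1, 11))
        assert len(hr.pairs) == 6   # n - 4

    def test_helix_restraint_near_zero_on_ideal_helix(self, helix10):
        hr = make_helix_restraints(helix10, "H", range(1, 11))
        e, _ = restraint_energy(helix10, RestraintSet(helix_restraints=[hr]))
        assert e < 0.1

    def test_helix_restraint_violated_on_strand(self, helix10):
        _set_backbone(helix10, "H", STRAND_PHI, STRAND_PSI)
        helix10.rebuild(force=True)
        hr = make_helix_restraints(helix10, "H", range(1, 11))
        e, _ = restraint_energy(helix10,
                                RestraintSet(helix_restraints=[hr]))
        assert e > 0.0

    def test_short_range_rejected(self, helix10):
        with pytest.raises(ValueError):
            make_helix_restraints(helix10, "H", range(1, 5))


class TestRestraintEnergy:
    def test_satisfied_set_zero(self, helix10):
        sel = [("H", i) for i in range(1, 11)]
        anchors = {k: helix10.cartesian[helix10.atom_index(*k, "CA")]
                   for k in sel}
        rs = RestraintSet(
            pins=make_pins_from_template(helix10, anchors, sel),
            helix_restraints=[make_helix_restraints(helix10, "H",
                                                    range(1, 11))])
        e, breakdown = restraint_energy(helix10, rs)
        assert e < 0.1
        assert len(breakdown) == 10 + 6

    def test_single_violated_pin_additivity(self, helix10):
        anchor = helix10.cartesian[helix10.atom_index("H", 3, "CA")].copy()
        anchor += [3.0, 0, 0]
        pin = PinRestraint(("H", 3, "CA"), anchor, 1.0, 10.0)
        e, _ = restraint_energy(helix10, RestraintSet(pins=[pin]))
        assert e == pytest.approx(pin_energy(3.0, 1.0, 10.0))

    def test_additivity_oracle_random_system(self, helix10):
        rng = np.random.default_rng(11)
        pins, dists = [], []
        X = helix10.cartesian
        for i in range(1, 11):
            anchor = (X[helix10.atom_index("H", i, "CA")]
                      + rng.normal(scale=2.0, size=3))
            pins.append(PinRestraint(("H", i, "CA"), anchor, 1.0, 10.0))
        for _ in range(5):
            a, b = rng.choice(np.arange(1, 11), 2, replace=False)
            dists.append(DistanceRestraint(("H", int(a), "CA"),
                                           ("H", int(b), "CA"), 2.0, 4.0))
        rs = RestraintSet(pins=pins, distances=dists)
        total, breakdown = restraint_energy(helix10, rs)
        # independent per-restraint recomputation
        want = 0.0
        for p in pins:
            dev = np.linalg.norm(X[helix10.atom_index(*p.atom)] - p.anchor)
            want += pin_energy(float(dev), p.half_width_d, p.force_k)
        for d in dists:
            r = np.linalg.norm(X[helix10.atom_index(*d.atom_a)]
                               - X[helix10.atom_index(*d.atom_b)])
            if r < d.lower:
                want += d.force_k * (d.lower - r) ** 2
            elif r > d.upper:
                want += d.force_k * (r - d.upper) ** 2
        assert total == pytest.approx(want, abs=1e-10)
        assert total == pytest.approx(sum(e for _, e in breakdown))
        assert total >= 0.0

    def test_invalid_distance_bounds(self):
        with pytest.raises(ValueError):
            DistanceRestraint(("H", 1, "CA"), ("H", 2, "CA"), 5.0, 2.0)
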