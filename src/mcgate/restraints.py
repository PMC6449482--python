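"""Flat-bottom parabolic restraints.

All restraint types share the same functional form: zero penalty inside a
tolerance window, quadratic growth outside it, continuous at the boundary.
The catalogue mirrors the constraint machinery used to keep homology models
near their templates and to steer state transitions:

* **pins** tether C-alpha atoms to template positions (default half-width
  d = 1 A, force constant 10 kcal/mol/A^2);
* **distance restraints** are the same device applied to interatomic
  distances, with independent lower and upper bounds;
* **torsion windows** confine backbone torsions to +/- a few degrees around
  reference values;
* **helix H-bond restraints** hold O(i)-N(i+4) pairs near 3.0 A to preserve
  alpha-helical segments under large steering forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PinRestraint", "DistanceRestraint", "TorsionWindowRestraint",
           "HelixHBondRestraint", "RestraintSet", "pin_energy",
           "make_pins_from_template", "make_helix_restraints",
           "restraint_energy"]

DEFAULT_PIN_K = 10.0      # kcal mol^-1 A^-2
DEFAULT_PIN_D = 1.0       # Angstrom


def pin_energy(deviation: float, d: float = DEFAULT_PIN_D,
               k: float = DEFAULT_PIN_K) -> float:
    """Flat-bottom parabolic penalty: 0 for deviation <= d, else k (dev-d)^2."""
    if deviation < 0:
        raise ValueError("deviation must be non-negative")
    if deviation <= d:
        return 0.0
    return k * (deviation - d) ** 2


@dataclass
class PinRestraint:
    atom: tuple          # (seg_id, resnum, atom_name); C-alpha by convention
    anchor: np.ndarray   # template position, Angstrom
    half_width_d: float = DEFAULT_PIN_D
    force_k: float = DEFAULT_PIN_K

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.half_width_d < 0:
            raise ValueError("half_width_d must be >= 0")
        if self.force_k <= 0:
            raise ValueError("force_k must be > 0")


@dataclass
class DistanceRestraint:
    atom_a: tuple
    atom_b: tuple
    lower: float
    upper: float
    force_k: float = DEFAULT_PIN_K

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class TorsionWindowRestraint:
    torsion: tuple              # (seg_id, resnum, name)
    reference: float            # degrees
    half_width: float = 5.0     # degrees
    force_k: float = 0.1        # kcal mol^-1 deg^-2


@dataclass
class HelixHBondRestraint:
    pairs: list                 # [(O locator, N locator), ...] for (i, i+4)
    target: float = 3.0         # Angstrom
    half_width: float = 0.3
    force_k: float = DEFAULT_PIN_K


@dataclass
class RestraintSet:
    pins: list = field(default_factory=list)
    distances: list = field(default_factory=list)
    torsion_windows: list = field(default_factory=list)
    helix_restraints: list = field(default_factory=list)

    def __iter__(self):
        yield from self.pins
        yield from self.distances
        yield from self.torsion_windows
        yield from self.helix_restraints

    def merged_with(self, other: "RestraintSet") -> "RestraintSet":
        return RestraintSet(self.pins + other.pins,
                            self.distances + other.distances,
                            self.torsion_windows + other.torsion_windows,
                            self.helix_restraints + other.helix_restraints)


def make_pins_from_template(system, template_coords, selection,
                            d: float = DEFAULT_PIN_D,
                            k: float = DEFAULT_PIN_K) -> list[PinRestraint]:
    """One pin per selected C-alpha, anchored at the template position.

    ``template_coords`` maps (seg_id, resnum) -> 3-vector (or supports the
    same via a callable); residues listed in ``system.unpin_calphas`` (e.g.
    vicinal-disulfide cysteines) are skipped.
    """
    pins = []
    orphans = []
    lookup = (template_coords if callable(template_coords)
              else template_coords.get)
    for key in selection:
        if tuple(key) in system.unpin_calphas:
            continue
        anchor = lookup(tuple(key))
        if anchor is None:
            orphans.append(tuple(key))
            continue
        pins.append(PinRestraint((key[0], key[1], "CA"), anchor, d, k))
    if orphans:
        raise ValueError(f"no template correspondence for C-alpha of: "
                         f"{orphans}")
    return pins


def make_helix_restraints(system, seg_id: str, resnums,
                          target: float = 3.0, half_width: float = 0.3,
                          force_k: float = DEFAULT_PIN_K
                          ) -> HelixHBondRestraint:
    """O(i)-N(i+4) restraints covering a helical residue range."""
    resnums = sorted(resnums)
    if len(resnums) < 5:
        raise ValueError("helical range must contain at least 5 residues")
    pairs = []
    for a, b in zip(resnums, resnums[4:]):
        system.atom_index(seg_id, a, "O")
        system.atom_index(seg_id, b, "N")
        pairs.append(((seg_id, a, "O"), (seg_id, b, "N")))
    return HelixHBondRestraint(pairs, target, half_width, force_k)


def _flat_bottom(x, lo, hi, k):
    if x < lo:
        return k * (lo - x) ** 2, -2 * k * (lo - x)
    if x > hi:
        return k * (x - hi) ** 2, 2 * k * (x - hi)
    return 0.0, 0.0


def restraint_energy(system, restraint_set: RestraintSet,
                     with_gradient: bool = False):
    """Total restraint energy, per-restraint breakdown, and (optionally)
    Cartesian / torsion gradients.

    Returns ``(total, breakdown)`` or ``(total, breakdown, grad_xyz,
    grad_torsion)`` where ``grad_torsion`` maps torsion-variable index to
    dE/dtheta (radians).
    """
    system.rebuild()
    X = system.cartesian
    total = 0.0
    breakdown = []
    grad = np.zeros_like(X) if with_gradient else None
    tgrad: dict[int, float] = {}

    def dist_term(ia, ib, lo, hi, k, label):
        nonlocal total
        dvec = X[ia] - X[ib]
        r = float(np.linalg.norm(dvec))
        e, de = _flat_bottom(r, lo, hi, k)
        total += e
        breakdown.append((label, e))
        if with_gradient and de != 0.0 and r > 0:
            g = (de / r) * dvec
            grad[ia] += g
            grad[ib] -= g

    for pin in restraint_set.pins:
        ia = system.atom_index(*pin.atom)
        dvec = X[ia] - pin.anchor
        r = float(np.linalg.norm(dvec))
        e, de = _flat_bottom(r, 0.0, pin.half_width_d, pin.force_k)
        total += e
        breakdown.append((("pin",) + tuple(pin.atom), e))
        if with_gradient and de != 0.0 and r > 0:
            grad[ia] += (de / r) * dvec

    for dr in restraint_set.distances:
        ia = system.atom_index(*dr.atom_a)
        ib = system.atom_index(*dr.atom_b)
        dist_term(ia, ib, dr.lower, dr.upper, dr.force_k,
                  ("dist",) + tuple(dr.atom_a) + tuple(dr.atom_b))

    for tw in restraint_set.torsion_windows:
        vi = system.var_index(*tw.torsion)
        val = np.degrees(system.torsion_values[vi])
        dev = (val - tw.reference + 180.0) % 360.0 - 180.0
        e, de = _flat_bottom(dev, -tw.half_width, tw.half_width, tw.force_k)
        total += e
        breakdown.append((("torsion",) + tuple(tw.torsion), e))
        if with_gradient and de != 0.0:
            # de is per degree; convert to per radian
            tgrad[vi] = tgrad.get(vi, 0.0) + de * 180.0 / np.pi

    for hr in restraint_set.helix_restraints:
        lo = hr.target - hr.half_width
        hi = hr.target + hr.half_width
        for (loc_o, loc_n) in hr.pairs:
            ia = system.atom_index(*loc_o)
            ib = system.atom_index(*loc_n)
            dist_term(ia, ib, lo, hi, hr.force_k,
                      ("helix",) + tuple(loc_o) + tuple(loc_n))

    if with_gradient:
        return total, breakdown, grad, tgrad
    return total, breakdown
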