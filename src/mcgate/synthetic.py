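"""Deterministic toy-channel generators and printed-table fixtures.

The toy channel is a pseudo-4-fold helix bundle that reproduces, at desk
scale, the architecture the pipeline is built for: four repeats each
contributing an outer (S5-like) and an inner, gate-forming (S6-like) helix
around a central pore axis; an amphipathic AID-like helix resting in a
groove of a beta-plate domain (two strand rails), hydrophobic face toward
the plate and polar face toward a short S0-like sensor helix carrying an
arginine; and an engineered arginine-glutamine pair standing in for the
sensor-AID hydrogen bond.  The generator emits the same topology in two
analytically constructed conformations -- open-like and closed-like gate
radii -- with a trivial atom correspondence, so homology threading, steered
transformation, double-shell mutant sampling and contact analysis are all
testable without downloads.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import matrix_to_euler
from .restraints import DistanceRestraint, RestraintSet
from .system import MolecularSystem, SegmentSpec, build_system

__all__ = ["ToyChannelSpec", "FixtureTable", "generate_toy_channel",
           "generate_mismatched_sequence", "table_fixture",
           "toy_linker_restraints"]

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 130.0


@dataclass(frozen=True)
class ToyChannelSpec:
    n_repeats: int = 4
    helix_len: int = 12             # S5/S6 length, residues
    open_radius: float = 6.0        # gate C-alpha ring radius, Angstrom
    closed_radius: float = 2.5
    aid_len: int = 12
    s5_radius: float = 16.0
    s6_top_radius: float = 9.0
    membrane_top: float = 17.5
    aid_z: float = -4.0
    plate_z: float = -9.0
    plate_halfwidth: float = 8.5
    iis0_z: float = 6.0
    s5_sequence: str = "AVAAAAAAAAAA"
    s6_sequence: str = "LAVFLAGAAGGG"      # glycines give the gate hinge
    # amphipathic: LEU face down toward the plate; E/Q/K face up; Q6 is the
    # H-bond acceptor for the sensor arginine
    aid_sequence: str = "LAELLQSLAKAL"
    iis0_sequence: str = "ALAARALA"        # R5 donates the engineered H-bond
    plate_sequence: str = "LSLSLSLS"
    seed: int = 0

    def __post_init__(self):
        if not (self.open_radius > self.closed_radius > 0):
            raise ValueError("require open_radius > closed_radius > 0")

    def gate_radius(self, state: str) -> float:
        if state == "open":
            return self.open_radius
        if state == "closed":
            return self.closed_radius
        raise ValueError(f"unknown state {state!r}")


@dataclass
class FixtureTable:
    table_id: str
    data: pd.DataFrame
    sum_row: pd.Series | None = None
    annotations: list = field(default_factory=list)


# --------------------------------------------------------------- placement
def _rot_between(u, v):
    """Proper rotation taking unit vector u to unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis for the half turn
        p = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-8:
            p = np.cross(u, [0.0, 1.0, 0.0])
        p /= np.linalg.norm(p)
        return _axis_rot(p, np.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_rot(axis, np.arctan2(s, c))


def _axis_rot(axis, angle):
    axis = np.asarray(axis, dtype=float)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + np.sin(angle) * k
            + (1 - np.cos(angle)) * (k @ k))


def _perp(vec, axis):
    return vec - np.dot(vec, axis) * axis


def place_segment(system: MolecularSystem, seg_id: str, point_a, point_b,
                  roll_atom=None, roll_dir=None, mode: str = "chord"):
    """Rigidly place a segment along the line ``point_a`` -> ``point_b``.

    In ``chord`` mode the first C-alpha sits exactly at ``point_a`` and the
    last C-alpha points toward (and, at canonical length, exactly reaches)
    ``point_b`` -- used where an endpoint must land on a target, e.g. the
    gate ring.  In ``axis`` mode the fitted helix axis itself runs through
    ``point_a``, so the residue cylinder is centred on the given line.
    An optional roll aligns the sidechain direction of ``roll_atom``
    (seg-local (resnum, atom)) with ``roll_dir`` perpendicular to the axis.
    """
    seg = system.segment(seg_id)
    si = seg.index
    system.rebuild()
    canon = system._canon[si]
    lo = seg.atom_slice.start
    first = system.residues[seg.residue_indices[0]].seq_number
    last = system.residues[seg.residue_indices[-1]].seq_number
    cas = np.array([canon[system.atom_index(
        seg_id, system.residues[ri].seq_number, "CA") - lo]
        for ri in seg.residue_indices])
    if mode == "axis":
        centroid = cas.mean(axis=0)
        _, _, vt = np.linalg.svd(cas - centroid)
        d = vt[0]
        if np.dot(d, cas[-1] - cas[0]) < 0:
            d = -d
        # project the terminal C-alphas onto the fitted axis
        ca0 = centroid + np.dot(cas[0] - centroid, d) * d
        ca1 = centroid + np.dot(cas[-1] - centroid, d) * d
    else:
        ca0 = canon[system.atom_index(seg_id, first, "CA") - lo]
        ca1 = canon[system.atom_index(seg_id, last, "CA") - lo]
    point_a = np.asarray(point_a, dtype=float)
    point_b = np.asarray(point_b, dtype=float)
    u = ca1 - ca0
    length = np.linalg.norm(u)
    u = u / length
    v = point_b - point_a
    v = v / np.linalg.norm(v)
    R = _rot_between(u, v)
    if roll_atom is not None and roll_dir is not None:
        resnum, atname = roll_atom
        w_local = canon[system.atom_index(seg_id, resnum, atname) - lo] - ca0
        w = _perp(R @ _perp(w_local, u), v)
        w_t = _perp(np.asarray(roll_dir, dtype=float), v)
        if np.linalg.norm(w) > 1e-8 and np.linalg.norm(w_t) > 1e-8:
            w /= np.linalg.norm(w)
            w_t /= np.linalg.norm(w_t)
            ang = np.arctan2(float(np.dot(np.cross(w, w_t), v)),
                             float(np.dot(w, w_t)))
            R = _axis_rot(v, ang) @ R
    t = point_a - R @ ca0
    system.root_orientations[si] = matrix_to_euler(R)
    system.root_positions[si] = t
    system.rebuild()


def _set_backbone(system, seg_id, phi, psi):
    seg = system.segment(seg_id)
    for ri in seg.residue_indices:
        res = system.residues[ri]
        for vi in res.backbone_var_indices:
            v = system.torsion_vars[vi]
            if v.name == "phi":
                system.torsion_values[vi] = np.radians(phi)
            elif v.name == "psi":
                system.torsion_values[vi] = np.radians(psi)
    system._canon_dirty[seg.index] = True


# --------------------------------------------------------------- generator
def generate_toy_channel(spec: ToyChannelSpec = ToyChannelSpec(),
                         state: str = "open") -> MolecularSystem:
    """Build the toy channel in the requested gate state.

    Open and closed systems share topology and atom ordering, so the atom
    correspondence between states is the identity.
    """
    gate_r = spec.gate_radius(state)   # validates state and radii
    n = spec.n_repeats
    specs = []
    for r in range(n):
        specs.append(SegmentSpec(
            f"S5.{r + 1}",
            tuple((_aa(spec.s5_sequence, i), i + 1)
                  for i in range(spec.helix_len)), group="alpha1"))
        specs.append(SegmentSpec(
            f"S6.{r + 1}",
            tuple((_aa(spec.s6_sequence, i), i + 1)
                  for i in range(spec.helix_len)), group="alpha1"))
    specs.append(SegmentSpec(
        "AID", tuple((_aa(spec.aid_sequence, i), i + 1)
                     for i in range(spec.aid_len)), group="alpha1"))
    specs.append(SegmentSpec(
        "IIS0", tuple((_aa(spec.iis0_sequence, i), i + 1)
                      for i in range(len(spec.iis0_sequence))),
        group="alpha1"))
    for b, ypos in (("beta1", spec.plate_halfwidth),
                    ("beta2", -spec.plate_halfwidth)):
        specs.append(SegmentSpec(
            b, tuple((_aa(spec.plate_sequence, i), i + 1)
                     for i in range(len(spec.plate_sequence))),
            group="beta_subunit"))
    system = build_system(specs)

    for r in range(n):
        _set_backbone(system, f"S5.{r + 1}", HELIX_PHI, HELIX_PSI)
        _set_backbone(system, f"S6.{r + 1}", HELIX_PHI, HELIX_PSI)
    _set_backbone(system, "AID", HELIX_PHI, HELIX_PSI)
    _set_backbone(system, "IIS0", HELIX_PHI, HELIX_PSI)
    _set_backbone(system, "beta1", STRAND_PHI, STRAND_PSI)
    _set_backbone(system, "beta2", STRAND_PHI, STRAND_PSI)
    system.rebuild(force=True)

    z_top = spec.membrane_top
    for r in range(n):
        phi_r = 2 * np.pi * r / n
        e_r = np.array([np.cos(phi_r), np.sin(phi_r), 0.0])
        e_t = np.array([-np.sin(phi_r), np.cos(phi_r), 0.0])
        # S5: vertical scaffold, state-independent, held high and wide so
        # the cytoplasmic belly stays free for AID/plate/sensor
        a = spec.s5_radius * e_r + np.array([0, 0, z_top + 12.5])
        place_segment(system, f"S5.{r + 1}", a, a + [0, 0, -18.0],
                      roll_atom=(6, "CB"), roll_dir=e_r, mode="axis")
        # S6: last C-alpha lands exactly on the gate ring, staggered
        # tangentially so the four inner helices cross side-by-side (bundle
        # crossing) instead of converging head-on.  The gate-ring height is
        # state-independent (the top pivot absorbs the tilt change), so the
        # gate motion between states is purely radial.
        stag = np.radians(25.0)
        e_g = np.array([np.cos(phi_r + stag), np.sin(phi_r + stag), 0.0])
        seg = system.segment(f"S6.{r + 1}")
        canon = system._canon[seg.index]
        lo = seg.atom_slice.start
        ca0 = canon[system.atom_index(f"S6.{r + 1}", 1, "CA") - lo]
        ca1 = canon[system.atom_index(f"S6.{r + 1}", spec.helix_len, "CA")
                    - lo]
        length = float(np.linalg.norm(ca1 - ca0))
        gate_xy = gate_r * e_g[:2]
        dxy_closed = float(np.linalg.norm(
            spec.closed_radius * e_g[:2] - spec.s6_top_radius * e_r[:2]))
        z_gate = z_top - np.sqrt(max(length ** 2 - dxy_closed ** 2, 1.0))
        dxy = float(np.linalg.norm(gate_xy - spec.s6_top_radius * e_r[:2]))
        top = spec.s6_top_radius * e_r + np.array(
            [0, 0, z_gate + np.sqrt(max(length ** 2 - dxy ** 2, 1.0))])
        target = np.array([gate_xy[0], gate_xy[1], z_gate])
        # bulky F4 points tangentially: clear of both the pore and S5
        place_segment(system, f"S6.{r + 1}", top, target,
                      roll_atom=(4, "CB"), roll_dir=e_r)

    # Cytoplasmic assembly axes: the AID axis is aligned with the staggered
    # repeat-1 gate direction, so the radial gate motion drags the AID along
    # its own helix axis (groove-guided sliding); "pvec" is the in-plane
    # normal along which the groove rails and the sensor helix run.
    stag = np.radians(25.0)
    dvec = np.array([np.cos(stag), np.sin(stag), 0.0])
    pvec = np.array([-np.sin(stag), np.cos(stag), 0.0])
    x0 = gate_r + 2.0
    aid_a = x0 * dvec + np.array([0, 0, spec.aid_z])
    place_segment(system, "AID", aid_a, aid_a + 18.0 * dvec,
                  roll_atom=(1, "CB"), roll_dir=[0, 0, -1.0], mode="axis")
    # sensor helix above the AID polar face, axis normal to the AID axis
    aid_mid = x0 + 8.0
    shift = 0.5 * (spec.open_radius - gate_r)   # follows half the AID shift
    s0_a = ((aid_mid - shift + 4.5) * dvec - 5.5 * pvec
            + np.array([0, 0, spec.iis0_z]))
    place_segment(system, "IIS0", s0_a, s0_a + 13.0 * pvec,
                  roll_atom=(5, "CB"), roll_dir=[0, 0, -1.0], mode="axis")
    # beta-plate groove rails, state-independent
    for b, ypos in (("beta1", spec.plate_halfwidth),
                    ("beta2", -spec.plate_halfwidth)):
        a = ((spec.closed_radius + 1.0) * dvec + ypos * pvec
             + np.array([0, 0, spec.plate_z]))
        place_segment(system, b, a, a + 24.0 * dvec,
                      roll_atom=(1, "CB"), roll_dir=[0, 0, 1.0], mode="axis")
    # sensor arginine reaches sideways-down so its guanidinium hovers next
    # to the AID glutamine without penetrating the AID helix
    for chi, deg in (("chi1", 60.0), ("chi2", 60.0), ("chi3", 180.0),
                     ("chi4", 180.0)):
        vi = system.var_index("IIS0", 5, chi)
        system.torsion_values[vi] = np.radians(deg)
    system.mark_dirty([vi])
    # groove leucines fold toward gauche- so the analytic template packs
    # without hard overlap against the sliding AID
    for seg_id in ("beta1", "beta2"):
        for ri in system.segment(seg_id).residue_indices:
            res = system.residues[ri]
            if res.name == "LEU":
                system.torsion_values[res.chi_var_indices[0]] = \
                    np.radians(-60.0)
            elif res.name == "SER":
                system.torsion_values[res.chi_var_indices[0]] = \
                    np.radians(-60.0)
    for num, chi_degs in ((spec.aid_len, (-60.0,)), (10, (180.0, 60.0)),
                          (5, (-60.0,))):
        if 1 <= num <= spec.aid_len:
            res = system.residue("AID", num)
            for vi, deg in zip(res.chi_var_indices, chi_degs):
                system.torsion_values[vi] = np.radians(deg)
    system._canon_dirty = [True] * len(system.segments)
    system.rebuild()
    return system


def _aa(sequence: str, i: int):
    one_to_three = {"A": "ALA", "L": "LEU", "V": "VAL", "F": "PHE",
                    "G": "GLY", "S": "SER", "E": "GLU", "Q": "GLN",
                    "K": "LYS", "R": "ARG", "D": "ASP", "N": "ASN",
                    "I": "ILE", "T": "THR", "C": "CYS", "M": "MET",
                    "P": "PRO", "W": "TRP", "Y": "TYR", "H": "HIS"}
    return one_to_three[sequence[i % len(sequence)]]


def toy_linker_restraints(spec: ToyChannelSpec = ToyChannelSpec()
                          ) -> RestraintSet:
    """The covalent-linker stand-in tying the AID N-terminus to the C-end of
    the repeat-1 inner helix (flat-bottom window up to 5.5 A, the span of
    the two-residue linker the toy does not model explicitly), plus the
    sensor-body tether standing in for the covalent continuation of the
    S0-like helix into the membrane-embedded sensor (a two-sided distance
    band to the outer scaffold: the sensor helix can pivot and slide but
    not float away)."""
    return RestraintSet(distances=[
        DistanceRestraint(("S6.1", spec.helix_len, "C"), ("AID", 1, "N"),
                          0.0, 6.8, 10.0),
        DistanceRestraint(("IIS0", len(spec.iis0_sequence), "CA"),
                          ("S5.1", spec.helix_len, "CA"),
                          13.0, 15.5, 10.0)])


# ------------------------------------------------- threading test material
def generate_mismatched_sequence(spec: ToyChannelSpec, n_substitutions: int,
                                 seed: int = 0):
    """Template system plus a model sequence with flagged mismatches.

    Returns ``(template_system, model_segment_specs, template_map)`` where
    the map aligns model residues to template residues one-to-one and flags
    exactly ``n_substitutions`` mismatched positions.
    """
    from .pipeline import TemplateMap

    template = generate_toy_channel(spec, "open")
    all_sites = [(seg.id, template.residues[ri].seq_number)
                 for seg in template.segments
                 for ri in seg.residue_indices]
    if n_substitutions > len(all_sites):
        raise ValueError("more substitutions than residues")
    rng = np.random.default_rng(seed)
    subs_idx = rng.choice(len(all_sites), size=n_substitutions,
                          replace=False)
    subs = {all_sites[int(k)] for k in subs_idx}
    swap = {"ALA": "SER", "LEU": "VAL", "VAL": "LEU", "PHE": "LEU",
            "GLY": "ALA", "SER": "THR", "GLU": "GLN", "GLN": "GLU",
            "LYS": "ARG", "ARG": "LYS", "THR": "SER", "ILE": "VAL"}
    model_specs = []
    pairs = []
    for tspec in template.segment_specs:
        res = []
        for (nm, num, var) in tspec.normalized():
            new = swap.get(nm, "ALA") if (tspec.id, num) in subs else nm
            res.append((new, num, var))
            pairs.append(((tspec.id, num), (tspec.id, num), new == nm))
        model_specs.append(SegmentSpec(tspec.id, tuple(res), tspec.group))
    return template, model_specs, TemplateMap(pairs)


# ------------------------------------------------------------ table fixtures
def table_fixture(table_id: str) -> FixtureTable:
    """Machine-readable transcription of a printed contact-energy table.

    ``table_id`` is one of ``table2``, ``table3``, ``table4``.  Values are
    verbatim, including signs and blanks; annotation lines (``#``) record
    printed inconsistencies.  For ``table4`` the printed SUM row is stored
    separately from the row data.
    """
    if table_id not in ("table2", "table3", "table4"):
        raise KeyError(f"unknown fixture table {table_id!r}")
    ref = importlib.resources.files("mcgate") / "data" / f"{table_id}.tsv"
    with ref.open() as fh:
        raw = fh.read().splitlines()
    annotations = [ln.lstrip("# ").rstrip() for ln in raw
                   if ln.startswith("#")]
    rows = [ln for ln in raw if ln and not ln.startswith("#")]
    header = rows[0].split("\t")
    recs = []
    for ln in rows[1:]:
        fields = ln.split("\t")
        fields += [""] * (len(header) - len(fields))
        recs.append(fields[:len(header)])
    df = pd.DataFrame(recs, columns=header)
    for col in header:
        if col in ("residue", "number", "label"):
            continue
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    if "number" in df.columns:
        df["number"] = df["number"].astype(str)
    sum_row = None
    if (df["residue"] == "SUM").any():
        sum_row = df[df["residue"] == "SUM"].iloc[0]
        df = df[df["residue"] != "SUM"].reset_index(drop=True)
    return FixtureTable(table_id, df, sum_row, annotations)
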