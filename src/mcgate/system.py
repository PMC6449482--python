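"""Molecular data model in internal (generalized) coordinates.

A :class:`MolecularSystem` is a set of covalently contiguous *segments*, each
an atom tree rooted at the N-terminal nitrogen of its first residue.  The
generalized coordinates are torsion angles (backbone phi/psi/omega and
sidechain chi), the Cartesian position of each free segment's root atom and
the Euler-angle orientation of its first three-atom frame.  Bond lengths and
bond angles are rigid except where a residue is flagged with flexible bond
angles (prolines; vicinal-disulfide cysteines).

Cartesian coordinates are a pure function of the generalized coordinates and
the topology: each segment is built once in a canonical frame by sequential
atom placement and then mapped by the rigid root transform, so rebuilding
with unchanged coordinates is bit-stable and root translations are exact
rigid motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (bond_angle, dihedral, euler_to_matrix, place_atom,
                       wrap_angle)
from .topology import TopologyLibrary, default_topology

__all__ = ["SegmentSpec", "Segment", "Residue", "TorsionVar",
           "MolecularSystem", "build_system"]

_D2R = np.pi / 180.0


@dataclass(frozen=True)
class SegmentSpec:
    """Definition of one covalent segment: (name, number, variant) triples."""

    id: str
    residues: tuple          # sequence of (resname, resnum) or (resname, resnum, variant)
    group: str = "other"     # {"alpha1", "beta_subunit", "other"}

    def normalized(self):
        out = []
        for item in self.residues:
            if len(item) == 2:
                out.append((item[0], int(item[1]), "default"))
            else:
                out.append((item[0], int(item[1]), item[2]))
        return tuple(out)


@dataclass
class Segment:
    id: str
    group: str
    index: int
    residue_indices: list[int]
    atom_slice: slice = field(default_factory=lambda: slice(0, 0))


@dataclass
class Residue:
    name: str
    seq_number: int
    variant: str
    segment_index: int
    atom_indices: list[int] = field(default_factory=list)
    chi_var_indices: list[int] = field(default_factory=list)
    backbone_var_indices: list[int] = field(default_factory=list)
    flexible_bond_angles: bool = False

    @property
    def key(self):
        return (self.segment_index, self.seq_number)


@dataclass
class TorsionVar:
    id: str            # "SEG/RESNUM/NAME"
    name: str          # phi, psi, omega, chi1...
    kind: str          # "bb" | "chi"
    seg_index: int
    res_index: int
    axis: tuple[int, int] | None = None   # (a2, a3) global atom indices


@dataclass
class _Entry:
    atom: int
    refs: tuple[int, int, int] | None
    bond: float
    angle: float               # radians
    angle_var: int | None
    tors_kind: str             # "fixed" | "var"
    tors_value: float          # radians: fixed value, or offset for vars
    tors_var: int | None
    special: str | None = None  # "N0" | "CA0" | "C0"


class MolecularSystem:
    """Atoms, residues and segments with forward kinematics."""

    def __init__(self, segment_specs, topology: TopologyLibrary | None = None,
                 disulfides=()):
        self.topology = topology or default_topology()
        self.segment_specs = tuple(segment_specs)
        self.disulfides = tuple(sorted(tuple(sorted(d)) for d in disulfides))
        self._construct()

    # ------------------------------------------------------------------ build
    def _construct(self):
        top = self.topology
        self.segments: list[Segment] = []
        self.residues: list[Residue] = []
        self.torsion_vars: list[TorsionVar] = []
        self.angle_var_entries: list[int] = []   # entry indices with var angles
        self.entries: list[_Entry] = []
        names, elements, charges, formal, ionized = [], [], [], [], []
        eps, rmin = [], []
        atom_res = []
        bonds: list[tuple[int, int]] = []
        self._atom_lookup: dict[tuple[str, int, str], int] = {}

        var_index: dict[str, int] = {}

        def get_var(seg_id, si, ri, resnum, name, kind, axis=None):
            vid = f"{seg_id}/{resnum}/{name}"
            if vid not in var_index:
                var_index[vid] = len(self.torsion_vars)
                self.torsion_vars.append(
                    TorsionVar(vid, name, kind, si, ri, axis))
            idx = var_index[vid]
            if axis is not None and self.torsion_vars[idx].axis is None:
                self.torsion_vars[idx].axis = axis
            return idx

        n_atoms = 0
        for si, spec in enumerate(self.segment_specs):
            residues = spec.normalized()
            if not residues:
                raise ValueError(f"segment {spec.id!r} is empty")
            seg = Segment(spec.id, spec.group, si, [])
            self.segments.append(seg)
            seg_start = n_atoms
            prev: dict[str, int] | None = None
            for local_i, (resname, resnum, variant) in enumerate(residues):
                if resname not in top and f"{resname}" not in top.residues:
                    raise ValueError(
                        f"unknown residue {resname!r} at {spec.id}:{resnum}")
                tmpl = top.get(resname, variant)
                ri = len(self.residues)
                res = Residue(resname, resnum, variant, si)
                res.flexible_bond_angles = (
                    resname == "PRO" or variant == "disulfide")
                self.residues.append(res)
                seg.residue_indices.append(ri)
                local: dict[str, int] = {}
                for at in tmpl.atoms:
                    ai = n_atoms
                    n_atoms += 1
                    local[at.name] = ai
                    res.atom_indices.append(ai)
                    names.append(at.name)
                    elements.append(at.element)
                    charges.append(at.charge)
                    formal.append(at.formal_charge)
                    ionized.append(at.ionized)
                    eps.append(at.lj_epsilon)
                    rmin.append(at.lj_rmin_half)
                    atom_res.append(ri)
                    self._atom_lookup[(spec.id, resnum, at.name)] = ai

                    entry = self._make_entry(
                        at, ai, local, prev, local_i, si, ri, resnum,
                        spec.id, get_var, res)
                    self.entries.append(entry)
                    if entry.refs is not None:
                        bonds.append((entry.refs[2], ai))
                    elif entry.special == "CA0":
                        bonds.append((local["N"], ai))  # chain-root N-CA
                # ring closure bonds and peptide bond
                for a, b in tmpl.ring_bonds:
                    bonds.append((local[a], local[b]))
                if prev is not None:
                    bonds.append((prev["C"], local["N"]))
                prev = local
            seg.atom_slice = slice(seg_start, n_atoms)

        # disulfide bonds (by (segment_id, resnum) pairs)
        for (ka, kb) in self.disulfides:
            sa = self._atom_lookup.get((ka[0], ka[1], "SG"))
            sb = self._atom_lookup.get((kb[0], kb[1], "SG"))
            if sa is None or sb is None:
                raise ValueError(f"disulfide partners {ka}/{kb} lack SG atoms")
            bonds.append((sa, sb))

        self.atom_names = np.array(names)
        self.atom_elements = np.array(elements)
        self.charges = np.array(charges)
        self.formal_charges = np.array(formal, dtype=int)
        self.ionized_mask = np.array(ionized, dtype=bool)
        self.lj_epsilon = np.array(eps)
        self.lj_rmin_half = np.array(rmin)
        self.atom_residue = np.array(atom_res, dtype=int)
        self.heavy_mask = self.atom_elements != "H"
        self.n_atoms = n_atoms
        self.bonds = bonds

        # coordinate state
        self.torsion_values = np.full(len(self.torsion_vars), np.pi)
        for v in self.torsion_vars:
            if v.name == "omega":
                self.torsion_values[var_index[v.id]] = np.pi
        self.angle_values = np.array(
            [self.entries[e].angle for e in self.angle_var_entries])
        self.root_positions = np.zeros((len(self.segments), 3))
        self.root_orientations = np.zeros((len(self.segments), 3))

        # flexibility masks (defaults: all torsions flexible, roots flexible)
        self.torsion_flexible = np.ones(len(self.torsion_vars), dtype=bool)
        self.angle_flexible = np.zeros(len(self.angle_var_entries), dtype=bool)
        for i, ei in enumerate(self.angle_var_entries):
            ri = self.atom_residue[self.entries[ei].atom]
            self.angle_flexible[i] = self.residues[ri].flexible_bond_angles
        self.root_flexible = np.ones(len(self.segments), dtype=bool)

        self._compute_dependencies()
        self._exclusions_cache = None
        self.unpin_calphas: set[tuple[str, int]] = set()

        self._canon = [None] * len(self.segments)
        self._canon_dirty = [True] * len(self.segments)
        self.cartesian = np.zeros((self.n_atoms, 3))
        self.rebuild()

    def _make_entry(self, at, ai, local, prev, local_i, si, ri, resnum,
                    seg_id, get_var, res):
        def resolve(nm):
            if nm.startswith("-"):
                return prev[nm[1:]] if prev is not None else None
            return local[nm]

        angle_var = None
        angle_rad = at.angle * _D2R
        entry_index = len(self.entries)

        # first residue of a segment: N/CA/C are placed canonically
        if prev is None and at.name in ("N", "CA", "C"):
            if at.name == "N":
                return _Entry(ai, None, 0, 0, None, "fixed", 0, None, "N0")
            if at.name == "CA":
                return _Entry(ai, None, 0, 0, None, "fixed", 0, None, "CA0")
            # C: virtual reference, torsion = phi
            vi = get_var(seg_id, si, ri, resnum, "phi", "bb",
                         axis=(local["N"], local["CA"]))
            res.backbone_var_indices.append(vi)
            e = _Entry(ai, (local["N"], local["N"], local["CA"]),
                       at.bond, angle_rad, None, "var", 0.0, vi, "C0")
            self._maybe_flex_angle(e, entry_index, res)
            return e

        if prev is None and at.refs is not None and any(
                r.startswith("-") for r in at.refs):
            # terminal amide H: fall back to an intra-residue reference
            if at.name == "H":
                e = _Entry(ai, (local["C"], local["CA"], local["N"]),
                           at.bond, angle_rad, None, "fixed", np.pi, None)
                return e
            raise ValueError(
                f"atom {at.name} of first residue needs previous residue")

        refs = tuple(resolve(r) for r in at.refs)
        kind, *rest = at.tors
        if kind == "f":
            e = _Entry(ai, refs, at.bond, angle_rad, None,
                       "fixed", rest[0] * _D2R, None)
        else:
            varname, offset = rest
            target_res = ri
            target_num = resnum
            if varname.endswith("-"):
                varname = varname[:-1]
                target_res = ri - 1
                target_num = self.residues[ri - 1].seq_number
            vkind = "bb" if varname in ("phi", "psi", "omega") else "chi"
            vi = get_var(seg_id, si, target_res, target_num, varname, vkind,
                         axis=(refs[1], refs[2]))
            tres = self.residues[target_res]
            if vkind == "bb":
                if vi not in tres.backbone_var_indices:
                    tres.backbone_var_indices.append(vi)
            else:
                if vi not in tres.chi_var_indices:
                    tres.chi_var_indices.append(vi)
            e = _Entry(ai, refs, at.bond, angle_rad, None,
                       "var", offset * _D2R, vi)
        self._maybe_flex_angle(e, entry_index, res)
        return e

    def _maybe_flex_angle(self, entry, entry_index, res):
        # residues with flexible bond angles get variable angles on heavy atoms
        if res.flexible_bond_angles and entry.refs is not None:
            elem = None  # promoted for all non-hydrogen placements
            name = None
            entry.angle_var = len(self.angle_var_entries)
            self.angle_var_entries.append(entry_index)

    # ----------------------------------------------------------- dependencies
    def _compute_dependencies(self):
        nv = len(self.torsion_vars)
        na = len(self.angle_var_entries)
        deps_t = [set() for _ in range(self.n_atoms)]
        deps_a = [set() for _ in range(self.n_atoms)]
        for e in self.entries:
            a = e.atom
            if e.refs is not None:
                for r in e.refs:
                    deps_t[a] |= deps_t[r]
                    deps_a[a] |= deps_a[r]
            if e.tors_var is not None:
                deps_t[a].add(e.tors_var)
            if e.angle_var is not None:
                deps_a[a].add(e.angle_var)
        self.torsion_downstream = [[] for _ in range(nv)]
        for a in range(self.n_atoms):
            for v in deps_t[a]:
                self.torsion_downstream[v].append(a)
        self.torsion_downstream = [np.array(x, dtype=int)
                                   for x in self.torsion_downstream]
        self.angle_downstream = [[] for _ in range(na)]
        for a in range(self.n_atoms):
            for v in deps_a[a]:
                self.angle_downstream[v].append(a)
        self.angle_downstream = [np.array(x, dtype=int)
                                 for x in self.angle_downstream]

    # ------------------------------------------------------------- kinematics
    def rebuild(self, force=False):
        """Recompute Cartesian coordinates from generalized coordinates."""
        for si, seg in enumerate(self.segments):
            if force or self._canon_dirty[si] or self._canon[si] is None:
                self._canon[si] = self._build_canonical(seg)
                self._canon_dirty[si] = False
            R = euler_to_matrix(self.root_orientations[si])
            t = self.root_positions[si]
            self.cartesian[seg.atom_slice] = self._canon[si] @ R.T + t
        return self.cartesian

    def _build_canonical(self, seg: Segment):
        lo = seg.atom_slice.start
        n = seg.atom_slice.stop - lo
        X = np.zeros((n, 3))
        for e in self.entries[lo:seg.atom_slice.stop]:
            a = e.atom - lo
            if e.special == "N0":
                X[a] = 0.0
                continue
            if e.special == "CA0":
                X[a] = (1.458, 0.0, 0.0)
                continue
            angle = (self.angle_values[e.angle_var]
                     if e.angle_var is not None else e.angle)
            if e.tors_kind == "fixed":
                tors = e.tors_value
            else:
                tors = self.torsion_values[e.tors_var] + e.tors_value
            if e.special == "C0":
                a1 = X[e.refs[0] - lo] + np.array([0.0, 1.0, 0.0])
                a2, a3 = X[e.refs[1] - lo], X[e.refs[2] - lo]
            else:
                a1, a2, a3 = (X[r - lo] for r in e.refs)
            X[a] = place_atom(a1, a2, a3, e.bond, angle, tors)
        return X

    def mark_dirty(self, torsion_indices=None, angle_indices=None):
        segs = set()
        if torsion_indices is not None:
            for i in np.atleast_1d(torsion_indices):
                segs.add(self.torsion_vars[int(i)].seg_index)
        if angle_indices is not None:
            for i in np.atleast_1d(angle_indices):
                e = self.entries[self.angle_var_entries[int(i)]]
                segs.add(self.residues[self.atom_residue[e.atom]].segment_index)
        for s in segs:
            self._canon_dirty[s] = True

    # ---------------------------------------------------------- coord vector
    def coordinate_layout(self):
        """Flexible coordinate vector layout.

        Returns (torsion_idx, angle_idx, root_idx) arrays; the packed vector
        is [torsions (rad), angles (rad), per-root position xyz + euler zyx].
        """
        t_idx = np.flatnonzero(self.torsion_flexible)
        a_idx = np.flatnonzero(self.angle_flexible)
        r_idx = np.flatnonzero(self.root_flexible)
        return t_idx, a_idx, r_idx

    @property
    def n_flexible(self):
        t, a, r = self.coordinate_layout()
        return len(t) + len(a) + 6 * len(r)

    def get_vector(self):
        t, a, r = self.coordinate_layout()
        parts = [self.torsion_values[t], self.angle_values[a]]
        for si in r:
            parts.append(self.root_positions[si])
            parts.append(self.root_orientations[si])
        return np.concatenate(parts) if parts else np.zeros(0)

    def set_vector(self, x):
        t, a, r = self.coordinate_layout()
        x = np.asarray(x, dtype=float)
        nt, na = len(t), len(a)
        if len(x) != nt + na + 6 * len(r):
            raise ValueError("coordinate vector has wrong length")
        if nt:
            new_t = wrap_angle(x[:nt])
            changed = new_t != self.torsion_values[t]
            if changed.any():
                self.torsion_values[t] = new_t
                self.mark_dirty(torsion_indices=t[changed])
        if na:
            new_a = x[nt:nt + na]
            changed = new_a != self.angle_values[a]
            if changed.any():
                self.angle_values[a] = new_a
                self.mark_dirty(angle_indices=a[changed])
        off = nt + na
        for si in r:
            self.root_positions[si] = x[off:off + 3]
            self.root_orientations[si] = x[off + 3:off + 6]
            off += 6
        self.rebuild()

    def coordinate_classes(self):
        """Per-vector-slot class labels: 'torsion' | 'angle' | 'root_pos' | 'root_euler'."""
        t, a, r = self.coordinate_layout()
        labels = ["torsion"] * len(t) + ["angle"] * len(a)
        for _ in r:
            labels += ["root_pos"] * 3 + ["root_euler"] * 3
        return labels

    # --------------------------------------------------------------- lookups
    def segment(self, seg_id: str) -> Segment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(f"no segment {seg_id!r}")

    def residue(self, seg_id: str, resnum: int) -> Residue:
        seg = self.segment(seg_id)
        for ri in seg.residue_indices:
            if self.residues[ri].seq_number == resnum:
                return self.residues[ri]
        raise KeyError(f"no residue {resnum} in segment {seg_id!r}")

    def atom_index(self, seg_id: str, resnum: int, atom_name: str) -> int:
        try:
            return self._atom_lookup[(seg_id, resnum, atom_name)]
        except KeyError:
            raise KeyError(
                f"no atom {atom_name!r} in {seg_id}:{resnum}") from None

    def var_index(self, seg_id: str, resnum: int, name: str) -> int:
        vid = f"{seg_id}/{resnum}/{name}"
        for i, v in enumerate(self.torsion_vars):
            if v.id == vid:
                return i
        raise KeyError(f"no torsion variable {vid!r}")

    def calpha_indices(self, selection=None):
        """Global indices of CA atoms; `selection` is (seg_id, resnum) pairs."""
        if selection is None:
            return np.flatnonzero(self.atom_names == "CA")
        return np.array([self.atom_index(s, r, "CA") for s, r in selection])

    # ------------------------------------------------------------ exclusions
    def bonded_separations(self, max_sep=3):
        """Pairs of atoms within `max_sep` bonds: dict (i, j) -> separation."""
        if self._exclusions_cache is not None:
            return self._exclusions_cache
        adj = [[] for _ in range(self.n_atoms)]
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        out = {}
        for start in range(self.n_atoms):
            dist = {start: 0}
            frontier = [start]
            for d in range(1, max_sep + 1):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = d
                            nxt.append(v)
                frontier = nxt
            for v, d in dist.items():
                if v > start:
                    key = (start, v)
                    out[key] = min(out.get(key, 99), d)
        self._exclusions_cache = out
        return out

    # ------------------------------------------------------------ operations
    def set_all_trans(self, residue_set):
        """Set all sidechain torsions of the given (seg_id, resnum) residues
        to 180 degrees."""
        for seg_id, resnum in residue_set:
            res = self.residue(seg_id, resnum)   # raises if absent
            for vi in res.chi_var_indices:
                self.torsion_values[vi] = np.pi
                self._canon_dirty[res.segment_index] = True
        self.rebuild()
        return self

    def measure_torsion(self, var_index: int) -> float:
        """Dihedral value (radians) of a torsion variable measured from the
        current Cartesian coordinates."""
        v = self.torsion_vars[var_index]
        for e in self.entries:
            if e.tors_var == var_index and e.special != "C0":
                p = [self.cartesian[r] for r in e.refs]
                return wrap_angle(
                    dihedral(p[0], p[1], p[2], self.cartesian[e.atom])
                    - e.tors_value)
        return float(self.torsion_values[var_index])

    def clone(self) -> "MolecularSystem":
        other = MolecularSystem(self.segment_specs, self.topology,
                                self.disulfides)
        other.copy_state_from(self)
        return other

    def copy_state_from(self, other: "MolecularSystem"):
        self.torsion_values[:] = other.torsion_values
        self.angle_values[:] = other.angle_values
        self.root_positions[:] = other.root_positions
        self.root_orientations[:] = other.root_orientations
        self.torsion_flexible[:] = other.torsion_flexible
        self.angle_flexible[:] = other.angle_flexible
        self.root_flexible[:] = other.root_flexible
        self._canon_dirty = [True] * len(self.segments)
        self.rebuild()
        return self


def build_system(segment_specs, topology: TopologyLibrary | None = None,
                 disulfides=()) -> MolecularSystem:
    """Construct a :class:`MolecularSystem` from segment definitions.

    Parameters
    ----------
    segment_specs : iterable of SegmentSpec
        Sequence + segment definitions; residue names must exist in the
        topology library.
    disulfides : iterable of ((seg_id, resnum), (seg_id, resnum))
        S-S bonded cysteine pairs (both must use the ``disulfide`` variant).
    """
    specs = list(segment_specs)
    if not specs:
        raise ValueError("no segments given")
    return MolecularSystem(specs, topology, disulfides)


def apply_mutation(system: MolecularSystem, site, new_residue: str,
                   variant: str = "default", disulfide_partner=None
                   ) -> MolecularSystem:
    """Return a new system with `site` (seg_id, resnum) mutated.

    Backbone geometry (phi/psi/omega and roots) is preserved; the new
    sidechain starts all-trans.  When `disulfide_partner` is given both
    residues become disulfide-variant cysteines, an S-S bond is created,
    both gain flexible bond angles and their alpha carbons are recorded in
    ``unpin_calphas`` (template pins on them must be dropped).
    """
    seg_id, resnum = site
    system.residue(seg_id, resnum)  # raises if absent
    mutated_sites = [(site, new_residue, variant)]
    disulfides = list(system.disulfides)
    if disulfide_partner is not None:
        if new_residue != "CYS":
            raise ValueError("disulfide_partner is only valid for CYS")
        pseg, pres = disulfide_partner
        system.residue(pseg, pres)
        # geometric feasibility: CB-CB distance must allow an S-S bond
        try:
            ca = system.cartesian[system.atom_index(seg_id, resnum, "CB")]
            cb = system.cartesian[system.atom_index(pseg, pres, "CB")]
            d = float(np.linalg.norm(ca - cb))
        except KeyError:
            ca = system.cartesian[system.atom_index(seg_id, resnum, "CA")]
            cb = system.cartesian[system.atom_index(pseg, pres, "CA")]
            d = float(np.linalg.norm(ca - cb))
        if d > 7.0:
            raise ValueError(
                f"disulfide between {site} and {disulfide_partner} is "
                f"geometrically unreachable (C-beta distance {d:.2f} A)")
        mutated_sites = [(site, "CYS", "disulfide"),
                         (disulfide_partner, "CYS", "disulfide")]
        disulfides.append(((seg_id, resnum), (pseg, pres)))

    site_map = {s[0]: (s[1], s[2]) for s in mutated_sites}
    new_specs = []
    for spec in system.segment_specs:
        res = []
        for (nm, num, var) in spec.normalized():
            if (spec.id, num) in site_map:
                nm, var = site_map[(spec.id, num)]
            res.append((nm, num, var))
        new_specs.append(SegmentSpec(spec.id, tuple(res), spec.group))

    out = MolecularSystem(new_specs, system.topology, disulfides)
    # copy coordinate state by variable id
    old_ids = {v.id: i for i, v in enumerate(system.torsion_vars)}
    for i, v in enumerate(out.torsion_vars):
        j = old_ids.get(v.id)
        if j is not None:
            out.torsion_values[i] = system.torsion_values[j]
    out.root_positions[:] = system.root_positions
    out.root_orientations[:] = system.root_orientations
    out.torsion_flexible[:] = True
    out.unpin_calphas = set(system.unpin_calphas)
    for (s, nm, var) in mutated_sites:
        if var == "disulfide":
            out.unpin_calphas.add(s)
    out._canon_dirty = [True] * len(out.segments)
    out.rebuild()
    return out
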