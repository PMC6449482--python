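"""The three analysis stages, as composable pipeline steps.

* **Homology build** -- thread a model sequence over a template structure
  and refine it in three consecutive MCM trajectories: (1) sidechain
  torsions only, (2) all generalized coordinates with C-alpha pins (default
  half-width 1 A) to prevent large backbone deformation while clashes
  relax, (3) unpinned, to verify the model is energetically stable.
  Residues that mismatch the template sequence start with all-trans
  sidechains.

* **State transformation** -- steered MCM walks the C-alpha atoms of the
  pore-domain helices toward their positions in a target-state structure,
  while companion restraints preserve helix integrity (alpha-helical H-bond
  restraints, 5-degree backbone-torsion windows), hold the bedplate
  (beta-subunit) and non-steered sensors near the start (flat-bottom pins,
  d = 2.5 / 2.0 A), leave designated groups free, and optionally bias one
  named residue pair (the sensor-AID anchor) -- switchable off for the
  unbiased deactivation variant, where only a 9 A cap on the AID/bedplate
  backbone separation remains.

* **Double-shell mutant sampling** -- residues with a heavy atom within
  15 A of the mutated residue form the flexible shell; residues within
  20 A (and not flexible) form the rigid shell that is held fixed and keeps
  the flexible shell from drifting into space occupied by the full model;
  everything else is excluded from the energy.  Flexible-shell sidechain
  torsions are randomized into (by default) 128 starting conformations,
  each energy-minimized, and the resulting ensemble is reported together
  with the members within 7 kcal/mol of the apparent global minimum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .energy import NonbondedOptions
from .mcm import (EnergyModel, MCMConfig, SteerSchedule, local_minimize,
                  run_mcm, run_steered)
from .restraints import (DistanceRestraint, PinRestraint, RestraintSet,
                         TorsionWindowRestraint, make_helix_restraints,
                         make_pins_from_template)
from .structtools import superpose
from .system import MolecularSystem, apply_mutation, build_system

__all__ = ["TemplateMap", "StateModel", "ShellPartition", "MutantEnsemble",
           "StageConfig", "TransformOptions", "stage_homology",
           "stage_transform", "build_shells", "stage_mutant"]


@dataclass
class TemplateMap:
    """Pairwise model <-> template residue alignment with mismatch flags.

    ``pairs`` is a list of ``(model_key, template_key, match)`` where keys
    are (segment_id, resnum) and ``match`` is True when the aligned residue
    types are identical.  Residue order must be strictly increasing on both
    sides within each segment.
    """

    pairs: list
    unresolved: list = field(default_factory=list)

    def __post_init__(self):
        per_seg: dict[str, int] = {}
        per_seg_t: dict[str, int] = {}
        for (mk, tk, _) in self.pairs:
            for key, tracker in ((mk, per_seg), (tk, per_seg_t)):
                seg, num = key
                if seg in tracker and num <= tracker[seg]:
                    raise ValueError(
                        f"alignment order not increasing at {key}")
                tracker[seg] = num

    def template_key(self, model_key):
        for (mk, tk, _) in self.pairs:
            if tuple(mk) == tuple(model_key):
                return tuple(tk)
        return None

    @property
    def mismatched(self):
        return [tuple(mk) for (mk, tk, m) in self.pairs if not m]


@dataclass
class StateModel:
    state_label: str                   # inactivated | open | closed | custom
    system: MolecularSystem
    provenance: dict = field(default_factory=dict)


@dataclass
class ShellPartition:
    center: tuple
    flexible_shell: set
    rigid_shell: set
    outside: set

    def __post_init__(self):
        assert not (self.flexible_shell & self.rigid_shell)
        assert tuple(self.center) in self.flexible_shell


@dataclass
class MutantEnsemble:
    starts: list                       # starting coordinate vectors
    results: list                      # (vector, energy)
    best_index: int
    window: float = 7.0                # kcal/mol

    @property
    def best(self):
        return self.results[self.best_index]

    @property
    def window_members(self):
        ebest = self.best[1]
        return [i for i, (_, e) in enumerate(self.results)
                if e - ebest <= self.window]


@dataclass(frozen=True)
class StageConfig:
    mcm: MCMConfig = MCMConfig()
    nb: NonbondedOptions = NonbondedOptions()
    pin_d: float = 1.0
    pin_k: float = 10.0
    extra_restraints: RestraintSet | None = None

    def hash(self) -> str:
        blob = json.dumps([repr(self.mcm), repr(self.nb), self.pin_d,
                           self.pin_k], sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ------------------------------------------------------------------ helpers
def _template_coords(template):
    """Coordinate lookup (seg, resnum) -> C-alpha position, and a general
    (seg, resnum, atom) accessor, from a system or a mapping."""
    if isinstance(template, MolecularSystem):
        template.rebuild()

        def ca(key):
            try:
                return template.cartesian[
                    template.atom_index(key[0], key[1], "CA")].copy()
            except KeyError:
                return None

        def atom(seg, num, name):
            try:
                return template.cartesian[
                    template.atom_index(seg, num, name)].copy()
            except KeyError:
                return None
        return ca, atom
    # mapping {(seg, resnum, atom): xyz}
    def ca(key):
        v = template.get((key[0], key[1], "CA"))
        return None if v is None else np.asarray(v, float)

    def atom(seg, num, name):
        v = template.get((seg, num, name))
        return None if v is None else np.asarray(v, float)
    return ca, atom


def _set_flexible(system, torsions="all", roots="all", chi_only_residues=None):
    """Configure the flexible masks; helper for stage protocols."""
    if torsions == "all":
        system.torsion_flexible[:] = True
    elif torsions == "chi":
        for i, v in enumerate(system.torsion_vars):
            system.torsion_flexible[i] = v.kind == "chi"
    elif torsions == "none":
        system.torsion_flexible[:] = False
    if roots == "all":
        system.root_flexible[:] = True
    elif roots == "none":
        system.root_flexible[:] = False


def all_calpha_keys(system):
    return [(seg.id, system.residues[ri].seq_number)
            for seg in system.segments for ri in seg.residue_indices]


# ------------------------------------------------------------ stage 1: build
def stage_homology(template, template_map: TemplateMap, model_specs,
                   config: StageConfig = StageConfig(),
                   state_label: str = "inactivated") -> StateModel:
    """Thread a model over a template and refine with the three-trajectory
    protocol.  ``template`` is a MolecularSystem or an atom-coordinate
    mapping; ``model_specs`` the model's segment definitions."""
    system = build_system(model_specs)
    aligned = {tuple(mk) for (mk, _, _) in template_map.pairs}
    for seg in system.segments:
        for ri in seg.residue_indices:
            key = (seg.id, system.residues[ri].seq_number)
            if key not in aligned:
                raise ValueError(f"model residue {key} missing from the "
                                 f"template alignment")
    ca_of, atom_of = _template_coords(template)

    # initialize internal coordinates from the template structure
    if isinstance(template, MolecularSystem):
        tmpl_ids = {v.id: i for i, v in enumerate(template.torsion_vars)}
        for i, v in enumerate(system.torsion_vars):
            j = tmpl_ids.get(v.id)
            if j is not None:
                system.torsion_values[i] = template.torsion_values[j]
        system.root_positions[:] = template.root_positions
        system.root_orientations[:] = template.root_orientations
    else:
        _measure_from_coords(system, atom_of)
    system._canon_dirty = [True] * len(system.segments)
    system.rebuild()
    system.set_all_trans(template_map.mismatched)

    base = config.extra_restraints or RestraintSet()
    anchors = {}
    for key in all_calpha_keys(system):
        pos = ca_of(key)
        if pos is not None:
            anchors[key] = pos
    reports = []

    # trajectory 1: sidechains only
    _set_flexible(system, torsions="chi", roots="none")
    t1 = run_mcm(EnergyModel(system, config.nb, base), config=config.mcm)
    system.set_vector(t1.lowest[0])
    # trajectory 2: everything flexible, pinned
    _set_flexible(system, torsions="all", roots="all")
    pins = make_pins_from_template(system, anchors, list(anchors),
                                   d=config.pin_d, k=config.pin_k)
    t2 = run_mcm(EnergyModel(system, config.nb,
                             base.merged_with(RestraintSet(pins=pins))),
                 config=config.mcm)
    system.set_vector(t2.lowest[0])
    # trajectory 3: unpinned stability
    t3 = run_mcm(EnergyModel(system, config.nb, base), config=config.mcm)
    system.set_vector(t3.lowest[0])
    for t, name in ((t1, "sidechains"), (t2, "pinned"), (t3, "unpinned")):
        reports.append({"trajectory": name, "energy": t.lowest[1],
                        "n_minimizations": t.n_minimizations,
                        "converged": t.converged})

    keys = [k for k in all_calpha_keys(system) if k in anchors]
    model_ca = system.cartesian[system.calpha_indices(keys)]
    tmpl_ca = np.array([anchors[k] for k in keys])
    fit = superpose(model_ca, tmpl_ca)
    return StateModel(state_label, system, provenance={
        "stage": "homology", "config_hash": config.hash(),
        "seed": config.mcm.rng_seed, "trajectories": reports,
        "ca_rmsd_to_template": fit.rmsd,
    })


def _measure_from_coords(system, atom_of):
    """Initialize torsions and roots by measuring the template coordinates."""
    from .geometry import dihedral, wrap_angle
    for i, v in enumerate(system.torsion_vars):
        for e in system.entries:
            if e.tors_var == i and e.special != "C0":
                pts = []
                ok = True
                for idx in (*e.refs, e.atom):
                    res = system.residues[system.atom_residue[idx]]
                    seg = system.segments[res.segment_index]
                    p = atom_of(seg.id, res.seq_number,
                                str(system.atom_names[idx]))
                    if p is None:
                        ok = False
                        break
                    pts.append(p)
                if ok:
                    system.torsion_values[i] = wrap_angle(
                        dihedral(*pts) - e.tors_value)
                break
    # roots: align each segment's first three backbone atoms
    from .geometry import matrix_to_euler
    system._canon_dirty = [True] * len(system.segments)
    system.rebuild(force=True)
    for seg in system.segments:
        first = system.residues[seg.residue_indices[0]].seq_number
        pts = [atom_of(seg.id, first, nm) for nm in ("N", "CA", "C")]
        if any(p is None for p in pts):
            continue
        lo = seg.atom_slice.start
        canon = system._canon[seg.index]
        loc = [canon[system.atom_index(seg.id, first, nm) - lo]
               for nm in ("N", "CA", "C")]
        L = np.array(loc) - loc[0]
        G = np.array(pts) - pts[0]
        # two-vector frame alignment (N->CA and N->C)
        def frame(a, b):
            x = a / np.linalg.norm(a)
            z = np.cross(a, b)
            z = z / np.linalg.norm(z)
            y = np.cross(z, x)
            return np.stack([x, y, z], axis=1)
        R = frame(G[1], G[2]) @ frame(L[1], L[2]).T
        system.root_orientations[seg.index] = matrix_to_euler(R)
        system.root_positions[seg.index] = pts[0] - R @ canon[
            system.atom_index(seg.id, first, "N") - lo]
    system.rebuild()


# -------------------------------------------------------- stage 2: transform
@dataclass
class TransformOptions:
    """Restraint layout for a steered state transformation."""

    targeted: list                       # C-alpha locators to steer
    helix_ranges: list = field(default_factory=list)   # (seg_id, [resnums])
    torsion_windows: list = field(default_factory=list)  # (seg, [resnums], deg)
    pinned_groups: list = field(default_factory=list)  # ([(seg,res)...], d)
    anchor_pair: tuple | None = None     # ((seg,res,atom),(seg,res,atom),hi)
    backbone_caps: list = field(default_factory=list)  # ((a),(b),limit)
    n_stages: int = 10
    target_half_width: float = 1.0
    target_k: float = 10.0
    stability_run: bool = True


def stage_transform(model: StateModel, target, options: TransformOptions,
                    config: StageConfig = StageConfig(),
                    state_label: str = "custom") -> StateModel:
    """Steer a state model toward target-state C-alpha positions.

    ``target`` is a MolecularSystem or coordinate mapping supplying the end
    anchors for the targeted atoms.  The companion restraints (helix
    H-bonds, torsion windows referenced to the *current* model values, pins
    anchored at current positions, optional anchor-pair bias and backbone
    separation caps) implement the steering protocol; setting
    ``options.anchor_pair = None`` gives the unbiased variant.
    """
    system = model.system
    ca_of, atom_of = _template_coords(target)
    start, end = [], []
    missing = []
    for loc in options.targeted:
        seg, num, name = loc
        p = atom_of(seg, num, name)
        if p is None:
            missing.append(loc)
            continue
        start.append(system.cartesian[system.atom_index(seg, num, name)])
        end.append(p)
    if missing:
        raise KeyError(f"no target correspondence for: {missing}")

    companion = RestraintSet()
    for seg_id, resnums in options.helix_ranges:
        companion.helix_restraints.append(
            make_helix_restraints(system, seg_id, resnums))
    for seg_id, resnums, half in options.torsion_windows:
        for num in resnums:
            for name in ("phi", "psi"):
                try:
                    vi = system.var_index(seg_id, num, name)
                except KeyError:
                    continue
                companion.torsion_windows.append(TorsionWindowRestraint(
                    (seg_id, num, name),
                    float(np.degrees(system.torsion_values[vi])), half))
    for selection, d in options.pinned_groups:
        anchors = {tuple(k): system.cartesian[
            system.atom_index(k[0], k[1], "CA")].copy() for k in selection}
        companion.pins.extend(make_pins_from_template(
            system, anchors, list(anchors), d=d, k=config.pin_k))
    if options.anchor_pair is not None:
        a, b, hi = options.anchor_pair
        companion.distances.append(DistanceRestraint(a, b, 0.0, hi))
    for a, b, hi in options.backbone_caps:
        companion.distances.append(DistanceRestraint(a, b, 0.0, hi))
    if config.extra_restraints is not None:
        companion = companion.merged_with(config.extra_restraints)

    schedule = SteerSchedule(
        targeted_atoms=list(options.targeted),
        start_anchors=np.array(start), end_anchors=np.array(end),
        n_stages=options.n_stages, half_width=options.target_half_width,
        force_k=options.target_k, companion=companion)
    system, report = run_steered(system, schedule, None, config.mcm,
                                 config.nb,
                                 stability_run=options.stability_run)
    prov = {
        "stage": "transform", "config_hash": config.hash(),
        "seed": config.mcm.rng_seed, "report": {
            k: (v if not isinstance(v, np.ndarray) else v.tolist())
            for k, v in report.items()},
        "restraint_dump": _restraint_dump(companion, schedule),
        "parent": model.provenance,
    }
    return StateModel(state_label, system, prov)


def _restraint_dump(companion: RestraintSet, schedule: SteerSchedule):
    """Auditable list of every restraint active during steering."""
    dump = [{"type": "target_pin", "atom": list(loc),
             "half_width": schedule.half_width, "k": schedule.force_k}
            for loc in schedule.targeted_atoms]
    for p in companion.pins:
        dump.append({"type": "pin", "atom": list(p.atom),
                     "half_width": p.half_width_d, "k": p.force_k})
    for d in companion.distances:
        dump.append({"type": "distance", "atoms": [list(d.atom_a),
                                                   list(d.atom_b)],
                     "lower": d.lower, "upper": d.upper, "k": d.force_k})
    for t in companion.torsion_windows:
        dump.append({"type": "torsion_window", "torsion": list(t.torsion),
                     "half_width": t.half_width, "k": t.force_k})
    for h in companion.helix_restraints:
        dump.append({"type": "helix_hbond", "n_pairs": len(h.pairs),
                     "target": h.target, "half_width": h.half_width})
    return dump


# ------------------------------------------------------ stage 3: mutants
def build_shells(model, site, r_flex: float = 15.0, r_rigid: float = 20.0
                 ) -> ShellPartition:
    """Double-shell partition around a mutated residue.

    Distances are minima over heavy-atom pairs.  The flexible shell holds
    residues with a heavy atom within ``r_flex`` of the center; the rigid
    shell those outside it but within ``r_rigid``; the remainder is
    excluded entirely.
    """
    system = model.system if isinstance(model, StateModel) else model
    system.rebuild()
    center = system.residue(*site)
    c_idx = [i for i in center.atom_indices if system.heavy_mask[i]]
    cpos = system.cartesian[c_idx]
    flexible, rigid, outside = set(), set(), set()
    for seg in system.segments:
        for ri in seg.residue_indices:
            res = system.residues[ri]
            key = (seg.id, res.seq_number)
            idx = [i for i in res.atom_indices if system.heavy_mask[i]]
            d = float(cdist(system.cartesian[idx], cpos).min())
            if d <= r_flex:
                flexible.add(key)
            elif d <= r_rigid:
                rigid.add(key)
            else:
                outside.add(key)
    return ShellPartition(tuple(site), flexible, rigid, outside)


def stage_mutant(model: StateModel, mutation_spec, shells=None,
                 n_starts: int = 128, config: StageConfig = StageConfig(),
                 window: float = 7.0, randomize: str = "sidechains"
                 ) -> tuple[StateModel, MutantEnsemble]:
    """Double-shell mutant sampling.

    ``mutation_spec`` is (site, new_residue[, variant[, disulfide_partner]]).
    Flexible-shell sidechain torsions are resampled uniformly in each of
    ``n_starts`` starting conformations (``randomize="all"`` also resamples
    their backbone); each start is energy-minimized with the rigid shell
    frozen and outside residues excluded from the energy.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    site, new_res, *rest = mutation_spec
    variant = rest[0] if rest else "default"
    partner = rest[1] if len(rest) > 1 else None
    mutant = apply_mutation(model.system, site, new_res, variant=variant,
                            disulfide_partner=partner)
    if shells is None:
        shells = build_shells(mutant, site)
    res_index = {(seg.id, mutant.residues[ri].seq_number): ri
                 for seg in mutant.segments for ri in seg.residue_indices}
    active = {res_index[k] for k in
              (shells.flexible_shell | shells.rigid_shell)}

    mutant.root_flexible[:] = False
    flex_t = []
    for i, v in enumerate(mutant.torsion_vars):
        res = mutant.residues[v.res_index]
        key = (mutant.segments[res.segment_index].id, res.seq_number)
        in_flex = key in shells.flexible_shell
        if randomize == "all":
            mutant.torsion_flexible[i] = in_flex
        else:
            mutant.torsion_flexible[i] = in_flex and v.kind == "chi"
        if mutant.torsion_flexible[i]:
            flex_t.append(i)
    model_e = EnergyModel(mutant, config.nb,
                          config.extra_restraints or RestraintSet(),
                          active_residues=active)

    rng = np.random.default_rng(config.mcm.rng_seed)
    t_idx, a_idx, r_idx = mutant.coordinate_layout()
    nt = len(t_idx)
    x0 = mutant.get_vector()
    starts, results = [], []
    for _ in range(n_starts):
        x = x0.copy()
        x[:nt] = rng.uniform(-np.pi, np.pi, nt)
        starts.append(x.copy())
        xm, em = local_minimize(model_e, x0=x,
                                max_iter=config.mcm.max_min_iterations)
        results.append((xm, em))
    best = int(np.argmin([e for (_, e) in results]))
    mutant.set_vector(results[best][0])
    ensemble = MutantEnsemble(starts, results, best, window)
    out = StateModel(model.state_label, mutant, provenance={
        "stage": "mutant", "config_hash": config.hash(),
        "seed": config.mcm.rng_seed, "site": list(site),
        "new_residue": new_res, "variant": variant,
        "n_starts": n_starts, "best_energy": results[best][1],
        "parent": model.provenance,
    })
    return out, ensemble
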