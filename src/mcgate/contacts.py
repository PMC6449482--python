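"""State-dependent residue contact-energy analysis.

A contact map lists residue pairs between two named segment groups with
their nonbonded interaction energies (computed without cutoff, so reported
contact tables do not depend on the 9 A truncation).  Contacts are
classified geometrically as hydrogen bonds, salt bridges or hydrophobic
contacts, and flagged repulsive when the energy is positive.  Printed-figure
binning schemes and cross-state comparison (shared / state-only contacts)
mirror the way such analyses are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import NonbondedOptions, nonbonded_energy
from .geometry import bond_angle

__all__ = ["ContactRecord", "BinScheme", "StateComparison", "contact_map",
           "classify_interaction", "bin_contacts", "compare_states",
           "aggregate_net_energy", "FIG3_SCHEME", "FIG6_SCHEME"]


@dataclass
class ContactRecord:
    residue_a: tuple            # (seg_id, resnum)
    residue_b: tuple
    energy: float               # kcal/mol
    e_lj: float = 0.0
    e_coul: float = 0.0
    types: set = field(default_factory=set)
    state_label: str | None = None
    bin_label: str | None = None

    @property
    def key(self):
        return tuple(sorted((self.residue_a, self.residue_b)))


@dataclass(frozen=True)
class BinScheme:
    """Descending energy thresholds with display labels.

    ``edges`` are the printed bin boundaries (kcal/mol, descending, i.e.
    increasingly negative); a record with edges[k] >= E > edges[k+1] gets
    labels[k]; E below the last edge gets the final label.  Records weaker
    (less negative) than edges[0] but at least ``display_floor`` in
    magnitude fall into the not-shown class; positive energies are labelled
    repulsive.
    """

    edges: tuple
    labels: tuple
    display_floor: float

    def __post_init__(self):
        if list(self.edges) != sorted(self.edges, reverse=True):
            raise ValueError("bin edges must be strictly descending")
        if len(self.labels) != len(self.edges):
            raise ValueError("need one label per edge")

    def assign(self, energy: float) -> str:
        if energy > 0:
            return "repulsive"
        if energy > self.edges[0]:
            return ("not_shown" if abs(energy) >= self.display_floor
                    else "below_floor")
        for k in range(len(self.edges) - 1):
            if self.edges[k] >= energy > self.edges[k + 1]:
                return self.labels[k]
        return self.labels[-1]


# the two printed schemes: neither is privileged
FIG3_SCHEME = BinScheme(edges=(-0.9, -1.5, -3.0, -5.0),
                        labels=("dotted", "thin", "intermediate", "thick"),
                        display_floor=0.4)
FIG6_SCHEME = BinScheme(edges=(-0.5, -2.5, -5.0),
                        labels=("thin", "intermediate", "thick"),
                        display_floor=0.5)


@dataclass
class StateComparison:
    presence: dict              # pair key -> set of state labels
    classification: dict        # pair key -> "only-<s>" | "shared-all" | "partial"


def _group_residues(system, group):
    """Resolve a group given as segment ids or residue keys to indices."""
    out = set()
    if all(isinstance(g, str) for g in group):
        for seg_id in group:
            seg = system.segment(seg_id)
            out.update(seg.residue_indices)
    else:
        idx = {(seg.id, system.residues[ri].seq_number): ri
               for seg in system.segments for ri in seg.residue_indices}
        for key in group:
            out.add(idx[tuple(key)])
    return out


def contact_map(model, group_a, group_b, presence_floor: float = 0.4,
                nb_options: NonbondedOptions | None = None,
                state_label: str | None = None) -> list[ContactRecord]:
    """Residue-pair contact energies between two segment groups.

    Records every pair with ``|E| >= presence_floor``; energies are computed
    without cutoff by default.  The sum of all per-pair energies (before the
    floor) equals the group-filtered total.
    """
    from .pipeline import StateModel
    system = model.system if isinstance(model, StateModel) else model
    if state_label is None and isinstance(model, StateModel):
        state_label = model.state_label
    ra = _group_residues(system, group_a)
    rb = _group_residues(system, group_b)
    if ra & rb:
        raise ValueError("contact groups overlap")
    nb = nb_options or NonbondedOptions(cutoff=np.inf)
    bd = nonbonded_energy(system, nb, group_filter=(ra, rb))
    records = []
    for (key_a, key_b), terms in bd.per_pair.items():
        if abs(terms["E_total"]) < presence_floor:
            continue
        rec = ContactRecord(key_a, key_b, terms["E_total"],
                            e_lj=terms["E_LJ"], e_coul=terms["E_coul"],
                            state_label=state_label)
        rec.types = classify_interaction(system, rec)
        records.append(rec)
    records.sort(key=lambda r: r.energy)
    return records


def _donors_acceptors(system, res):
    """(donor_heavy, hydrogen) pairs and acceptor atoms of a residue."""
    donors, acceptors = [], []
    adj = {}
    for a, b in system.bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for i in res.atom_indices:
        el = system.atom_elements[i]
        if el == "H":
            for j in adj.get(i, []):
                if system.atom_elements[j] in ("N", "O", "S"):
                    donors.append((j, i))
        elif el in ("O", "S"):
            acceptors.append(i)
        elif el == "N":
            has_h = any(system.atom_elements[j] == "H"
                        for j in adj.get(i, []))
            if not has_h:
                acceptors.append(i)
    return donors, acceptors


def classify_interaction(system, record: ContactRecord) -> set:
    """Geometric interaction typing for one contact record.

    h_bond: donor-heavy to acceptor <= 3.5 A with D-H...A angle >= 120 deg;
    salt_bridge: opposite net formal charges with an N/O-N/O pair <= 4.0 A;
    hydrophobic: neither, with the LJ term dominating; repulsive: E > 0.
    """
    system.rebuild()
    X = system.cartesian
    res_a = system.residue(*record.residue_a)
    res_b = system.residue(*record.residue_b)
    types = set()
    if record.energy > 0:
        types.add("repulsive")
    for (ra, rb) in ((res_a, res_b), (res_b, res_a)):
        donors, _ = _donors_acceptors(system, ra)
        _, acceptors = _donors_acceptors(system, rb)
        for (d, h) in donors:
            for a in acceptors:
                if np.linalg.norm(X[d] - X[a]) <= 3.5:
                    ang = np.degrees(bond_angle(X[d], X[h], X[a]))
                    if ang >= 120.0:
                        types.add("h_bond")
    qa = int(sum(system.formal_charges[i] for i in res_a.atom_indices))
    qb = int(sum(system.formal_charges[i] for i in res_b.atom_indices))
    if qa * qb < 0:
        na = [i for i in res_a.atom_indices
              if system.atom_elements[i] in ("N", "O")]
        nb_ = [i for i in res_b.atom_indices
               if system.atom_elements[i] in ("N", "O")]
        if na and nb_:
            from scipy.spatial.distance import cdist
            if cdist(X[na], X[nb_]).min() <= 4.0:
                types.add("salt_bridge")
    if not types & {"h_bond", "salt_bridge"}:
        if record.energy <= 0 and abs(record.e_lj) >= abs(record.e_coul):
            types.add("hydrophobic")
    return types


def bin_contacts(records, scheme: BinScheme):
    """Assign each record exactly one bin label (record retained even when
    the label is the not-shown display-floor class)."""
    for rec in records:
        rec.bin_label = scheme.assign(rec.energy)
    return records


def compare_states(maps: dict) -> StateComparison:
    """Cross-state contact presence: ``maps`` is {state_label: records}."""
    if maps and len(maps) < 2:
        raise ValueError("state comparison needs at least two states")
    presence: dict = {}
    for state, records in maps.items():
        for rec in records:
            presence.setdefault(rec.key, set()).add(state)
    classification = {}
    all_states = set(maps)
    for key, states in presence.items():
        if len(states) == 1:
            classification[key] = f"only-{next(iter(states))}"
        elif states == all_states:
            classification[key] = "shared-all"
        else:
            classification[key] = "partial"
    return StateComparison(presence, classification)


def aggregate_net_energy(source, residue: str, state: str) -> float:
    """Net intersegment contact energy of one residue in one state.

    ``source`` is either a list of ContactRecord (then ``residue`` is a
    (seg, resnum) key and records are filtered by state label) or a
    FixtureTable whose columns are ``<residue>_<state initial>`` (e.g. the
    G402S / G406R columns of the printed mutant table).  The result is the
    arithmetic sum, rounded to 2 decimals for reporting.
    """
    from .synthetic import FixtureTable
    if isinstance(source, FixtureTable):
        col = f"{residue}_{state[0]}"
        if col not in source.data.columns:
            raise KeyError(f"fixture {source.table_id} has no column {col!r}"
                           f" (residue {residue!r}, state {state!r})")
        vals = source.data[col].dropna()
        if vals.empty:
            raise KeyError(f"no entries for {residue!r} in state {state!r}")
        return round(float(vals.sum()), 2)
    records = [r for r in source
               if (r.state_label == state or state is None)
               and (tuple(residue) in (r.residue_a, r.residue_b))]
    if not records and source:
        raise KeyError(f"residue {residue!r} absent from records")
    return round(float(sum(r.energy for r in records)), 2)
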