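"""Built-in amino-acid topology library.

Residue templates define, for every atom, its nonbonded parameters and an
internal-coordinate build rule (a Z-matrix entry): three reference atoms, a
bond length, a bond angle and a torsion specification.  Torsions are either
fixed (rigid geometry) or bound to a named variable (``phi``, ``psi``,
``omega``, ``chi1`` ... ``chi5``).  Reference atom names prefixed with ``-``
refer to the previous residue in the chain.

The parameter set is a self-consistent united-atom table in the AMBER
lineage: polar hydrogens are explicit, nonpolar hydrogens are united into
their heavy atoms.  Partial charges sum to the formal charge of each residue
variant.  The library can be exported to / loaded from a documented JSON
schema (see :func:`dump_json` / :func:`load_json`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "AtomTemplate",
    "ResidueTemplate",
    "TopologyLibrary",
    "default_topology",
    "dump_json",
    "load_json",
]

# Lennard-Jones classes: rmin/2 (Angstrom), epsilon (kcal/mol)
_LJ = {
    "C": (2.00, 0.12),   # united aliphatic/aromatic carbon
    "N": (1.85, 0.16),
    "O": (1.66, 0.21),
    "S": (2.00, 0.25),
    "H": (0.60, 0.0157),  # polar hydrogen
}

# canonical backbone geometry (Angstrom / degrees)
_B_NC = 1.329   # C(i-1)-N
_B_NCA = 1.458
_B_CAC = 1.525
_B_CO = 1.231
_B_NH = 1.010
_A_CNCA = 121.7
_A_NCAC = 111.2
_A_CACN = 116.2
_A_CACO = 120.5


@dataclass(frozen=True)
class AtomTemplate:
    """One atom of a residue template, with its build rule."""

    name: str
    element: str
    charge: float                    # elementary charges
    formal_charge: int = 0
    ionized: bool = False            # member of an ionized group
    refs: tuple[str, str, str] | None = None  # (a1, a2, a3); None for chain roots
    bond: float = 0.0                # a3-atom distance, Angstrom
    angle: float = 0.0               # a2-a3-atom angle, degrees
    # torsion spec: ("f", deg) fixed, or ("v", varname, offset_deg)
    tors: tuple = ("f", 0.0)

    @property
    def partial_charge(self) -> float:
        return self.charge

    @property
    def lj_rmin_half(self) -> float:
        return _LJ[self.element][0]

    @property
    def lj_epsilon(self) -> float:
        return _LJ[self.element][1]

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class ResidueTemplate:
    name: str                         # 3-letter code
    atoms: tuple[AtomTemplate, ...]
    chis: tuple[str, ...] = ()        # flexible sidechain torsion names
    # extra bonds beyond the build tree (ring closures), by atom name
    ring_bonds: tuple[tuple[str, str], ...] = ()
    variant: str = "default"

    def atom(self, name: str) -> AtomTemplate:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} has no atom {name!r}")

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)


def _bb(gly: bool = False, pro: bool = False) -> list[AtomTemplate]:
    """Backbone atom templates shared by all residues.

    The chain-root placement of N/CA/C for the first residue of a segment is
    handled by the builder; the refs below apply from the second residue on.
    """
    n_chg, ca_chg = (-0.52, 0.21)
    ats = [
        AtomTemplate("N", "N", -0.26 if pro else n_chg,
                     refs=("-N", "-CA", "-C"), bond=_B_NC, angle=_A_CACN,
                     tors=("v", "psi-", 0.0)),
        AtomTemplate("CA", "C", 0.26 if pro else (0.25 if gly else ca_chg),
                     refs=("-CA", "-C", "N"), bond=_B_NCA, angle=_A_CNCA,
                     tors=("v", "omega", 0.0)),
        AtomTemplate("C", "C", 0.53 if gly else 0.53,
                     refs=("-C", "N", "CA"), bond=_B_CAC, angle=_A_NCAC,
                     tors=("v", "phi", 0.0)),
        AtomTemplate("O", "O", -0.53,
                     refs=("N", "CA", "C"), bond=_B_CO, angle=_A_CACO,
                     tors=("v", "psi", 180.0)),
    ]
    if not pro:
        ats.append(AtomTemplate("H", "H", 0.31 if not gly else 0.27,
                                refs=("CA", "-C", "N"), bond=_B_NH,
                                angle=119.0, tors=("f", 180.0)))
    return ats


def _cb(charge: float = 0.0) -> AtomTemplate:
    # fixed branch torsion off the phi-bearing axis; -120 gives L-chirality
    return AtomTemplate("CB", "C", charge, refs=("C", "N", "CA"),
                        bond=1.530, angle=110.5, tors=("f", -120.0))


def _sc(name, elem, chg, a1, a2, a3, bond, angle, tors,
        formal=0, ionized=False):
    return AtomTemplate(name, elem, chg, formal_charge=formal,
                        ionized=ionized, refs=(a1, a2, a3), bond=bond,
                        angle=angle, tors=tors)


def _residue(name, side, chis=(), ring_bonds=(), gly=False, pro=False,
             variant="default"):
    return ResidueTemplate(name, tuple(_bb(gly=gly, pro=pro) + side),
                           chis=tuple(chis), ring_bonds=tuple(ring_bonds),
                           variant=variant)


def _build_library() -> dict[str, ResidueTemplate]:
    lib: dict[str, ResidueTemplate] = {}

    lib["GLY"] = _residue("GLY", [], gly=True)
    lib["ALA"] = _residue("ALA", [_cb()])

    lib["SER"] = _residue("SER", [
        _cb(0.25),
        _sc("OG", "O", -0.65, "N", "CA", "CB", 1.430, 110.5, ("v", "chi1", 0.0)),
        _sc("HG", "H", 0.40, "CA", "CB", "OG", 0.960, 108.5, ("v", "chi2", 0.0)),
    ], chis=("chi1", "chi2"))

    lib["CYS"] = _residue("CYS", [
        _cb(0.10),
        _sc("SG", "S", -0.45, "N", "CA", "CB", 1.810, 114.0, ("v", "chi1", 0.0)),
        _sc("HG", "H", 0.35, "CA", "CB", "SG", 1.330, 96.0, ("v", "chi2", 0.0)),
    ], chis=("chi1", "chi2"))
    # oxidized form: no thiol hydrogen; the S-S bond is added by the system
    lib["CYS:disulfide"] = _residue("CYS", [
        _cb(0.10),
        _sc("SG", "S", -0.10, "N", "CA", "CB", 1.810, 114.0, ("v", "chi1", 0.0)),
    ], chis=("chi1",), variant="disulfide")

    lib["THR"] = _residue("THR", [
        _cb(0.25),
        _sc("OG1", "O", -0.65, "N", "CA", "CB", 1.430, 109.5, ("v", "chi1", 0.0)),
        _sc("CG2", "C", 0.0, "N", "CA", "CB", 1.530, 110.5, ("v", "chi1", -120.0)),
        _sc("HG1", "H", 0.40, "CA", "CB", "OG1", 0.960, 108.5, ("v", "chi2", 0.0)),
    ], chis=("chi1", "chi2"))

    lib["VAL"] = _residue("VAL", [
        _cb(),
        _sc("CG1", "C", 0.0, "N", "CA", "CB", 1.530, 110.5, ("v", "chi1", 0.0)),
        _sc("CG2", "C", 0.0, "N", "CA", "CB", 1.530, 110.5, ("v", "chi1", 122.0)),
    ], chis=("chi1",))

    lib["LEU"] = _residue("LEU", [
        _cb(),
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.530, 116.3, ("v", "chi1", 0.0)),
        _sc("CD1", "C", 0.0, "CA", "CB", "CG", 1.530, 110.5, ("v", "chi2", 0.0)),
        _sc("CD2", "C", 0.0, "CA", "CB", "CG", 1.530, 110.5, ("v", "chi2", 122.0)),
    ], chis=("chi1", "chi2"))

    lib["ILE"] = _residue("ILE", [
        _cb(),
        _sc("CG1", "C", 0.0, "N", "CA", "CB", 1.530, 110.5, ("v", "chi1", 0.0)),
        _sc("CG2", "C", 0.0, "N", "CA", "CB", 1.530, 110.5, ("v", "chi1", -122.0)),
        _sc("CD1", "C", 0.0, "CA", "CB", "CG1", 1.530, 110.5, ("v", "chi2", 0.0)),
    ], chis=("chi1", "chi2"))

    lib["MET"] = _residue("MET", [
        _cb(),
        _sc("CG", "C", 0.06, "N", "CA", "CB", 1.530, 114.0, ("v", "chi1", 0.0)),
        _sc("SD", "S", -0.12, "CA", "CB", "CG", 1.810, 112.7, ("v", "chi2", 0.0)),
        _sc("CE", "C", 0.06, "CB", "CG", "SD", 1.810, 100.9, ("v", "chi3", 0.0)),
    ], chis=("chi1", "chi2", "chi3"))

    lib["PRO"] = _residue("PRO", [
        _cb(),
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.495, 104.5, ("v", "chi1", 30.0)),
        _sc("CD", "C", 0.0, "CA", "CB", "CG", 1.507, 105.5, ("v", "chi2", -35.0)),
    ], chis=("chi1", "chi2"), ring_bonds=(("CD", "N"),), pro=True)

    # planar hexagon: 120 deg angles, 180/0 torsions close the ring exactly
    phe_ring = [
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.510, 114.0, ("v", "chi1", 0.0)),
        _sc("CD1", "C", 0.0, "CA", "CB", "CG", 1.400, 120.0, ("v", "chi2", 0.0)),
        _sc("CD2", "C", 0.0, "CD1", "CB", "CG", 1.400, 120.0, ("f", 180.0)),
        _sc("CE1", "C", 0.0, "CB", "CG", "CD1", 1.400, 120.0, ("f", 180.0)),
        _sc("CE2", "C", 0.0, "CB", "CG", "CD2", 1.400, 120.0, ("f", 180.0)),
        _sc("CZ", "C", 0.0, "CG", "CD1", "CE1", 1.400, 120.0, ("f", 0.0)),
    ]
    lib["PHE"] = _residue("PHE", [_cb()] + phe_ring,
                          chis=("chi1", "chi2"),
                          ring_bonds=(("CZ", "CE2"),))

    tyr_side = [replace(a, charge=(0.25 if a.name == "CZ" else a.charge))
                for a in phe_ring]
    lib["TYR"] = _residue("TYR", [_cb()] + tyr_side + [
        _sc("OH", "O", -0.65, "CD1", "CE1", "CZ", 1.364, 120.0, ("f", 180.0)),
        _sc("HH", "H", 0.40, "CE1", "CZ", "OH", 0.960, 110.0, ("v", "chi3", 0.0)),
    ], chis=("chi1", "chi2", "chi3"), ring_bonds=(("CZ", "CE2"),))

    # indole: exact pentagon + approximate fused hexagon (rigid, tree-built)
    lib["TRP"] = _residue("TRP", [
        _cb(),
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.510, 114.0, ("v", "chi1", 0.0)),
        _sc("CD1", "C", 0.0, "CA", "CB", "CG", 1.370, 127.0, ("v", "chi2", 0.0)),
        _sc("NE1", "N", -0.33, "CB", "CG", "CD1", 1.370, 108.0, ("f", 180.0)),
        _sc("HE1", "H", 0.33, "CG", "CD1", "NE1", 1.010, 125.0, ("f", 180.0)),
        _sc("CE2", "C", 0.0, "CG", "CD1", "NE1", 1.370, 108.0, ("f", 0.0)),
        _sc("CD2", "C", 0.0, "CD1", "NE1", "CE2", 1.400, 108.0, ("f", 0.0)),
        _sc("CZ2", "C", 0.0, "CD1", "NE1", "CE2", 1.400, 130.0, ("f", 180.0)),
        _sc("CE3", "C", 0.0, "NE1", "CE2", "CD2", 1.400, 130.0, ("f", 180.0)),
        _sc("CH2", "C", 0.0, "NE1", "CE2", "CZ2", 1.400, 117.0, ("f", 180.0)),
        _sc("CZ3", "C", 0.0, "CE2", "CD2", "CE3", 1.400, 118.0, ("f", 180.0)),
    ], chis=("chi1", "chi2"),
        ring_bonds=(("CD2", "CG"), ("CZ3", "CH2")))

    lib["ASP"] = _residue("ASP", [
        _cb(-0.10),
        _sc("CG", "C", 0.62, "N", "CA", "CB", 1.527, 112.6, ("v", "chi1", 0.0),
            ionized=True),
        _sc("OD1", "O", -0.76, "CA", "CB", "CG", 1.250, 118.4, ("v", "chi2", 0.0),
            formal=-1, ionized=True),
        _sc("OD2", "O", -0.76, "OD1", "CB", "CG", 1.250, 118.4, ("f", 180.0),
            ionized=True),
    ], chis=("chi1", "chi2"))

    lib["GLU"] = _residue("GLU", [
        _cb(),
        _sc("CG", "C", -0.10, "N", "CA", "CB", 1.530, 114.0, ("v", "chi1", 0.0)),
        _sc("CD", "C", 0.62, "CA", "CB", "CG", 1.527, 112.6, ("v", "chi2", 0.0),
            ionized=True),
        _sc("OE1", "O", -0.76, "CB", "CG", "CD", 1.250, 118.4, ("v", "chi3", 0.0),
            formal=-1, ionized=True),
        _sc("OE2", "O", -0.76, "OE1", "CG", "CD", 1.250, 118.4, ("f", 180.0),
            ionized=True),
    ], chis=("chi1", "chi2", "chi3"))

    lib["ASN"] = _residue("ASN", [
        _cb(),
        _sc("CG", "C", 0.55, "N", "CA", "CB", 1.527, 112.6, ("v", "chi1", 0.0)),
        _sc("OD1", "O", -0.55, "CA", "CB", "CG", 1.231, 120.9, ("v", "chi2", 0.0)),
        _sc("ND2", "N", -0.60, "OD1", "CB", "CG", 1.328, 116.5, ("f", 180.0)),
        _sc("HD21", "H", 0.30, "OD1", "CG", "ND2", 1.010, 119.0, ("f", 180.0)),
        _sc("HD22", "H", 0.30, "OD1", "CG", "ND2", 1.010, 119.0, ("f", 0.0)),
    ], chis=("chi1", "chi2"))

    lib["GLN"] = _residue("GLN", [
        _cb(),
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.530, 114.0, ("v", "chi1", 0.0)),
        _sc("CD", "C", 0.55, "CA", "CB", "CG", 1.527, 112.6, ("v", "chi2", 0.0)),
        _sc("OE1", "O", -0.55, "CB", "CG", "CD", 1.231, 120.9, ("v", "chi3", 0.0)),
        _sc("NE2", "N", -0.60, "OE1", "CG", "CD", 1.328, 116.5, ("f", 180.0)),
        _sc("HE21", "H", 0.30, "OE1", "CD", "NE2", 1.010, 119.0, ("f", 180.0)),
        _sc("HE22", "H", 0.30, "OE1", "CD", "NE2", 1.010, 119.0, ("f", 0.0)),
    ], chis=("chi1", "chi2", "chi3"))

    lib["LYS"] = _residue("LYS", [
        _cb(),
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.530, 114.0, ("v", "chi1", 0.0)),
        _sc("CD", "C", 0.0, "CA", "CB", "CG", 1.530, 111.3, ("v", "chi2", 0.0)),
        _sc("CE", "C", 0.25, "CB", "CG", "CD", 1.530, 111.3, ("v", "chi3", 0.0),
            ionized=True),
        _sc("NZ", "N", -0.30, "CG", "CD", "CE", 1.470, 111.5, ("v", "chi4", 0.0),
            formal=1, ionized=True),
        _sc("HZ1", "H", 0.35, "CD", "CE", "NZ", 1.010, 109.5, ("v", "chi5", 60.0),
            ionized=True),
        _sc("HZ2", "H", 0.35, "CD", "CE", "NZ", 1.010, 109.5, ("v", "chi5", 180.0),
            ionized=True),
        _sc("HZ3", "H", 0.35, "CD", "CE", "NZ", 1.010, 109.5, ("v", "chi5", -60.0),
            ionized=True),
    ], chis=("chi1", "chi2", "chi3", "chi4", "chi5"))

    lib["ARG"] = _residue("ARG", [
        _cb(),
        _sc("CG", "C", 0.0, "N", "CA", "CB", 1.530, 114.0, ("v", "chi1", 0.0)),
        _sc("CD", "C", 0.10, "CA", "CB", "CG", 1.530, 111.3, ("v", "chi2", 0.0),
            ionized=True),
        _sc("NE", "N", -0.40, "CB", "CG", "CD", 1.470, 111.5, ("v", "chi3", 0.0),
            ionized=True),
        _sc("CZ", "C", 0.50, "CG", "CD", "NE", 1.330, 124.0, ("v", "chi4", 0.0),
            formal=1, ionized=True),
        _sc("HE", "H", 0.30, "CZ", "CD", "NE", 1.010, 118.0, ("f", 180.0),
            ionized=True),
        _sc("NH1", "N", -0.45, "CD", "NE", "CZ", 1.330, 120.0, ("f", 0.0),
            ionized=True),
        _sc("NH2", "N", -0.45, "CD", "NE", "CZ", 1.330, 120.0, ("f", 180.0),
            ionized=True),
        _sc("HH11", "H", 0.35, "NE", "CZ", "NH1", 1.010, 120.0, ("f", 0.0),
            ionized=True),
        _sc("HH12", "H", 0.35, "NE", "CZ", "NH1", 1.010, 120.0, ("f", 180.0),
            ionized=True),
        _sc("HH21", "H", 0.35, "NE", "CZ", "NH2", 1.010, 120.0, ("f", 0.0),
            ionized=True),
        _sc("HH22", "H", 0.35, "NE", "CZ", "NH2", 1.010, 120.0, ("f", 180.0),
            ionized=True),
    ], chis=("chi1", "chi2", "chi3", "chi4"))

    # histidine: exact pentagon; three tautomer variants
    def his_ring(nd1_chg, ce1_chg, ne2_chg, cg_chg, cd2_chg, ionized=False,
                 formal_on=None):
        def f(nm):
            return (1 if nm == formal_on else 0)
        return [
            _sc("CG", "C", cg_chg, "N", "CA", "CB", 1.510, 114.0,
                ("v", "chi1", 0.0), ionized=ionized),
            _sc("ND1", "N", nd1_chg, "CA", "CB", "CG", 1.370, 122.0,
                ("v", "chi2", 0.0), formal=f("ND1"), ionized=ionized),
            _sc("CE1", "C", ce1_chg, "CB", "CG", "ND1", 1.340, 108.0,
                ("f", 180.0), ionized=ionized),
            _sc("NE2", "N", ne2_chg, "CG", "ND1", "CE1", 1.340, 108.0,
                ("f", 0.0), ionized=ionized),
            _sc("CD2", "C", cd2_chg, "ND1", "CE1", "NE2", 1.370, 108.0,
                ("f", 0.0), ionized=ionized),
        ]

    hd1 = _sc("HD1", "H", 0.36, "CE1", "CG", "ND1", 1.010, 126.0, ("f", 180.0))
    he2 = _sc("HE2", "H", 0.36, "ND1", "CE1", "NE2", 1.010, 125.0, ("f", 180.0))
    lib["HIS:HID"] = _residue(
        "HIS", [_cb()] + his_ring(-0.40, 0.20, -0.40, 0.12, 0.12) + [hd1],
        chis=("chi1", "chi2"), ring_bonds=(("CD2", "CG"),), variant="HID")
    lib["HIS:HIE"] = _residue(
        "HIS", [_cb()] + his_ring(-0.40, 0.20, -0.40, 0.12, 0.12) + [he2],
        chis=("chi1", "chi2"), ring_bonds=(("CD2", "CG"),), variant="HIE")
    lib["HIS:HIP"] = _residue(
        "HIS",
        [_cb()] + his_ring(-0.30, 0.35, -0.30, 0.28, 0.27, ionized=True,
                           formal_on="ND1")
        + [replace(hd1, charge=0.35, ionized=True),
           replace(he2, charge=0.35, ionized=True)],
        chis=("chi1", "chi2"), ring_bonds=(("CD2", "CG"),), variant="HIP")
    lib["HIS"] = lib["HIS:HIE"]  # neutral default tautomer

    return lib


@dataclass
class TopologyLibrary:
    """Residue-name -> template mapping with variant lookup.

    Keys are 3-letter codes; protonation / redox variants are reachable as
    ``"HIS:HIP"``, ``"CYS:disulfide"`` etc.
    """

    residues: dict[str, ResidueTemplate] = field(default_factory=_build_library)

    def get(self, name: str, variant: str = "default") -> ResidueTemplate:
        key = name if variant in ("default", None) else f"{name}:{variant}"
        try:
            return self.residues[key]
        except KeyError:
            raise KeyError(
                f"unknown residue {name!r} (variant {variant!r}) in topology"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.residues


_DEFAULT: TopologyLibrary | None = None


def default_topology() -> TopologyLibrary:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = TopologyLibrary()
    return _DEFAULT


def dump_json(lib: TopologyLibrary, path) -> None:
    """Export the library to the documented JSON schema.

    Schema: ``{residue_key: {"name", "variant", "chis", "ring_bonds",
    "atoms": [{"name","element","charge","formal_charge","ionized","refs",
    "bond","angle","tors"}]}}``.
    """
    doc = {}
    for key, res in lib.residues.items():
        doc[key] = {
            "name": res.name,
            "variant": res.variant,
            "chis": list(res.chis),
            "ring_bonds": [list(b) for b in res.ring_bonds],
            "atoms": [
                {
                    "name": a.name, "element": a.element, "charge": a.charge,
                    "formal_charge": a.formal_charge, "ionized": a.ionized,
                    "refs": list(a.refs) if a.refs else None,
                    "bond": a.bond, "angle": a.angle, "tors": list(a.tors),
                }
                for a in res.atoms
            ],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_json(path) -> TopologyLibrary:
    with open(path) as fh:
        doc = json.load(fh)
    residues = {}
    for key, rd in doc.items():
        atoms = tuple(
            AtomTemplate(
                ad["name"], ad["element"], ad["charge"],
                formal_charge=ad["formal_charge"], ionized=ad["ionized"],
                refs=tuple(ad["refs"]) if ad["refs"] else None,
                bond=ad["bond"], angle=ad["angle"], tors=tuple(ad["tors"]),
            )
            for ad in rd["atoms"]
        )
        residues[key] = ResidueTemplate(
            rd["name"], atoms, chis=tuple(rd["chis"]),
            ring_bonds=tuple(tuple(b) for b in rd["ring_bonds"]),
            variant=rd["variant"],
        )
    return TopologyLibrary(residues)
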