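"""Default stage profiles: which groups are steered, pinned, or free.

The pipeline stages are group-generic; this module binds them to concrete
segment layouts.  For the toy channel the assignment mirrors the full
steering protocol:

* steered pore-domain group: the inner (S6-like) helices, targeted at their
  C-alpha atoms;
* free groups: the AID-like helix and the sensor (S0-like) helix -- no pins,
  so their displacements are observables;
* bedplate group: the beta-plate rails, pinned with penalty-free half-width
  2.5 A;
* non-steered sensor group: the outer (S5-like) helices, pinned with
  half-width 2.0 A;
* helix-preservation H-bond restraints on the outer helices, 5-degree
  backbone torsion windows on the AID helix and the cytoplasmic parts of
  the inner helices;
* the optional sensor-AID anchor (arginine-glutamine distance window) and
  the 9 A cap on AID / bedplate backbone separation, plus the covalent-
  linker stand-in tying AID to the repeat-1 inner helix.
"""

from __future__ import annotations

import numpy as np

from .pipeline import TransformOptions
from .synthetic import ToyChannelSpec

__all__ = ["toy_transform_options", "toy_transform_flexibility"]


def toy_transform_options(system, spec: ToyChannelSpec = ToyChannelSpec(),
                          anchored: bool = True, n_stages: int = 5,
                          aid_cap: float = 9.0) -> TransformOptions:
    """Steering restraint layout for the toy channel."""
    n = spec.n_repeats
    targeted = [(f"S6.{r + 1}", i, "CA")
                for r in range(n) for i in range(1, spec.helix_len + 1)]
    helix_ranges = [(f"S5.{r + 1}", list(range(1, spec.helix_len + 1)))
                    for r in range(n)]
    torsion_windows = (
        [("AID", list(range(1, spec.aid_len + 1)), 5.0)]
        + [(f"S6.{r + 1}", list(range(7, spec.helix_len + 1)), 5.0)
           for r in range(n)])
    pinned = (
        [([("beta1", i) for i in range(1, len(spec.plate_sequence) + 1)]
          + [("beta2", i) for i in range(1, len(spec.plate_sequence) + 1)],
          2.5)]
        + [([(f"S5.{r + 1}", i) for i in range(1, spec.helix_len + 1)], 2.0)
           for r in range(n)])
    anchor = ((("IIS0", 5, "CZ"), ("AID", 6, "OE1"), 4.5)
              if anchored else None)
    # 9 A cap between AID backbone and the nearest bedplate backbone atom
    # (the covalent-linker stand-ins live in synthetic.toy_linker_restraints
    # and are supplied through StageConfig.extra_restraints)
    caps = []
    system.rebuild()
    plate_cas = []
    for seg_id in ("beta1", "beta2"):
        for i in range(1, len(spec.plate_sequence) + 1):
            plate_cas.append((seg_id, i))
    plate_pos = np.array([system.cartesian[system.atom_index(s, i, "CA")]
                          for (s, i) in plate_cas])
    for i in range(1, spec.aid_len + 1):
        p = system.cartesian[system.atom_index("AID", i, "CA")]
        j = int(np.argmin(np.linalg.norm(plate_pos - p, axis=1)))
        caps.append((("AID", i, "CA"),
                     (plate_cas[j][0], plate_cas[j][1], "CA"), aid_cap))
    return TransformOptions(
        targeted=targeted, helix_ranges=helix_ranges,
        torsion_windows=torsion_windows, pinned_groups=pinned,
        anchor_pair=anchor, backbone_caps=caps, n_stages=n_stages)


def toy_transform_flexibility(system, spec: ToyChannelSpec = ToyChannelSpec()):
    """Desk-scale flexibility for the toy transform: the inner helices and
    the free groups move as rigid bodies, the free groups also keep
    sidechain freedom; the pinned scaffold holds its placement."""
    # moving parts: the steered inner helices and the free groups; the
    # pinned scaffold (outer helices, bedplate) keeps its placement -- its
    # pins stay in the restraint dump but the desk-scale profile does not
    # spend coordinates on them
    system.root_flexible[:] = False
    for seg in system.segments:
        if seg.id in {"AID", "IIS0"} or seg.id.startswith("S6."):
            system.root_flexible[seg.index] = True
    # gate-forming residues are glycine/alanine, so the inner helices move
    # as rigid bodies; only the free groups keep sidechain freedom
    flex_segments = {"AID", "IIS0"}
    for i, v in enumerate(system.torsion_vars):
        seg = system.segments[v.seg_index].id
        system.torsion_flexible[i] = (v.kind == "chi"
                                      and seg in flex_segments)
    return system
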