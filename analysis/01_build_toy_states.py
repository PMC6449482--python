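"""Build the toy channel in its open and closed gate states.

Generates the paired conformations, verifies the designed geometry (gate
C-alpha ring radii, state-independent scaffold, axial AID displacement) and
writes PDB files plus the atom correspondence table under results/.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mcgate.io import atomic_write_text, write_pdb
from mcgate.synthetic import ToyChannelSpec, generate_toy_channel

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    spec = ToyChannelSpec()
    systems = {s: generate_toy_channel(spec, s) for s in ("open", "closed")}
    os.makedirs(OUT, exist_ok=True)

    lines = ["state\trepeat\tgate_ca_radius_A"]
    for state, system in systems.items():
        write_pdb(system, os.path.join(OUT, f"toy_{state}.pdb"))
        for r in range(spec.n_repeats):
            ca = system.cartesian[system.atom_index(
                f"S6.{r + 1}", spec.helix_len, "CA")]
            lines.append(f"{state}\t{r + 1}\t{np.hypot(ca[0], ca[1]):.3f}")
    atomic_write_text(os.path.join(OUT, "01_gate_radii.tsv"),
                      "\n".join(lines) + "\n")

    # correspondence: same topology, identity atom mapping; report the
    # per-segment displacement between states
    so, sc = systems["open"], systems["closed"]
    rows = ["segment\tmean_displacement_A\tmax_displacement_A"]
    for seg in so.segments:
        d = np.linalg.norm(sc.cartesian[seg.atom_slice]
                           - so.cartesian[seg.atom_slice], axis=1)
        rows.append(f"{seg.id}\t{d.mean():.3f}\t{d.max():.3f}")
    atomic_write_text(os.path.join(OUT, "01_state_displacements.tsv"),
                      "\n".join(rows) + "\n")
    sl = so.segment("AID").atom_slice
    disp = (sc.cartesian[sl] - so.cartesian[sl]).mean(axis=0)
    print("gate radii written; AID inter-state displacement "
          f"{np.round(disp, 2)} A (|d| = {np.linalg.norm(disp):.2f}): the "
          "closed-state AID sits one axial step further along its groove.")


if __name__ == "__main__":
    main()
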