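"""Thread a mismatched toy sequence over the toy template and refine it.

Runs the three-trajectory refinement protocol (sidechains only; everything
flexible under 1 A C-alpha pins; unpinned stability) at reduced desk-scale
convergence windows and reports the final C-alpha RMSD to the template.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mcgate.io import atomic_write_text, write_pdb
from mcgate.mcm import EnergyModel, MCMConfig, local_minimize
from mcgate.energy import NonbondedOptions
from mcgate.pipeline import StageConfig, stage_homology
from mcgate.synthetic import (ToyChannelSpec, generate_mismatched_sequence,
                              toy_linker_restraints)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    spec = ToyChannelSpec(n_repeats=2, helix_len=8, aid_len=8)
    template, model_specs, tmap = generate_mismatched_sequence(
        spec, n_substitutions=4, seed=11)
    linker = toy_linker_restraints(spec)
    # settle the analytic template into a self-consistent minimum first
    local_minimize(EnergyModel(template, NonbondedOptions(), linker),
                   max_iter=200)
    cfg = StageConfig(mcm=MCMConfig(max_min_iterations=40,
                                    convergence_window=4,
                                    max_minimizations=8, rng_seed=0),
                      extra_restraints=linker)
    model = stage_homology(template, tmap, model_specs, cfg)

    os.makedirs(OUT, exist_ok=True)
    write_pdb(model.system, os.path.join(OUT, "02_refined_model.pdb"))
    rows = ["trajectory\tlowest_energy_kcal\tn_minimizations\tconverged"]
    for t in model.provenance["trajectories"]:
        rows.append(f"{t['trajectory']}\t{t['energy']:.2f}"
                    f"\t{t['n_minimizations']}\t{t['converged']}")
    rows.append(f"ca_rmsd_to_template_A\t"
                f"{model.provenance['ca_rmsd_to_template']:.3f}")
    atomic_write_text(os.path.join(OUT, "02_refinement.tsv"),
                      "\n".join(rows) + "\n")
    print(f"{len(tmap.mismatched)} mismatched residues threaded all-trans; "
          f"final C-alpha RMSD to template "
          f"{model.provenance['ca_rmsd_to_template']:.3f} A "
          "(the reduced protocol keeps the fold on the template).")


if __name__ == "__main__":
    main()
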