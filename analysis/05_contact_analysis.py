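"""State-dependent contact analysis of the toy open/closed pair, plus the
printed-table aggregation.

Computes AID/sensor and AID/bedplate contact maps in both gate states,
bins them with the two printed schemes, classifies contacts as shared or
state-specific, and aggregates the shipped transcription of the printed
mutant contact-energy table (including its annotated sum discrepancy).
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mcgate.contacts import (FIG3_SCHEME, aggregate_net_energy,
                             bin_contacts, compare_states, contact_map)
from mcgate.io import atomic_write_text
from mcgate.synthetic import ToyChannelSpec, generate_toy_channel, \
    table_fixture

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    spec = ToyChannelSpec()
    systems = {s: generate_toy_channel(spec, s) for s in ("open", "closed")}
    os.makedirs(OUT, exist_ok=True)

    for pair_name, ga, gb in (("AID_sensor", ["AID"], ["IIS0"]),
                              ("AID_plate", ["AID"], ["beta1", "beta2"])):
        maps = {}
        rows = ["state\tres_a\tres_b\tE_total\ttypes\tbin"]
        for state, system in systems.items():
            records = contact_map(system, ga, gb, state_label=state)
            bin_contacts(records, FIG3_SCHEME)
            maps[state] = records
            for r in records:
                rows.append(f"{state}\t{r.residue_a[0]}:{r.residue_a[1]}"
                            f"\t{r.residue_b[0]}:{r.residue_b[1]}"
                            f"\t{r.energy:.2f}"
                            f"\t{','.join(sorted(r.types))}\t{r.bin_label}")
        comp = compare_states(maps)
        shared = sum(1 for c in comp.classification.values()
                     if c == "shared-all")
        only = len(comp.classification) - shared
        rows.append(f"# {shared} shared contacts, {only} state-specific")
        atomic_write_text(os.path.join(OUT, f"05_contacts_{pair_name}.tsv"),
                          "\n".join(rows) + "\n")
        print(f"{pair_name}: {shared} shared / {only} state-specific "
              "contacts")

    t4 = table_fixture("table4")
    rows = ["mutant\tstate\tnet_contact_energy_kcal"]
    for mutant in ("G402S", "G406R"):
        for state in ("closed", "open"):
            rows.append(f"{mutant}\t{state}\t"
                        f"{aggregate_net_energy(t4, mutant, state):.2f}")
    rows.append("# printed SUM row: " + "\t".join(
        str(t4.sum_row[c]) for c in ("G402S_c", "G402S_o", "G406R_c",
                                     "G406R_o")))
    for note in t4.annotations:
        rows.append("# " + note)
    atomic_write_text(os.path.join(OUT, "05_table4_aggregation.tsv"),
                      "\n".join(rows) + "\n")
    print("printed-table net contact energies aggregated "
          "(G402S: closed -0.75 / open -2.72; G406R: closed -0.81 / "
          "open sums to -4.89 vs printed -4.98, annotated).")


if __name__ == "__main__":
    main()
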