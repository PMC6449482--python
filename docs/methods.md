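# Methods

`mcgate` models conformational transitions of P-loop ion channels — the
pore-forming module of voltage-gated calcium and sodium channels — by
energy minimization in internal (generalized) coordinates, the approach
used for homology modeling and state-transformation studies of Cav
channels.  This note records the model, its assumptions, the tunable
parameters, the synthetic test world, and the numerical choices.

## Molecular model

A system is a set of covalent *segments* (helices, strands, subunit
fragments), each an atom tree rooted at the N-terminal nitrogen of its
first residue.  The generalized coordinates are:

* torsion angles (backbone φ/ψ/ω and sidechain χ), radians internally and
  degrees at every I/O surface;
* the Cartesian position of each segment's root atom;
* the Euler-angle orientation (intrinsic z-y-x) of each segment's first
  three-atom frame.

Bond lengths and bond angles are rigid, except that prolines and
vicinal-disulfide cysteines are flagged with flexible bond angles (their
placement angles become additional coordinates).  Aromatic rings are
rigid: rings are built as closed planar polygons in the atom tree
(pentagons and hexagons close exactly; the tryptophan fused ring is a
rigid approximation).  Cartesian coordinates are a pure function of the
generalized coordinates: each segment is built once in a canonical frame
by sequential atom placement (NeRF) and mapped by the rigid root
transform, so rebuilding is bit-stable and root translations are exact.

The residue library is a self-consistent united-atom table in the AMBER
lineage: polar hydrogens explicit, nonpolar hydrogens united into their
heavy atoms; per-element Lennard-Jones classes; partial charges that sum
to each variant's formal charge.  Histidine ships in three tautomers (H on
N-δ1, on N-ε2, doubly protonated), cysteine in reduced and disulfide
forms.  The historical AMBER parameter tables are *not* reproduced value
for value — every check in this package is an oracle or property check,
not an absolute-energy comparison — and the library is exportable to a
documented JSON schema.

## Energy

Nonbonded energy is Lennard-Jones 6–12 (r_min combination arithmetic,
well-depth geometric) plus Coulomb with a distance-dependent dielectric
ε(r) = 4r, i.e. `E_C = 332.06 q_i q_j / (4 r²)` kcal/mol.  Pairs are
truncated at 9 Å with a shifting function; pairs in which both atoms
belong to ionized groups (Arg/Lys/His⁺ head groups, Asp/Glu carboxylates)
are computed without any cutoff.  1-2 and 1-3 bonded pairs are excluded,
1-4 pairs scaled by 0.5.  Two shift modes exist: `shifted_force` (default;
energy *and* radial derivative vanish at the cutoff, which the quasi-Newton
minimizer needs) and `shifted_energy`.  The published protocol this
package follows cites an environment-dependent dielectric and a specific
shifting function that are not specified in the source; ε(r) = slope·r
with a configurable slope and the two shift modes above are this package's
documented stand-ins.  Contact-energy *reporting* is computed without a
cutoff so tables do not depend on the truncation radius.

Totals decompose exactly per residue pair (to 1e-8 relative), which is
what the contact analysis consumes.

## Restraints

All restraints share one functional form, the flat-bottom parabola: zero
penalty inside a tolerance window, `k·(deviation − width)²` outside,
continuous at the boundary.

| restraint | window | default k |
|---|---|---|
| Cα pin to a template position | d = 1 Å (bedplate 2.5 Å, non-steered sensors 2 Å) | 10 kcal mol⁻¹ Å⁻² |
| distance restraint (lower/upper) | per use | 10 kcal mol⁻¹ Å⁻² |
| backbone torsion window | ±5° around the current model value | 0.1 kcal mol⁻¹ deg⁻² |
| helical H-bond O(i)–N(i+4) | 3.0 ± 0.3 Å | 10 kcal mol⁻¹ Å⁻² |

The torsion-window k and the helix H-bond target/width are this package's
choices (the source protocol states only the 5° window and "alpha-helical
H-bonds").  Distance restraints are deliberately the same device as pins
applied to interatomic distances.

## Monte Carlo minimization

One MCM cycle: perturb a single randomly chosen flexible coordinate
(torsions resample uniformly in (−180°, 180°]; root positions take
Gaussian steps of σ = 0.5 Å, root orientations σ = 10°, flexible bond
angles σ = 5°), locally minimize the total energy, and Metropolis-accept
the minimized point against the current minimized point at T = 600 K (the
temperature is a conventional conformational-search choice; the source
does not state one).  A trajectory terminates when 2000 consecutive
minimizations fail to lower the lowest energy found; the first
minimization establishes the running lowest and does not count toward the
window.  Acceptance compares candidate-minimum against current-minimum
energy (an interpretation; the alternative — proposal vs. current —
is not distinguishable from the source).

The local minimizer is L-BFGS-B over the flexible coordinates with
analytic gradients: nonbonded and restraint forces are projected onto each
torsion's rotation axis (`dE/dθ = Σ F·(û × r)` over the downstream atoms);
root translations are exact force sums; root-orientation gradients use
matrix-level central differences of the Euler rotation.  The contract is
behavioral — monotone, iteration-capped — not algorithm-prescriptive.

**Steered MCM** walks the anchors of target pins linearly from start to
end positions over a number of stages (default 10; the source says only
"stepwise").  During steering each minimization is capped at 100
iterations so consecutive accepted points stay close; a stage ends after
50 accepted points or 500 proposals (a package choice).  After the last
stage the trajectory runs at the end anchors to the convergence window,
then an unconstrained stability trajectory runs and its Cα drift is
reported (no hard threshold — the protocol only asks that the model be
energetically stable).

## Pipeline stages

**Homology build.**  The model sequence is threaded over the template by
copying measured torsions and root frames; alignment-mismatched residues
start with all-trans sidechains.  Three consecutive MCM trajectories: (1)
sidechain torsions only; (2) all coordinates with d = 1 Å Cα pins; (3)
unpinned.  The final Cα RMSD to the template is reported.  Trajectory 2
pins every modeled Cα (whether the source pinned only the α1 subunit is
not stated).

**State transformation.**  Target pins steer the pore-domain helix Cα
atoms to their positions in the target-state structure; companions:
helix H-bond restraints on the outer helices, 5° torsion windows on the
AID helix and the cytoplasmic parts of the inner helices (referenced to
the *current* model values), pins on the bedplate (2.5 Å) and non-steered
sensors (2 Å), no restraints on the designated free groups, an optional
anchor distance restraint between one sensor/AID residue pair, and a 9 Å
cap on AID/bedplate backbone separation.  Dropping the anchor gives the
unbiased deactivation variant.  Every active restraint appears in an
auditable dump in the stage provenance.

**Double-shell mutants.**  Residues with a heavy atom within 15 Å of the
mutated residue form the flexible shell; those within 20 Å (and not
flexible) form the rigid shell, held bit-frozen; everything else is
excluded from the energy entirely (the rigid shell prevents the flexible
shell from drifting into space the full model occupies).  Flexible-shell
*sidechain* torsions are randomized uniformly into 128 starting
conformations and each start is energy-minimized; backbone randomization
of a 15 Å shell without the full model's guidance is unphysical, so it is
off by default and available as a flag (`randomize="all"`).  The ensemble
reports the apparent global minimum and the members within 7 kcal/mol
of it.

## The synthetic toy channel

The generator emits a pseudo-4-fold bundle in two analytically
constructed conformations with identical topology (atom correspondence is
the identity):

* four repeats of an outer (S5-like, poly-Ala) and inner (S6-like,
  glycine-hinged) helix, 12 residues each; the inner-helix terminal Cα
  atoms land exactly on a gate ring of radius 6.0 Å (open) or 2.5 Å
  (closed), tangentially staggered so the bundle crosses side-by-side;
  the gate-ring height is state-independent, so gate motion is purely
  radial;
* an amphipathic 12-residue AID-like helix (Leu face down, E/Q/K face up,
  Gln-6 the engineered H-bond acceptor) whose axis is aligned with the
  repeat-1 gate direction and which rests in a groove formed by two
  Leu/Ser strand rails (the beta-plate); in the closed state the AID sits
  3.5 Å further along its own axis;
* a short sensor helix (S0-like) crossing above the AID polar face whose
  arginine (R5) reaches toward Gln-6 — the stand-in for the sensor–AID
  hydrogen bond.

Two connectivity stand-ins are part of the toy world (the toy does not
model the linkers explicitly): a flat-bottom distance window (≤ 6.8 Å)
tying the AID N-terminus to the repeat-1 inner-helix C-end, and a
two-sided band (13–15.5 Å) tying the sensor helix C-end to the outer
scaffold, standing in for the covalent continuation of S0 into the
membrane-embedded sensor body.  Sidechain rotamers of a handful of
interface residues are set once, by a deterministic clash search over the
two states, so the analytic templates pack without hard overlap; residual
strain (~10³ kcal/mol, localized at designed contacts) relaxes in the
first minimization, mirroring a raw homology start.

What the toy does *not* emulate: membrane and solvent, realistic channel
sequences, P-loops and selectivity filter, the full sensor domains, or
absolute energetics.  A green toy-scale test establishes that the
*machinery* (threading, steering, shells, contact analysis) behaves per
its contracts — not that any full-scale structural prediction is correct.

## Desk-scale (reduced) protocol settings

The full protocol values (2000-minimization window, 100-iteration steered
cap, 128 starts, 10 stages) are the library defaults.  Tests and analysis
scripts run a documented reduced profile on one CPU: 5 steering stages,
3 accepted points / 5 proposals per stage, a 60-iteration minimizer cap
during steering, convergence window 6, 16 mutant starts, and flexibility
restricted to the moving parts (inner-helix/AID/sensor rigid-body
coordinates plus free-group sidechains; the pinned scaffold keeps its
placement, its pins remaining in the audit dump).  Steered-transform
checks start from a briefly minimized open model — transforms operate on
refined models in the pipeline, and the analytic template would otherwise
first "settle" into its groove during steering and obscure the drag
signal being measured.

## Numerical choices and degenerate inputs

* Angles wrap to (−π, π]; torsion-window deviations wrap mod 360°.
* The minimizer result is discarded if it fails to lower the energy
  (minimization is monotone by contract).
* Superposition is a Kabsch-type SVD fit (backed by Biopython's
  `SVDSuperimposer`) with a reflection guard; degenerate (collinear or
  < 3-point) selections are rejected.
* Contact typing: H-bond = donor-heavy–acceptor ≤ 3.5 Å with D–H…A
  ≥ 120°; salt bridge = opposite net formal charges with any N/O–N/O pair
  ≤ 4.0 Å; hydrophobic = neither, with |LJ| ≥ |Coulomb|; repulsive ⇔
  E > 0.  H-bond energetics arise from LJ + Coulomb only (no dedicated
  10–12 term); geometry is used for *detection* only.
* Printed bin boundaries ("−0.9 to −1.5", "−1.51 to −3.0", …) are taken
  as two-decimal half-open intervals, thresholds configurable.
* The universal-label map is anchored by worked label/residue pairs;
  positions without an in-text anchor are flagged `provisional` in the
  shipped TSV, and one self-inconsistent printed label is resolved in
  favor of the consistent assignment (documented in the file header).

## Known limitations

* The dielectric is distance-dependent only; the environment-dependent
  component of the cited function is not reproduced.
* Proline and tryptophan ring-closure geometry is approximate (rigid
  trees, no closure constraint beyond the exclusion bond).
* The toy channel's closed gate is geometrically tight; steering into it
  is resisted by the LJ wall, so targeted atoms satisfy their anchors to
  the restraint window, not exactly.
* Full-scale inputs (cryo-EM/X-ray templates, real channel sequences) are
  accepted by the same interfaces (PDB reader, alignment maps) but
  reproducing published full-size models requires cluster-scale sampling
  and is out of scope for the test surface.
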