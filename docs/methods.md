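# Methods

## Contact model

A protein–ligand atomic contact exists when the minimum heavy-atom
distance between a residue and the ligand is strictly below the
ligand-contact cutoff (default 5.5 Å, roughly two carbon van der Waals
radii plus a water diameter). Hydrogens are ignored everywhere: the
models this package evaluates are heavy-atom homology models, and
protonation-dependent chemistry enters through the ligand descriptor
flags and residue templates instead.

The distance rule alone over-predicts, so a contact is *chemically
valid* only if it realizes at least one classical interaction. What
would otherwise be a visual-inspection step is codified as four
deterministic geometric rules, each with its own cutoff (all
configurable through `ContactThresholds`):

| interaction | rule | default |
|---|---|---|
| hydrogen bond | side-chain donor/acceptor N or O vs. complementary ligand atom | < 3.5 Å |
| salt bridge | charged side-chain group atom vs. oppositely charged ligand atom | < 4.0 Å |
| aromatic stacking | residue ring centroid vs. ligand ring centroid | < 5.0 Å |
| hydrophobic | apolar side-chain carbon vs. apolar ligand carbon | < 4.5 Å |

Backbone N/O atoms never contribute hydrogen bonds — the rules describe
side-chain chemistry, and backbone-only polar proximity is deliberately
not a predicted interaction. Residue chemistry (donors, acceptors,
charged groups, ring atoms, apolar carbons) comes from fixed per-residue
templates; an apolar carbon is a side-chain carbon not bonded to N or O
in the template. Histidine is neutral by default and becomes a cation
only under an explicit protonation flag. Ligand chemistry is always
declared in a per-atom descriptor file (charge, ring membership,
donor/acceptor, apolar flags): perceiving bonds from docked heavy-atom
geometry is ambiguous, declaring them is not.

Residue–residue contact maps use the van der Waals sum criterion over
side-chain heavy atoms only: a pair is in contact when some atom pair is
closer than r(a) + r(b) + tolerance. The radii are a Bondi-style table
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å), replaceable by file.
The practical form of the criterion in the structural-analysis
literature carries a tolerance; the default is 0.6 Å, and setting it to
0 recovers the literal "shorter than the sum of the radii" rule. Pairs
closer than 4 positions in sequence are excluded (trivially contacting
neighbours carry no activation signal); glycine, having no side chain,
participates in no pairs.

## Generic numbering

Residues are labelled helix.offset with the most conserved position of
each TM helix fixed at X.50, so that 7.52 names the same structural
position in every receptor. Numbers are projected from an annotated
template (TM spans + anchor indices) onto a target through a supplied
alignment: offset = 50 + signed distance from the anchor, counted in
reference positions. The full GPCRdb bulge/constriction adjustments are
not implemented — numbers are plain template-projected offsets, which is
also how template-based models inherit their numbering in practice.
Alignment computation is out of scope; alignments are inputs. A target
gapped at a helix anchor leaves that helix unmapped (reported, not
guessed); offsets falling outside 1–99 leave the residue unmapped rather
than clamped.

## Evaluation against mutagenesis

Tested residues are deduplicated to one effect class each; a residue
with both affecting and non-affecting mutations counts as affecting
(worst-case collapse). When a record carries only an EC50 fold change,
a configurable threshold (default ≥ 2-fold, or "abolished") classes it.
Only residues in the extracellular half of the bundle enter the
confusion matrix, because that is where the class A orthosteric site
lies; the half-split projects Cα positions onto the bundle's first
principal axis, oriented so the N-terminal end of TM1 (extracellular by
class A topology) is positive, with the centroid as the boundary (ties
included).

The confusion matrix is defined over *experimentally tested* residues
only: FP counts tested no-effect residues that the model predicts, and
the predictive-power denominator is the number of tested residues.
Contacted-but-untested residues are listed separately and never enter
the counts — the alternative (counting them as FP) would punish models
for predictions no experiment has probed. Precision and recall use the
0/0 → 0 convention. Metrics are kept at full precision internally and
rounded half-away-from-zero to two decimals only for display.

## Activation rewiring

For each receptor with an active and an inactive structure, both contact
maps are built and diffed after mapping residues to generic positions;
pairs involving unmapped residues are dropped and counted. A generic
pair is reported when it changes (gained or lost) in at least
`min_support` receptor pairs; the default of 3 asks for a majority of a
typical five-receptor panel. Reported positions are ranked by the number
of rewired pairs that involve them, restricted to positions whose
(class-level) conservation meets a threshold — default 70%, with residue
classes such as branched-aliphatic V/L/I shipped as configuration. State
labels are taken from the input manifest as given; the package does not
second-guess them.

## Synthetic data generator

The generator emulates the pipeline's study conditions, not membrane
physics. Receptors are seven idealized helices (24 residues each,
1.5 Å rise, 100° turn, 2.3 Å local radius) on a 12 Å circle, alternating
direction so TM1's N-terminus is extracellular; side chains are 1–3
pseudo-atoms with correct element types, enough for every distance and
chemistry rule to engage exactly as planted. The ligand sits on the
bundle axis in the extracellular half with one atom per interaction
class (a quaternary cation, an acceptor-only oxygen, one six-carbon
ring, two apolar carbons).

Planted contact residues are placed to satisfy exactly one interaction
rule at 0.3 Å inside its cutoff; decoys and all other residues stay at
least 0.5 Å outside the 5.5 Å contact cutoff. These margins dominate the
10⁻³ Å coordinate round-off of the PDB format, so parse/write
round-trips cannot flip any rule. Every generator verifies its own
planted truth by brute force before returning and raises on any
violation — there are no silently bad fixtures. Two deliberate
constraints keep labels exact: the ligand hydroxyl is acceptor-only (a
donor oxygen would hand acidic side chains an unplanted hydrogen bond
when helix azimuths are adjacent), and at most one aromatic-stacking
contact can be planted (a second partner for the single ligand ring
would sweep within hydrophobic range of the apolar ligand carbons, since
phenylalanine ring carbons are genuinely apolar).

Mutagenesis tables realize a requested (TP, FP, TN, FN) exactly by
assigning effect classes to planted-contact and decoy residues (all in
the top half), with fold changes drawn consistently with the effect
class. Family alignments plant per-column residue frequencies with exact
deterministic allocation (round(freq·n) rows, assignment shuffled by
seed); the reference row always carries the template sequence.
Gap-defective rows receive gaps in a set fraction of TM columns;
motif-defective rows receive gaps at the anchor columns, so they fail
conserved-feature scans while staying under the gap threshold.
Active/inactive pairs start from the bare bundle and flip listed generic
pairs by rebuilding their side chains as carbon chains meeting 0.6 Å
inside the carbon–carbon vdW cutoff; applying the toggle twice restores
the original coordinates exactly. A sampler pre-screens candidate pairs
(adjacent helices, matched z level, an analytic clearance check against
all third-party side chains) so that planted rewirings never create
spurious contacts; the generator independently re-verifies by diffing
full contact maps.

Every generator is a pure function of (seed, parameters): identical
seeds give byte-identical files.

## What passing tests do and do not show

The synthetic bench demonstrates that the rules, metrics and aggregation
are implemented exactly as specified: planted truths are recovered with
zero error across seeds, and all contact computations match exhaustive
brute-force oracles. It does not demonstrate accuracy on real docked
models — real side chains have rotameric ambiguity, real ligands have
tautomers and partial charges, real mutagenesis mixes binding and
transduction effects, and real alignments have loop regions the
numbering module does not cover. The generator's geometry is schematic
by design; margins, not realism, are what make the ground truth exact.

## Numerical and degenerate-input choices

Cutoffs are strict inequalities throughout, so boundary atoms (e.g. at
exactly 5.5 Å) are out-of-contact. Distance ties at the top-half
boundary are included. The bundle axis accepts collinear Cα sets (the
principal direction of a line is exact) and rejects only coincident
points. Altloc handling keeps the highest-occupancy conformer, ties
resolved toward conformer A. Waters are dropped at parse time; unknown
elements fall back to the first letter of the atom name with a logged
warning. Empty selections (glycine under a side-chain filter) raise a
dedicated error rather than returning an infinite distance.

## Problem sizes

The shipped test-suite and acceptance benchmarks use 168-residue
bundles, 25-row alignments, 50 complexes for oracle equivalence, 100
confusion-matrix scenarios, and 20 state pairs with 1–5 rewired
contacts each — sizes chosen so exhaustive brute-force verification of
every instance stays routine on a single CPU.
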