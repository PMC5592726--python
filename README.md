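# gpcreval

Evaluation toolkit for structural models of chemosensory GPCR–agonist
complexes.

Bitter taste receptors (hTAS2Rs) and odorant receptors (hORs) have no
experimental structures, so their agonist complexes are studied through
homology models plus docking. The only systematic way to judge such a
model is to compare it with site-directed mutagenesis: residues whose
mutation shifts the agonist's EC50 should be in contact with the ligand
in a good model, and residues with no EC50 shift should not.
`gpcreval` implements that comparison as a reusable, tested pipeline,
together with an activation analysis that looks for conserved generic
positions whose side-chain contact network differs between active and
inactive receptor states.

## What it computes

**Ligand contacts.** A receptor residue is in atomic contact with the
ligand when any heavy-atom pair lies below 5.5 Å. A contact counts as
*predicted* only if it also realizes a classical chemical interaction —
hydrogen bond (donor/acceptor N/O pairs < 3.5 Å), salt bridge
(opposite charges < 4.0 Å), aromatic stacking (ring centroids < 5.0 Å)
or hydrophobic contact (apolar carbons < 4.5 Å). Ligand chemistry is
declared in a small per-atom descriptor file, never perceived from
geometry.

**Evaluation against mutagenesis.** Over experimentally tested residues
in the extracellular ("top") half of the bundle — the location of the
canonical class A orthosteric site:

    TP: EC50-affecting and predicted       FN: EC50-affecting, not predicted
    FP: no-effect yet predicted            TN: no-effect, not predicted

    PREC = TP / (TP + FP)
    REC  = TP / (TP + FN)
    predictive power = (TP + TN) * 100 / (tested residues in the top half)

**Activation rewiring.** For receptors with both active and inactive
structures, side-chain contact maps (atom pairs closer than the sum of
their van der Waals radii, backbone excluded) are diffed in
generic-number space (GPCRdb-style helix.offset labels such as 7.52) and
aggregated across receptors; positions are ranked by how many rewired
pairs involve them, restricted to positions conserved in a family
alignment.

**Conservation and curation.** Per-position conservation percentages
over family MSAs, conserved-motif scanning (N1.50, D[E]RY, NPxxY and the
hTAS2R/hOR variants), and the curation filter that discards rows with
large TM gaps or missing conserved features.

**Synthetic data.** Seeded generators emit every input the pipeline
consumes — 7-helix bundles with a bound ligand and planted contact
labels, mutagenesis tables with planted (TP, FP, TN, FN), alignments with
exact planted column frequencies, and active/inactive pairs with planted
rewired contacts — so the whole pipeline is testable end to end without
any downloads.

## Worked example

```sh
gpcreval simulate --seed 1 --outdir scen \
    --contacts "hbond=1,salt_bridge=1,hydrophobic=1" --decoys 6 --intended 2,1,2,0
gpcreval contacts --pdb scen/complex.pdb --descriptor scen/ligand.tsv \
    --numbering synth --out contacts.tsv
gpcreval evaluate --pdb scen/complex.pdb --contacts contacts.tsv \
    --mutagenesis scen/mutagenesis.tsv --out eval.json
```

The last step prints

```
INFO gpcreval: TP=2 FP=1 TN=2 FN=0 prec=0.67 rec=1.00 power=80.0%
```

meaning: of the five tested residues in the top half, both
EC50-affecting residues were predicted as chemically valid contacts
(recall 1.00), one no-effect residue was also predicted (precision
2/3), and 4 of 5 residues were classified correctly (predictive power
80%). `eval.json` carries the full per-residue ledger plus contacted
residues that were never tested (reported separately, never counted).

The same executable drives the other stages: `numbering` projects
generic numbers through an alignment, `conserve`/`curate` query and
filter family MSAs, `rewire` aggregates active/inactive contact-map
differences from a manifest of structure pairs, and `report` pools
per-complex evaluations.

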