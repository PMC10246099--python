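# Methods

## Hydrogen-bond model

A hydrogen bond is accepted when three geometric criteria hold
simultaneously: both heteroatoms are O or N; the heavy-atom
(donor-to-acceptor) distance satisfies 2.3 Å ≤ R ≤ 3.2 Å; and the
donor–H–acceptor angle θ is at least 135°, taking the maximum over the
donor's hydrogens (relevant for NH₂/NH₃⁺ groups). Bonds are classed by
distance alone: short (SHB) for R ≤ 2.7 Å, normal (NHB) for R ≥ 2.8 Å. Both
window boundaries are inclusive. The open interval (2.7, 2.8) Å belongs to
neither class; such bonds are labeled `INTERMEDIATE` and excluded from
training datasets, since forcing them into either class would blur the very
boundary the classifier is asked to learn.

Only side-chain sites of the 11 polar residues participate on the protein
side (Ser OG, Thr OG1, Tyr OH, Asp OD1/OD2, Glu OE1/OE2, Asn OD1/ND2,
Gln OE1/NE2, His ND1/NE2, Lys NZ, Arg NE/NH1/NH2, Trp NE1); backbone amides
and carbonyls are excluded. Every ligand O/N atom is a candidate site, with
donor capability read from its attached hydrogens and acceptor capability
from element and hydrogen count (a nitrogen with no hydrogen is treated as a
lone-pair acceptor). Bonds within one residue or one ligand, between two
ligands, and through crystal symmetry are not considered; neither are
C–H···O contacts, halogen bonds, water bridges or metal coordination.

When both partners of a contact could donate (hydroxyl–hydroxyl), the
direction with the larger θ is taken as the donor; an exact tie goes to the
protein side. His is modeled neutral with the NE2–H tautomer (ND1 accepts,
NE2 donates); Asp/Glu carboxylates are deprotonated and Lys/Arg protonated,
the standard pH-7 states.

### Resolution filter

The atomic-resolution filter keeps structures with resolution ≤ 1.1 Å
(unknown resolution fails conservatively). A 0.1 Å coordinate error — the
best X-ray structures — is already comparable to the width of the SHB/NHB
gap, so looser structures cannot distinguish the classes. Crystallization
additives (glycerol, ethylene glycols, PEG fragments, MPD, sulfate,
phosphate, nitrate, acetate, halides and all single-atom ions) are excluded
from the ligand list by default, since they sit in lattices for crystal
preparation rather than function.

## Idealized hydrogen placement

Deposited X-ray models usually lack hydrogens, so polar hydrogens are
placed at idealized internal coordinates rather than by force-field
minimization: O–H 0.96 Å, N–H 1.01 Å, tetrahedral (109.5°) or trigonal
(120°) angles as the site demands. Rotatable hydroxyls (Ser/Thr/Tyr and
ligand C–OH) are oriented on their ideal cone toward the nearest acceptor
within 3.5 Å, else staggered against the anchor carbon's other substituent.
Lys NZ receives three staggered hydrogens, amide and guanidinium nitrogens
their in-plane hydrogens, ring N–H the in-plane bisector. Existing
hydrogens (neutron structures, pre-protonated models) are never moved, so
placement is idempotent. Terminal ligand oxygens are treated as hydroxyls
only when the C–O distance exceeds 1.32 Å (a shorter bond is a carbonyl);
ligand nitrogens with a single heavy neighbor beyond 1.40 Å get primary-amine
hydrogens, while multiply-connected ligand nitrogens are left as acceptors.
Residues missing the required heavy atoms are skipped with a warning.

## Ligand perception and descriptors

With a CCD dictionary block, atoms, formal charges and bond orders are taken
verbatim. Without one, atoms are bonded when their distance is at most the
covalent-radius sum plus 0.45 Å; aromatic rings are flagged on planar 5/6
cycles with short conjugated bonds; remaining short bonds are promoted to
double, shortest first, within each atom's valence capacity (assuming no
implicit hydrogens, the deposited-structure convention).

The functional group of a site atom is matched most-specific-first:
sulfate > phosphate > carboxylate > carboxyl > ester > amide > phenol >
alkyl hydroxyl > aromatic ring N > alkyl amine > other, so the function is
total on O/N atoms. Carboxyl and carboxylate are distinguished by explicit
charges or by the presence of an acidic hydrogen; without either evidence
the group defaults to the charged pH-7 form. The per-bond "ligand charge"
feature is the formal charge of the participating group, not the whole
molecule; the molecular net charge is kept as metadata.

Descriptors: logP is the Crippen atom-contribution value computed with
RDKit (a crude per-element table is the fallback for unparameterizable
graphs, with a warning); pKa/pKb come from a template lookup on the
ionizable groups present (carboxylic acid ≈ 4, phosphate ≈ 2, sulfate ≈ −3,
phenol ≈ 10; amine conjugate acid ≈ 10.5 and aromatic ring N ≈ 5, reported
as pKb = 14 − pKa(conjugate acid)), taking the strongest acid and strongest
base. Non-ionizable molecules carry the sentinel 99.0, far outside any real
pKa range so tree learners can isolate it. These three descriptors carry
little model weight, so template accuracy suffices.

## The 14-feature vector and the ensemble

Each protein–ligand bond is described by: amino-acid side-chain charge,
residue type and heteroatom element; ligand group charge, functional group,
pKa, pKb and logP; and the six sequence neighbors at offsets −3…+3 of the
hydrogen-bonded residue, with the padding token "—" past chain termini.
Categorical features are encoded as ordinal codes against fixed, versioned
vocabularies (tree learners split natively on levels; models refuse to load
against a different vocabulary version).

Datasets are split 80:20 stratified by class. Training repeats ten times
with member seed = base seed + member index: draw a balanced dataset by
undersampling the NHB majority to the SHB count; select the interaction
depth by 10-fold cross-validated exponential loss over the candidate grid
1–12 (ties to the smaller depth, fold assignment seeded; each member
cross-validates its own balanced dataset); then refit on the entire
balanced dataset with 5000 trees and shrinkage 0.01 under exponential
(AdaBoost-type) loss. Member probabilities come from the boosted margin
through the canonical exponential-loss link 1/(1 + e^(−2F)); the ensemble
probability is their arithmetic mean, classified SHB when ≥ 0.870 (the
recommended operating point; precision- or recall-oriented users can move
it). Feature importances are each member's relative-influence (impurity
reduction) scores normalized to sum 100, averaged across members.

`fast_config()` (500 trees, fixed depth 3) is the reduced-cost setting used
throughout the test suite and the acceptance script; the ensemble pipeline
is identical, only cheaper. Problem sizes used there: feature tables of
1272 SHBs + 2733 NHBs — the observed protein–ligand class imbalance — and
toy complexes of 5–10 planted bonds.

## Synthetic data

The toy-complex generator plants each bond as an isolated geometric test
case on a polyalanine scaffold: one substituted polar donor residue (Ser,
Thr, Tyr or Lys) whose site atom sits at exactly the prescribed R from the
ligand fragment's acceptor atom, with the donor hydrogen solved from the
D–H–A triangle to realize the prescribed θ. Plants are spaced 20 Å apart
(far beyond the 3.2 Å window) and decoy alanines sit ≥ 4 Å away, so the
detectable set is known exactly and recovery can be asserted as set
equality. The generator emits standard PDB text and minimal CCD blocks, so
fixtures exercise the real parsing path. Ligand fragments carry no
hydroxyl hydrogens (the deposited-structure convention), making the planted
residue the unambiguous donor.

The feature-table generator draws labels at a configurable imbalance
(default 1272:2733) and samples residue and functional group from
class-conditional tables ordered like the observed propensities: SHB rows
favor Tyr/Asp/Glu (type A1) and phenol/alkyl-hydroxyl groups (L1/L2), NHB
rows favor Arg/Lys/Asn/Gln/Trp (A3) and ester/amide/amine/ring-N groups
(L4). A `strength` parameter interpolates the tables toward uniform;
strength 0 is an exact null. Charge, heteroatom, pKa, pKb and logP are the
chemistry-determined companions of the sampled categoricals (logP with
Gaussian noise, σ = 0.5); sequence neighbors are uniform noise. The
generating log-likelihood ratio and a Monte-Carlo estimate of its
achievable AUC (≈ 0.98 at full strength) are returned alongside, so
recovery tests compare the trained ensemble against what the generator
admits. What the tables deliberately do not emulate: correlated sequence
context, per-structure bond clustering, label noise from coordinate error,
and the long tail of rare functional groups — so passing recovery tests
demonstrates that the pipeline learns planted chemistry-like signal, not
that real-corpus accuracy is reproduced.

## Numerical choices and edge cases

- Distance-window boundaries inclusive on both sides; R outside
  [2.3, 3.2] Å is a domain error for the classifier.
- Altloc resolution keeps the conformer with the highest mean occupancy,
  ties to the alphabetically first identifier; conformers are never mixed.
- Precision at a threshold with zero predicted positives is reported as a
  missing value, not 0 or 1.
- The precision/recall sweep uses every distinct predicted probability plus
  {0, 1} — the exact step curve, no arbitrary grid.
- AUC is the trapezoidal area under the ROC, equal to the pairwise rank
  statistic with ties counted half.
- Undersampling with more SHBs than NHBs returns the input unchanged with a
  warning (no oversampling).
- All randomness flows from explicit integer seeds: member seeds are
  base + index, CV folds are seeded separately, and generators are
  byte-reproducible for a fixed spec.

## Known limitations

- Hydrogen placement is idealized, not energy-minimized; strained or
  bifurcated donors may get slightly different θ than a force-field
  optimization would produce.
- His protonation/tautomer state is fixed (neutral, NE2–H) rather than
  configurable per site.
- Distance-based bond perception can misassign orders in delocalized
  groups; supplying the CCD block is always preferred.
- Template pKa/pKb ignore substituent effects entirely.
- The released evaluation targets synthetic conditions; no claim is made
  about accuracy on the curated experimental corpus, which is not
  redistributable here.
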