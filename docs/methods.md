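# Methods

`fragforge` implements a fragment-addition pipeline for structure-based lead
optimization: given a protein receptor, a bound ligand, and the atom where a
fragment should be grown, a 3D convolutional network predicts a topological
fingerprint of a suitable fragment, and candidates are retrieved from a
fragment library by fingerprint similarity. This note documents the model,
the defaults, the synthetic data used for testing, and the design choices
made where the design was genuinely open.

## Fragmentation and dataset construction

Every acyclic single bond between heavy atoms of a bound ligand is cut once.
The larger connected component (by heavy-atom count) is the *trimmed
ligand*, kept in its bound pose; the smaller is the *fragment*, carrying a
dummy-atom attachment marker at the cut site. The trimmed-ligand atom of the
cut bond is the *branching atom*. Ties in component size are broken by
molecular weight (the lighter piece is the fragment), then by canonical
SMILES (lexicographically smaller is the fragment) — a cut of ethane
therefore yields a deterministic, if arbitrary, assignment.

Filters, applied in order with the first failure reported:

1. fragment molecular weight above 150 Da (strict inequality; MW is
   computed on the hydrogen-capped fragment, so the open valence counts as
   one hydrogen);
2. fragments with no heavy atom (a bare hydrogen is not a fragment);
3. no fragment heavy atom within 4.0 Å of any receptor heavy atom
   (inclusive cutoff).

All geometry uses heavy atoms only; hydrogens are implicit throughout.

### Property classes

A fragment is **aromatic** if any atom is aromatic after RDKit sanitization,
otherwise **aliphatic** (a strict partition). It is **acidic** if it
contains a carboxylic acid or carboxylate, an aryl O–H or S–H, a P/S atom
double-bonded to oxygen bearing an additional oxygen and an O–H (phosphates,
phosphonates, sulfates, sulfonates), a tetrazole ring, or an S(=O)–N group
(sulfonamides/sulfinamides). It is **basic** if it contains a primary,
secondary or tertiary aliphatic amine — implemented as a non-aromatic sp3
nitrogen whose heavy neighbors are all non-aromatic carbons, none of them
multiply bonded to a heteroatom (this excludes amides and anilines; whether
anilines count as "aliphatic amines" is a judgment call, and the
exclusionary reading follows the usual convention that aryl amines are not
aliphatic) — or an aliphatic nitrogen double-bonded to an atom other than
oxygen or nitrogen (imines, amidines, guanidines). A fragment can be both
acidic and basic; such ambivalent fragments are excluded when assembling
acid- or base-targeted datasets, because they carry no clean supervision
signal for either class.

Size classes split at three heavy atoms: *small* ≤ 3, *large* ≥ 4.

### Fingerprints

Fragment targets are 2048-bit RDKit topological path fingerprints with
maximum path length 10, computed on the capped fragment with the cap
hydrogen kept *explicit*. The explicit cap hydrogen participates in paths,
which keeps single-heavy-atom fragments (methyl, hydroxyl, halogens) from
producing all-zero fingerprints — an all-zero target would make the cosine
training loss undefined, and small fragments dominate real datasets.
Identical fragments give identical bit vectors regardless of atom order or
cut provenance.

## Splits

**Family split.** Entries are grouped by protein-family label and whole
families are assigned to train/validation/test targeting 60/20/20 by entry
count: families are shuffled with a seeded generator (after an internal
sort, so input order is irrelevant) and assigned greedily to the split with
the largest remaining deficit. When counts divide exactly this reproduces
the requested fractions exactly; a single family always lands in train.

**High-priority deduplication.** Ligand identity is canonical isomeric
SMILES string equality (similarity-based deduplication is deliberately out
of scope — identity filtering balances independence against data retention).
In order: validation/test examples without a ligand identity are dropped;
validation/test examples whose ligand occurs in train are dropped; test
examples whose ligand occurs in validation are dropped. The training set
never shrinks, and after deduplication no ligand identity is shared between
any two splits. Entries left with no examples are removed, with every
removal logged as (entry, ligand, split, reason).

**Butina ligand-cluster split** (for fine-tuning datasets, where all
receptors belong to one family and family splitting is impossible). Ligands
are clustered with the Butina leader algorithm on Morgan-fingerprint
(radius 2, 2048 bits) Tanimoto similarity at cutoff 0.4; whole clusters are
assigned 60/20/20 by cluster count with the same greedy-deficit rule.
Ligands are sorted by canonical identity before clustering, which makes the
center-selection tie-break (neighbor count, then identity order)
deterministic and input-order invariant.

## Voxelization

Receptor and trimmed ligand are rendered into a 9-channel 24×24×24 grid
with 0.75 Å spacing centered on the branching atom: receptor C, O, N, S and
other-heavy channels, then ligand C, O, N and other-heavy channels. Each
atom adds `exp(-(d/r)^2)` to grid points within `1.75 r` of its center,
where `r` is the element's Bondi van der Waals radius (unknown elements use
the carbon radius and the catch-all channel); contributions sum across
atoms. The decay function is a pluggable argument, so an alternative
smoothing kernel can be substituted without touching the grid code.

Two conventions worth stating explicitly:

* With 24 points per axis there is no central grid point; grid coordinates
  are `center + (i − 11.5) · 0.75`, placing the branching atom midway
  between the two central planes. An atom exactly at the center therefore
  peaks at the eight innermost points with density
  `exp(-(0.375·√3 / r)²)`, not 1.0.
* Rotation augmentation rotates *coordinates* about the branching atom
  before gridding, never the discretized grid, avoiding resampling
  artifacts. Rotations are uniform on SO(3) (quaternions from seeded
  generators).

## Network and training

The model is a staged 3D CNN in float32: input batch normalization → three
Conv(k3, valid, 64 channels)+ReLU pairs (24³→22³→20³→18³) → max-pool k2 +
batch normalization (→9³) → three more Conv+ReLU pairs (→7³→5³→3³) → global
average pooling (→64) → dropout 0.5 → FC 64→512 → ReLU → dropout 0.5 → FC
512→2048 → sigmoid. The loss is the batch-mean cosine distance between the
continuous prediction and the binary target fingerprint. Optimization uses
Adam, learning rate 1e-4, batch size 16, 60 epochs for full training runs
and 30 for fine-tuning.

Because no tensor framework is part of the dependency set, the network is
implemented directly in NumPy: convolutions run as per-example im2col GEMMs
(BLAS-backed, no materialized whole-batch column buffer), and every layer
carries a hand-derived backward pass verified against numerical
differentiation and, for the convolution, against an independent
`scipy.signal.correlate` oracle.

Choices the architecture description leaves open:

* batch normalization uses conventional batch statistics in training and
  running statistics (momentum 0.1) in evaluation;
* validation examples are always rendered in the identity orientation, so
  model selection is reproducible; training examples get a fresh uniform
  rotation every epoch;
* the batch-mean (not sum) cosine distance is used;
* the last incomplete batch is kept;
* weights use fan-in-scaled uniform initialization from a seeded generator;
* the production checkpoint is the epoch with the lowest validation loss,
  earliest on ties; checkpoints are single-file `.npz` archives holding
  weights, running statistics, epoch, metric and the model configuration.

Fine-tuning loads a foundational checkpoint's weights, restricts examples
to fragments with at least four heavy atoms, and trains 30 epochs under the
ligand-cluster split. A zero-epoch fine-tune reproduces the foundational
model bit for bit.

## Evaluation

For each test example the model runs eight times under fresh random
rotations and the predicted fingerprints are averaged element-wise. The
label set consists of the deduplicated fragments of the test set itself
(ordered lexicographically), which guarantees the ground truth is present.
Ranking is by cosine similarity, descending, with ties broken by canonical
identity; ground-truth matching is by canonical fragment identity, not
fingerprint equality, since distinct fragments can collide in fingerprint
space. Top-K accuracy is reported for K ∈ {1, 8, 16, 32, 64}; the analytic
random baseline is 100·K/N percent. The reliability analysis pools each
example's top-16 selections, bins them by cosine similarity (width 0.025
from 0.80 to 1.00 plus a catch-all below 0.80, pooled across ranks), and
reports per-bin accuracy with binomial standard errors. Property-match
analysis asks how often the rank-1 selection carries an expected property
class.

## Synthetic fixtures

The fixture generator emulates the statistical structure the pipeline
assumes without any database access: a small drug-like ligand with a seeded
distance-geometry conformer, surrounded by a shell of receptor heavy atoms
(C/N/O/S/P, carbon-dominated) placed 2–6 Å from ligand atoms with a
guaranteed contact within 4.0 Å. Fixtures are deterministic per seed and
carry protein-family labels for split testing.

What fixtures do **not** emulate: real secondary structure and bonded
receptor geometry, chemically coherent binding pockets (receptor atoms are
an unbonded cloud), realistic ligand pose strain, crystallographic noise,
or the size and redundancy structure of curated complex databases. Tests
passing on fixtures therefore validate the pipeline's mechanics —
fragmentation arithmetic, filter logic, split independence, grid geometry,
learning dynamics — not chemical accuracy on real complexes, and the
absolute retrieval accuracies published for full-database training are
explicitly out of scope here.

## The small-set learnability benchmark

The overfitting benchmark trains the full-width network on 20 fixture
examples covering exactly five structurally distinct (trimmed ligand,
fragment) classes: butyl/benzene, carboxymethyl/toluene,
methylsulfonyl/pyridine, dimethylaminomethyl/cyclohexane and glycol
ether/cyclopentane. Each class models one binding site (a bound ligand pose
in its receptor shell); the four replicas per class are replicate
structures of that site, with receptor coordinates perturbed by 0.4 Å
Gaussian jitter the way independent crystal structures of one receptor
family differ. All five fragments have at least four heavy atoms,
mirroring the large-fragment constraint of the fine-tuning protocol (which
discards fragments with three or fewer heavy atoms). Success is Top-1 ≥
80% against the five-fragment label set under the standard eight-rotation
evaluation, within 30 epochs.

A 20-example set at the production batch size yields only two optimizer
steps per epoch, and 60 Adam steps at learning rate 1e-4 leave the model
near a constant predictor regardless of dataset. The benchmark therefore
uses the small-dataset configuration: batch size 1 (600 optimizer steps in
30 epochs), learning rate 3e-4, and dropout disabled — dropout exists to
prevent overfitting, which is exactly what this benchmark must achieve.
Larger rates (≥5e-4 at this batch size) reproducibly drive the pre-sigmoid
logits to saturation, where the cosine loss — scale-invariant in the
prediction — supplies no restoring gradient and training freezes; 3e-4 is
the stable setting. Architecture, loss, rotation augmentation, checkpoint
selection and the evaluation protocol are unchanged. An optional
warmup/cosine learning-rate schedule is available in the training loop for
short-run experiments, but the benchmark uses the constant rate. Problem
sizes throughout the test suite (dozens of fixtures, 20-example training
runs) are chosen so the full pipeline exercises every code path at desk
scale.

## Known limitations

* Receptor atom clouds carry no bond or residue information; any PDB
  parsing beyond heavy-atom extraction (altlocs, insertion codes, model
  selection beyond the first) is minimal.
* The NumPy engine is single-threaded BLAS-bound; it is sized for desk-scale
  experiments, not full-database training.
* SMARTS-based acid/base rules are literal encodings of the stated classes;
  tautomer- or pKa-aware classification is out of scope.
* The density kernel is the stated exponential decay; the original
  smoothing function it stands in for is configurable but not bundled.
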