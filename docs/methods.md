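# Methods

## Problem and model

`sparsepocket` predicts ligand binding sites on protein structures by
treating the problem as semantic segmentation of a sparse 3-D point cloud:
every protein atom is a point carrying a nine-channel chemical descriptor,
and the model labels each atom as binding or non-binding.  Protein
structures are overwhelmingly empty space, so instead of dense voxel grids
the pipeline uses sparse tensors — a set of occupied integer coordinates
with attached features — and generalized sparse convolutions that are
evaluated only at occupied coordinates.

A structure becomes three matrices: C (N×5 integer coordinates `x, y, z, t,
b`, where `t` indexes the structure and `b` the batch), F (N×9 features)
and L (N×1 binary labels).  An atom is labelled binding when it lies within
5 Å (inclusive) of any ligand atom.

### Featurization

Nine channels per atom, in fixed order: hybridization (1/2/3 for
sp/sp²/sp³, 0 unknown), heavy-atom degree, heteroatom degree (bonded
N/O/S/P), hydrophobic flag (carbon with no bonded heteroatom), aromatic
flag, partial charge, acceptor, donor, ring.  Two perception backends:

* **rules** (default, mandatory): lookup tables derived from the standard
  amino-acid bond topology, with a mid-chain convention (backbone N and C
  each gain one peptide-bond neighbour).  Partial charges are coarse
  per-class constants (e.g. backbone N −0.35 e, carbonyl O −0.55 e).  The
  backend is deterministic and dependency-free; atoms of unknown residues
  fall back to isolated-atom features with a logged warning.
* **rdkit** (optional): full toolkit perception — RDKit hybridization,
  aromaticity, Gasteiger charges, pharmacophore donors/acceptors.  When the
  toolkit cannot sanitize a structure the rule backend takes over.  The
  test suite uses this backend as an independent oracle for the rule
  tables on idealized residues.

### Quantization

Grid coordinate = `floor((xyz − origin)/resolution)` with the origin at the
per-structure minimum corner.  Default resolution 1.0 Å: atomic spacing is
~1.5 Å, so almost every atom keeps its own cell while the integer grid
stays compact; the value is configurable and the tests exercise the
0.001 Å limit (no merges).  Atoms sharing a cell are merged with feature
mean (conserves per-channel mass) and label max (never loses a positive);
`atom_map` records the merge so per-row predictions can be projected back
onto source atoms.

## Network

A UNet/ResNet encoder–decoder built from three blocks: convolution block
(sparse conv → batch norm → ReLU), transpose block (sparse transpose conv →
batch norm → ReLU) and the ResNet basic block (two conv+norm stages with an
identity or 1³-projected shortcut).  Four encoder levels downsample by
stride-2 3³ convolutions; four decoder levels upsample by stride-2 3³
transpose convolutions onto the coordinate sets recorded at the matching
encoder level, concatenate the skip features, and run basic blocks.  A 1³
single-logit convolution with bias closes the network; sigmoid outputs are
row-aligned with the input tensor.

The stem is the one non-hypercubic kernel: the 3³ spatial cube replicated
at temporal offsets {0, 1} (54 offsets).  Convolutions treat `t` as a
fourth coordinate axis and `b` as a strict partition key, so the stem's
dt=+1 taps only ever see a same-batch neighbouring structure; on a single
structure they find nothing and the stem degrades to a plain 3³ kernel.
With the published best configuration (encoder planes 32/48/128/128,
decoder 128/128/48/32, block counts 2,3,1,3,3,2,1,3, nine input channels)
the network holds exactly 10,861,601 trainable parameters; this total is
asserted in the tests and recomputed by `scripts/acceptance.py`, and it
pins down the kernel/stride choices above — any other stem kernel,
downsampling kernel or skip wiring moves the count.

The engine is a reference CPU implementation in numpy: kernel maps are
built by packed-coordinate binary search, forward/backward passes are
gather–GEMM–scatter per offset, and a reverse-mode tape provides exact
gradients for every layer (verified against finite differences and, for
the convolutions, against dense-grid oracles at 1e−6).  Output coordinates
derive from input occupancy (floor-divided by the stride); no dilation, so
sparsity is preserved.  Head bias initializes at −2 so an untrained network
starts near the base rate of the rare positive class; conv weights use
He-style initialization from a recorded seed.

## Training

Two class-imbalance losses: soft Dice (smoothing 1.0) and focal loss
−α_t(1−p_t)^γ log p_t (defaults γ=1, α=0.15, the published best).  AdamW
(β₁=0.9, β₂=0.999, weight decay 0.01 — standard values; the source work
does not print them) with decoupled decay.  Early stopping watches the
validation loss with a patience counter, while model selection keeps the
checkpoint with the best validation PRC-AUC; both series are logged per
epoch together with validation F1 at probability 0.5.  Data are split
80/20 with ligand-grouped exclusivity: structures sharing any ligand
identifier are merged into one group (union–find) and whole groups are
assigned greedily in seed-shuffled order, so no ligand appears on both
sides.  The hyperparameter driver is a pluggable `Sampler`
(suggest/report); a seeded random sampler ships as the default, and a
Bayesian strategy can be plugged in without changing the loop.

All randomness flows from one named seed; on a single thread two runs
produce bit-identical weight trajectories and histories.

## Postprocessing and evaluation

Atoms with probability ≥ 0.5 are mapped back to source-atom Å coordinates
and clustered with DBSCAN (eps 5.5 Å, min 5 atoms, k-d-tree neighbour
queries with leaf size 100).  The implementation follows the classic
algorithm in ascending point order, which fixes the one ambiguity of
DBSCAN — border points reachable from several clusters join the first
cluster discovered — so runs are reproducible; it is verified exactly
against an index-free brute-force reference and cross-checked against
scikit-learn's core-point and noise sets.  Each cluster becomes a pocket
with its member atoms, residues, and arithmetic-mean centre.

Pocket-centric scoring: DCA (minimum distance from pocket centre to any
ligand atom) and DCC (distance from pocket centre to the ligand centroid),
with a site counted as a hit at ≤ 4 Å and success rates taken over all
annotated sites — structures with no predictions still contribute their
sites to the denominator.  The default matching rule lets any pocket claim
a site; a greedy one-to-one `nearest_exclusive` variant is provided because
the published definition does not state which pocket is matched when
several qualify.  Residue-centric scoring: a residue is binding when any
atom lies within the 5 Å labelling radius of a ligand atom, predicted when
any atom belongs to a pocket; precision, recall, F1 and MCC are computed
per structure and macro-averaged, with zero-denominator terms contributing
0 (this penalizes empty predictions rather than dropping the structure).

## Synthetic data

The generator produces protein-like fixtures so the full cycle runs with no
downloads.  Residues carry six atoms (N, CA, C, O, CB and one side-chain
tip) along a directionally persistent reflected random walk (3.8 Å CA
step) in an 80 Å box; defaults are 1020 atoms (170 residues), two planted
pockets, eight ligand atoms per pocket.  Pockets anchor at cleft-like
neighbourhoods (40th–75th percentile of local CA density) with the ligand
blob at the neighbourhood centroid, sites separated by at least
2·(pocket_radius + 5 Å) + 6 Å so distinct sites cannot merge during
clustering; the ligand scatter stays within half the pocket radius.  These
choices keep the positive-label fraction at a protein-like few percent
(3.9–7.9% over 40 seeds) and make every planted site recoverable by
construction: clustering the *true* labels yields a pocket within 4 Å DCC
of every ligand centroid.

The learnable signal is chemical, not positional: pocket-lining residues
draw from a polar, donor/acceptor-rich alphabet (SER/THR/LYS/TYR/ASN) with
probability `positive_feature_bias` (default 0.9) while background
residues are predominantly hydrophobic (LEU/VAL/ILE/PHE), so after
ordinary featurization the label correlates with the local density of
polar side chains.  Geometry is independent of residue identity, so labels
cannot be read off coordinates alone, and no single atom's features decide
its label — the network must integrate a neighbourhood.

What the generator does **not** emulate: real secondary structure and
packing, ligand chemistry (pseudo-ligands are featureless coordinate
blobs), crystallographic noise, the size and diversity of curated
protein–ligand corpora, and any apo/holo conformational difference.
Passing tests therefore demonstrate that the machinery is correct and that
the model class can learn a spatially structured chemical signal at desk
scale — they say nothing about accuracy on real structures, which requires
training on a real corpus.

## Numerical and design choices

* "Above 2 Å" resolution curation is strict: exactly 2.0 Å passes; files
  without a REMARK 2 record pass that criterion with a warning.
* Alternate locations: blank or 'A' kept, others dropped; first MODEL kept
  when several have equal atom counts.
* "Within 5 Å" labelling is inclusive (≤).
* Quantization tie-breaks: feature mean, label max, `np.unique`
  lexicographic cell ordering.
* Desk-scale problem sizes: the test suite trains width-12 networks on
  five ~1000-atom structures for ≤ 200 epochs; the published-scale
  configuration is only instantiated and counted, never trained here.
* The layer-count convention behind a "171-layer" description of this
  architecture family is not reproducible from the printed information;
  the package reports parameter counts instead.

## Known limitations

Single-threaded CPU engine, not performance-competitive with production
sparse-conv libraries; no GPU or mixed precision.  The rule-based
featurizer is a deliberately coarse approximation of toolkit perception
(its charges are class constants, not Gasteiger values).  mmCIF input is
out of scope, as are pocket ranking/druggability scores.
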