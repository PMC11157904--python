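# sparsepocket

Ligand binding site prediction on sparse atomic point clouds.

Knowing where a small molecule binds a protein is central to understanding
protein function and to structure-based drug design, but experimental
mapping of binding sites is slow and expensive.  `sparsepocket` predicts
binding sites computationally by treating the task as semantic segmentation
of a sparse 3-D point cloud: every atom of a protein structure is a point
with a nine-channel chemical descriptor (hybridization, heavy/hetero
degree, hydrophobicity, aromaticity, partial charge, donor/acceptor, ring
membership), and a sparse-convolutional UNet/ResNet encoder–decoder labels
each atom as binding or non-binding.  Predicted binding atoms are then
clustered into discrete pockets with DBSCAN.

The package is aimed at structural-bioinformatics practitioners and method
developers: it is a complete, desk-scale reference implementation of the
sparse pipeline — PDB parsing and curation, featurization, sparse
tensorization, the convolution engine with exact gradients, training with
class-imbalance losses, pocket extraction, and evaluation — with a
synthetic-data generator so every stage runs and is tested without any
external dataset.

## The model in brief

A structure is a sparse tensor: coordinates C ∈ ℤ^{N×5} (grid `x,y,z`,
structure index `t`, batch index `b`), features F ∈ ℝ^{N×9}, labels
L ∈ {0,1}^N, where an atom is labelled binding when it lies within 5 Å of
a ligand atom.  The generalized sparse convolution evaluated at the
predefined output coordinates C^out is

    X_u^out = Σ_{i ∈ N^D(u, C^in)} W_i · x_{u+i}^in ,   u ∈ C^out,

where N^D is the kernel-offset set.  The encoder applies a hybrid-kernel
stem and four stride-2 levels of convolution + residual basic blocks; the
decoder mirrors them with transpose convolutions and skip concatenation,
ending in a single-logit head.  Training minimizes the focal loss
−α_t(1−p_t)^γ log p_t (γ=1, α=0.15 by default) with AdamW, early stopping
on validation loss and model selection by validation PRC-AUC.  Pockets are
DBSCAN clusters (eps 5.5 Å, ≥5 atoms) of predicted binding atoms; scoring
uses DCA/DCC success rates (≤4 Å) and macro-averaged residue-level
precision/recall/F1/MCC.  See `docs/methods.md` for the full account.

## Worked example

`examples/inspect_network.py` builds the full published configuration and
prints its architecture fingerprint:

```
encoder out-planes : (32, 48, 128, 128)
decoder out-planes : (128, 128, 48, 32)
basic-block counts : (2, 3, 1, 3, 3, 2, 1, 3)
trainable arrays   : 155
trainable params   : 10,861,601
```

The parameter total counts every convolution/transpose kernel, batch-norm
affine pair and the head weights+bias; it pins down the kernel and stride
choices of the architecture.

`examples/train_on_synthetic.py` generates five synthetic complexes with
planted, chemically biased pockets and overfits a narrow network (width 12,
~117k parameters) in a few CPU-minutes; an abbreviated history:

```
 epoch  train_loss  val_loss  val_prc_auc   val_f1
     1    0.118426  0.037066     0.059208 0.000000
    21    0.019333  0.026106     0.598644 0.000000
    41    0.004632  0.006745     0.996939 0.839161
    51    0.002051  0.002857     1.000000 0.975309
final training-set per-atom F1: 0.956
```

The loss is the focal loss over atoms; `val_prc_auc` is the area under the
precision–recall curve for the atom-level binding class, and F1 is scored
at probability 0.5.  A training-set F1 near 1 shows the network has learned
the planted geometric+chemical pocket signal.  `examples/predict_and_score.py`
continues through pocket extraction and scoring on one two-site structure:

```
synth000042: 1020 atoms, 2 planted sites, 961 occupied cells
pocket 1: 56 atoms, 11 residues, centre [61.1 25.3 70.2]
pocket 2: 33 atoms, 6 residues, centre [45.  62.6 14.4]
{
  "success_rate_dca": 100.0,
  "success_rate_dcc": 100.0,
  "precision": 100.0,
  ...
}
```

Both planted sites are recovered: each pocket centre lies within 4 Å of
its ligand (DCA and DCC hits), and every binding residue is found with no
false positives.

## Command line

The same pipeline is scriptable from the shell:

```bash
sparsepocket make-fixtures --n 10 --seed 1 --out data/
sparsepocket prepare --pdb data/ --ligand data/ligands.csv --out prep/
sparsepocket train --data prep/ --seed 0 --out model/
sparsepocket predict --model model/checkpoint.npz --pdb data/synth_000.pdb --out pred/
sparsepocket evaluate --pred pred/ --truth data/ --out report.csv
```

Chain handling mirrors typical server usage: `--mode single` treats the
file as one complex, `--mode per-chain` predicts each chain separately, and
`--mode chains --chains A,B` treats a chain subset as one complex.  Every
command writes its resolved configuration and a log into the output
directory.

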