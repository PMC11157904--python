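"""Train a reduced network on synthetic complexes and watch it learn.

Five protein-like structures with planted, chemically biased binding pockets
are generated, tensorized, and used to overfit a narrow (width-12) network.
The printed history shows the focal loss falling and the per-atom F1 rising;
by the end the model has memorized the pocket signal in its training data.
Runs in a few minutes on one CPU.
"""

import numpy as np

from sparsepocket import (
    NetworkSpec,
    SparseUNet,
    TrainingConfig,
    generate_dataset,
    tensorize_structure,
    train,
)
from sparsepocket.losses import f1_at_threshold

complexes, manifest = generate_dataset(5, seed=1)
tensors = [tensorize_structure(s, l, t=i) for i, (s, l) in enumerate(complexes)]
print("structures:", [s.structure_id for s, _ in complexes])
print("tensor rows:", [t.n_rows for t in tensors])
print("positive fraction:", [round(float(t.labels.mean()), 3) for t in tensors])

net = SparseUNet(NetworkSpec.reduced(width=12), seed=1)
config = TrainingConfig(
    batch_size=5, learning_rate=3e-3, loss="focal",
    focal_gamma=1.0, focal_alpha=0.25,
    max_epochs=60, patience=60, seed=1,
)
result = train(net, tensors, tensors, config)
print(result.history.iloc[::10].to_string(index=False))

net.load_state_arrays(result.best_state)
probs = np.concatenate([net.forward(t) for t in tensors])
labels = np.concatenate([t.labels for t in tensors]).astype(float)
print(f"final training-set per-atom F1: {f1_at_threshold(probs, labels):.3f}")
# F1 near 1.0 means the network separates pocket-lining atoms from the rest
# of the structure on the data it was trained on.
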