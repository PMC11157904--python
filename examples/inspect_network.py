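"""Build the full published network configuration and count its parameters.

The best configuration found by the hyperparameter search uses encoder
out-planes 32/48/128/128, decoder out-planes 128/128/48/32 and basic-block
counts 2,3,1,3,3,2,1,3 on nine input feature channels.  The count below sums
every trainable array: convolution/transpose kernels, batch-norm affine
pairs, and the single-logit head weights and bias.
"""

from sparsepocket import NetworkSpec, build_network

spec = NetworkSpec.published_best()
net = build_network(spec, seed=0)

print(f"encoder out-planes : {spec.encoder_planes}")
print(f"decoder out-planes : {spec.decoder_planes}")
print(f"basic-block counts : {spec.block_counts}")
print(f"trainable arrays   : {len(net.parameters())}")
print(f"trainable params   : {net.parameter_count():,}")
# The parameter total is the architecture's fingerprint: change any kernel
# shape, stride, or the skip wiring and this number moves.
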