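"""The sparse encoder–decoder (UNet/ResNet) for per-atom binding prediction.

The encoder opens with a stem convolution carrying a hybrid, non-hypercubic
kernel (the 3³ spatial cube replicated at temporal offsets {0, 1}; 54
offsets) and then runs four levels of [stride-2 3³ convolution block →
basic blocks].  The decoder mirrors it with four levels of [stride-2 3³
transpose block → skip concatenation → basic blocks]; skip features come
from the matching encoder level, so the decoder returns exactly to the
input coordinate set.  A 1³ single-logit head with bias closes the network;
sigmoid probabilities are row-aligned with the input tensor.

With the published best configuration (encoder out-planes 32/48/128/128,
decoder 128/128/48/32, basic-block counts 2,3,1,3,3,2,1,3, nine input
channels) the network holds exactly 10,861,601 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sparse import (
    BasicBlock,
    BatchNorm,
    KernelOffsets,
    Parameter,
    SparseConv,
    SparseConvTranspose,
    SparseFeatureMap,
    Tape,
    concat,
    relu,
)
from .tensorize import SparseProteinTensor

__all__ = ["NetworkSpec", "SparseUNet", "build_network", "save_checkpoint", "load_checkpoint"]

_N_LEVELS = 4


@dataclass(frozen=True)
class NetworkSpec:
    """Out-planes and basic-block counts per level, plus kernel conventions."""

    in_channels: int = 9
    encoder_planes: tuple[int, ...] = (32, 48, 128, 128)
    decoder_planes: tuple[int, ...] = (128, 128, 48, 32)
    block_counts: tuple[int, ...] = (2, 3, 1, 3, 3, 2, 1, 3)
    init_dim: int = 32
    kernel_size: int = 3
    norm_epsilon: float = 1e-5
    norm_momentum: float = 0.1

    def __post_init__(self) -> None:
        if len(self.encoder_planes) != _N_LEVELS or len(self.decoder_planes) != _N_LEVELS:
            raise ValueError("encoder_planes and decoder_planes must list 4 levels")
        if len(self.block_counts) != 2 * _N_LEVELS:
            raise ValueError("block_counts must list 8 entries (encoder then decoder)")
        if any(p <= 0 for p in self.encoder_planes + self.decoder_planes):
            raise ValueError("plane counts must be positive")
        if any(c < 1 for c in self.block_counts):
            raise ValueError("block counts must be at least 1 per level")

    @classmethod
    def published_best(cls) -> "NetworkSpec":
        """The best configuration from the published hyperparameter search."""
        return cls()

    @classmethod
    def reduced(cls, width: int = 12, blocks: int = 1) -> "NetworkSpec":
        """A desk-scale network for synthetic-data experiments."""
        return cls(
            encoder_planes=(width,) * _N_LEVELS,
            decoder_planes=(width,) * _N_LEVELS,
            block_counts=(blocks,) * (2 * _N_LEVELS),
            init_dim=width,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        for k in ("encoder_planes", "decoder_planes", "block_counts"):
            d[k] = tuple(d[k])
        return cls(**d)


class SparseUNet:
    """Encoder–decoder over sparse atomic tensors; one logit per input row."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = KernelOffsets.cubic(spec.kernel_size)
        eps, mom = spec.norm_epsilon, spec.norm_momentum

        self.stem_conv = SparseConv(
            spec.in_channels, spec.init_dim, KernelOffsets.hybrid_stem(), rng=rng
        )
        self.stem_bn = BatchNorm(spec.init_dim, eps, mom)

        self.enc_convs: list[SparseConv] = []
        self.enc_bns: list[BatchNorm] = []
        self.enc_blocks: list[list[BasicBlock]] = []
        ch = spec.init_dim
        for lvl in range(_N_LEVELS):
            self.enc_convs.append(SparseConv(ch, ch, k, stride=2, rng=rng))
            self.enc_bns.append(BatchNorm(ch, eps, mom))
            blocks = []
            for b in range(spec.block_counts[lvl]):
                blocks.append(
                    BasicBlock(
                        ch if b == 0 else spec.encoder_planes[lvl],
                        spec.encoder_planes[lvl],
                        k,
                        eps,
                        mom,
                        rng=rng,
                    )
                )
                ch = spec.encoder_planes[lvl]
            self.enc_blocks.append(blocks)

        self.dec_convs: list[SparseConvTranspose] = []
        self.dec_bns: list[BatchNorm] = []
        self.dec_blocks: list[list[BasicBlock]] = []
        skip_channels = [spec.init_dim] + list(spec.encoder_planes[:-1])
        for lvl in range(_N_LEVELS):
            planes = spec.decoder_planes[lvl]
            self.dec_convs.append(SparseConvTranspose(ch, planes, k, stride=2, rng=rng))
            self.dec_bns.append(BatchNorm(planes, eps, mom))
            ch = planes + skip_channels[_N_LEVELS - 1 - lvl]
            blocks = []
            for b in range(spec.block_counts[_N_LEVELS + lvl]):
                blocks.append(BasicBlock(ch if b == 0 else planes, planes, k, eps, mom, rng=rng))
                ch = planes
            self.dec_blocks.append(blocks)

        self.head = SparseConv(ch, 1, KernelOffsets.identity(), bias=True, rng=rng)
        # bias the head toward the negative class: binding atoms are rare
        self.head.bias.data[:] = -2.0

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params = self.stem_conv.parameters() + self.stem_bn.parameters()
        for conv, bn, blocks in zip(self.enc_convs, self.enc_bns, self.enc_blocks):
            params += conv.parameters() + bn.parameters()
            for blk in blocks:
                params += blk.parameters()
        for conv, bn, blocks in zip(self.dec_convs, self.dec_bns, self.dec_blocks):
            params += conv.parameters() + bn.parameters()
            for blk in blocks:
                params += blk.parameters()
        params += self.head.parameters()
        return params

    def parameter_count(self) -> int:
        """Total number of trainable scalars (conv weights, biases, norm affines)."""
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[:] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Named weight arrays, including batch-norm running statistics."""
        arrays: dict[str, np.ndarray] = {}

        def grab(prefix: str, obj) -> None:
            if isinstance(obj, (SparseConv, SparseConvTranspose)):
                arrays[f"{prefix}.weight"] = obj.weight.data
                if obj.bias is not None:
                    arrays[f"{prefix}.bias"] = obj.bias.data
            elif isinstance(obj, BatchNorm):
                arrays[f"{prefix}.gamma"] = obj.gamma.data
                arrays[f"{prefix}.beta"] = obj.beta.data
                arrays[f"{prefix}.running_mean"] = obj.running_mean
                arrays[f"{prefix}.running_var"] = obj.running_var
            elif isinstance(obj, BasicBlock):
                grab(f"{prefix}.conv1", obj.conv1)
                grab(f"{prefix}.bn1", obj.bn1)
                grab(f"{prefix}.conv2", obj.conv2)
                grab(f"{prefix}.bn2", obj.bn2)
                if obj.down_conv is not None:
                    grab(f"{prefix}.down_conv", obj.down_conv)
                    grab(f"{prefix}.down_bn", obj.down_bn)

        grab("stem_conv", self.stem_conv)
        grab("stem_bn", self.stem_bn)
        for lvl in range(_N_LEVELS):
            grab(f"enc{lvl}.conv", self.enc_convs[lvl])
            grab(f"enc{lvl}.bn", self.enc_bns[lvl])
            for bi, blk in enumerate(self.enc_blocks[lvl]):
                grab(f"enc{lvl}.block{bi}", blk)
        for lvl in range(_N_LEVELS):
            grab(f"dec{lvl}.conv", self.dec_convs[lvl])
            grab(f"dec{lvl}.bn", self.dec_bns[lvl])
            for bi, blk in enumerate(self.dec_blocks[lvl]):
                grab(f"dec{lvl}.block{bi}", blk)
        grab("head", self.head)
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        current = self.state_arrays()
        missing = set(current) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint missing arrays: {sorted(missing)[:5]}")
        for name, dst in current.items():
            src = np.asarray(arrays[name], dtype=float)
            if src.shape != dst.shape:
                raise ValueError(
                    f"checkpoint/spec mismatch for {name}: {src.shape} vs {dst.shape}"
                )
            dst[...] = src

    # -- forward ------------------------------------------------------------
    def forward_logits(
        self,
        tensor: SparseProteinTensor | SparseFeatureMap,
        training: bool = False,
        tape: Optional[Tape] = None,
    ) -> SparseFeatureMap:
        if isinstance(tensor, SparseProteinTensor):
            x = SparseFeatureMap(tensor.coords, tensor.feats.astype(float))
        else:
            x = tensor
        if len(x.feats) == 0:
            raise ValueError("cannot run the network on an empty tensor")
        if x.n_channels != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} feature channels, got {x.n_channels}"
            )
        h = self.stem_conv.forward(x, out_coords=x.coords, tape=tape)
        h = self.stem_bn.forward(h, training=training, tape=tape)
        h = relu(h, tape=tape)
        skips = [h]
        for lvl in range(_N_LEVELS):
            h = self.enc_convs[lvl].forward(h, tape=tape)
            h = self.enc_bns[lvl].forward(h, training=training, tape=tape)
            h = relu(h, tape=tape)
            for blk in self.enc_blocks[lvl]:
                h = blk.forward(h, training=training, tape=tape)
            skips.append(h)
        skips.pop()  # deepest level is the decoder input, not a skip
        for lvl in range(_N_LEVELS):
            skip = skips.pop()
            h = self.dec_convs[lvl].forward(h, out_coords=skip.coords, tape=tape)
            h = self.dec_bns[lvl].forward(h, training=training, tape=tape)
            h = relu(h, tape=tape)
            h = concat(h, skip, tape=tape)
            for blk in self.dec_blocks[lvl]:
                h = blk.forward(h, training=training, tape=tape)
        return self.head.forward(h, out_coords=h.coords, tape=tape)

    def forward(self, tensor, training: bool = False, tape: Optional[Tape] = None) -> np.ndarray:
        """Per-row binding probabilities, row-aligned with the input tensor."""
        logits = self.forward_logits(tensor, training=training, tape=tape)
        return 1.0 / (1.0 + np.exp(-logits.feats[:, 0]))


def build_network(spec: Optional[NetworkSpec] = None, seed: int = 0) -> SparseUNet:
    return SparseUNet(spec or NetworkSpec.published_best(), seed=seed)


def save_checkpoint(net: SparseUNet, path) -> None:
    """Versioned archive of the NetworkSpec plus named weight arrays."""
    arrays = net.state_arrays()
    np.savez_compressed(
        path,
        __format_version__=np.array([1]),
        __spec_json__=np.array([net.spec.to_json()]),
        __seed__=np.array([net.seed]),
        **arrays,
    )


def load_checkpoint(path) -> SparseUNet:
    with np.load(path, allow_pickle=False) as data:
        spec = NetworkSpec.from_json(str(data["__spec_json__"][0]))
        net = SparseUNet(spec, seed=int(data["__seed__"][0]))
        arrays = {k: data[k] for k in data.files if not k.startswith("__")}
    net.load_state_arrays(arrays)
    return net
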