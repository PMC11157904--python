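"""A reference CPU engine for generalized sparse convolution.

Sparse tensors are sets of occupied integer coordinates (columns x, y, z, t,
b) with attached feature rows.  A convolution with kernel-offset set N^D
evaluates, for every predefined output coordinate u,

    X_u^out = sum over offsets i in N^D with u*s + i occupied of  W_i x_{u*s+i}

so only occupied coordinates are touched and sparsity is preserved.  Offsets
are 4-vectors applied to (x, y, z, t); the batch column b is a strict
partition key and is never mixed across.  Strided convolutions emit
coordinates on the coarser grid (spatial floor-division by the stride);
transpose convolutions are the adjoint map back onto a predefined finer
coordinate set.

Layers carry their own parameters and push backward closures onto a tape,
giving exact reverse-mode gradients without any framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "KernelOffsets",
    "SparseFeatureMap",
    "Tape",
    "Parameter",
    "SparseConv",
    "SparseConvTranspose",
    "BatchNorm",
    "relu",
    "concat",
    "add",
    "BasicBlock",
    "build_kernel_map",
    "downsample_coords",
]

# coordinate packing bounds: spatial in [-_SPATIAL_SHIFT, 2**14 - _SPATIAL_SHIFT),
# t and b in [-2, 2**11 - 2).  Comfortably covers Å-scale protein grids.
_SPATIAL_SHIFT = 64
_TB_SHIFT = 2


@dataclass(frozen=True)
class KernelOffsets:
    """An ordered set of integer (dx, dy, dz, dt) kernel offsets."""

    offsets: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] not in (3, 4):
            raise ValueError("offsets must be (K, 3) or (K, 4) integers")
        if arr.shape[1] == 3:  # spatial-only shorthand: dt = 0
            arr = np.concatenate([arr, np.zeros((len(arr), 1), dtype=np.int64)], axis=1)
        if len(np.unique(arr, axis=0)) != len(arr):
            raise ValueError("kernel offsets must be unique")
        object.__setattr__(self, "offsets", arr)

    @property
    def size(self) -> int:
        return len(self.offsets)

    @classmethod
    def cubic(cls, kernel_size: int = 3) -> "KernelOffsets":
        """The standard cubic kernel: {-(k//2) … k//2}³ at dt = 0."""
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("cubic kernels must have odd positive size")
        r = kernel_size // 2
        axis = np.arange(-r, r + 1)
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
        return cls(grid.reshape(-1, 3))

    @classmethod
    def hybrid_stem(cls) -> "KernelOffsets":
        """The non-hypercubic stem kernel: 3³ spatial cube × dt in {0, 1}.

        54 offsets; on a single structure the dt=+1 half finds no occupied
        coordinates and the kernel degrades gracefully to the cubic 3³.
        """
        cube = cls.cubic(3).offsets[:, :3]
        dt0 = np.concatenate([cube, np.zeros((27, 1), dtype=np.int64)], axis=1)
        dt1 = np.concatenate([cube, np.ones((27, 1), dtype=np.int64)], axis=1)
        return cls(np.vstack([dt0, dt1]))

    @classmethod
    def identity(cls) -> "KernelOffsets":
        return cls(np.zeros((1, 3), dtype=np.int64))


@dataclass
class SparseFeatureMap:
    """Coordinates + row-aligned features at one stride level of the network."""

    coords: np.ndarray  # (M, 5) int
    feats: np.ndarray  # (M, C) float
    stride: int = 1
    grad: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 5)
        self.feats = np.asarray(self.feats, dtype=float)
        if self.feats.ndim != 2 or len(self.feats) != len(self.coords):
            raise ValueError("feats must be (M, C) and row-aligned with coords")

    @property
    def n_channels(self) -> int:
        return self.feats.shape[1]

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.feats)
        self.grad += g


class Tape:
    """Reverse-mode tape: closures run in reverse execution order."""

    def __init__(self) -> None:
        self._ops: list[Callable[[], None]] = []

    def push(self, fn: Callable[[], None]) -> None:
        self._ops.append(fn)

    def backward(self, output: SparseFeatureMap, seed_grad: np.ndarray) -> None:
        output.accumulate_grad(seed_grad)
        for fn in reversed(self._ops):
            fn()


@dataclass
class Parameter:
    data: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


def _pack(coords: np.ndarray) -> np.ndarray:
    """Pack (M, 5) integer coordinates into sortable int64 keys."""
    c = coords.astype(np.int64)
    s = c[:, :3] + _SPATIAL_SHIFT
    tb = c[:, 3:] + _TB_SHIFT
    if s.size and (s.min() < 0 or s.max() >= 1 << 14):
        raise ValueError("spatial coordinate out of packable range")
    if tb.size and (tb.min() < 0 or tb.max() >= 1 << 11):
        raise ValueError("t/b coordinate out of packable range")
    return (
        (s[:, 0] << 50)
        | (s[:, 1] << 36)
        | (s[:, 2] << 22)
        | (tb[:, 0] << 11)
        | tb[:, 1]
    )


def downsample_coords(coords: np.ndarray, stride: int) -> np.ndarray:
    """Unique coarse-grid coordinates: spatial floor-division, t/b kept."""
    coarse = coords.copy()
    coarse[:, :3] = np.floor_divide(coarse[:, :3], stride)
    return np.unique(coarse, axis=0)


def build_kernel_map(
    in_coords: np.ndarray,
    out_coords: np.ndarray,
    offsets: KernelOffsets,
    stride: int = 1,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-offset (input_rows, output_rows) index pairs.

    Output coordinate u reads input coordinate u*stride + offset.  Within one
    offset both index arrays are duplicate-free, so gathered adds never
    collide and plain fancy indexing is safe.
    """
    keys = _pack(in_coords)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    maps = []
    scaled = out_coords.copy()
    scaled[:, :3] *= stride
    for off in offsets.offsets:
        query = scaled.copy()
        query[:, :3] += off[:3]
        query[:, 3] += off[3]
        qkeys = _pack(query)
        pos = np.searchsorted(sorted_keys, qkeys)
        pos_clipped = np.minimum(pos, len(sorted_keys) - 1)
        hit = (
            np.zeros(len(qkeys), dtype=bool)
            if len(sorted_keys) == 0
            else sorted_keys[pos_clipped] == qkeys
        )
        out_rows = np.flatnonzero(hit)
        in_rows = order[pos_clipped[hit]]
        maps.append((in_rows, out_rows))
    return maps


def _he_init(rng: np.random.Generator, k: int, out_ch: int, in_ch: int) -> np.ndarray:
    std = np.sqrt(2.0 / (k * in_ch))
    return rng.normal(0.0, std, size=(k, out_ch, in_ch))


class SparseConv:
    """Generalized sparse convolution with per-offset weight matrices W_i."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        offsets: KernelOffsets,
        stride: int = 1,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.offsets = offsets
        self.stride = stride
        self.weight = Parameter(_he_init(rng, offsets.size, out_channels, in_channels))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(
        self,
        x: SparseFeatureMap,
        out_coords: Optional[np.ndarray] = None,
        tape: Optional[Tape] = None,
    ) -> SparseFeatureMap:
        if x.n_channels != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.n_channels}, layer expects {self.in_channels}"
            )
        if out_coords is None:
            out_coords = (
                x.coords if self.stride == 1 else downsample_coords(x.coords, self.stride)
            )
        maps = build_kernel_map(x.coords, out_coords, self.offsets, self.stride)
        y_feats = np.zeros((len(out_coords), self.out_channels))
        W = self.weight.data
        for k, (ii, oo) in enumerate(maps):
            if len(ii):
                y_feats[oo] += x.feats[ii] @ W[k].T
        if self.bias is not None:
            y_feats += self.bias.data
        y = SparseFeatureMap(out_coords, y_feats, stride=x.stride * self.stride)

        if tape is not None:
            x_feats = x.feats

            def _backward() -> None:
                gy = y.grad
                if gy is None:
                    return
                gx = np.zeros_like(x_feats)
                for k, (ii, oo) in enumerate(maps):
                    if len(ii):
                        gx[ii] += gy[oo] @ W[k]
                        self.weight.grad[k] += gy[oo].T @ x_feats[ii]
                if self.bias is not None:
                    self.bias.grad += gy.sum(axis=0)
                x.accumulate_grad(gx)

            tape.push(_backward)
        return y


class SparseConvTranspose:
    """Adjoint of the strided sparse convolution: upsampling onto fine coords.

    The fine coordinate v = u*stride + offset receives W_i x_u from every
    coarse input u whose receptive field covers it.  As a linear map this is
    exactly the transpose of the corresponding :class:`SparseConv` whose
    per-offset weights are the W_iᵀ.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        offsets: KernelOffsets,
        stride: int = 1,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.offsets = offsets
        self.stride = stride
        self.weight = Parameter(_he_init(rng, offsets.size, out_channels, in_channels))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(
        self,
        x: SparseFeatureMap,
        out_coords: np.ndarray,
        tape: Optional[Tape] = None,
    ) -> SparseFeatureMap:
        if x.n_channels != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.n_channels}, layer expects {self.in_channels}"
            )
        # same map as the matching strided conv (coarse reads fine), roles swapped
        maps = build_kernel_map(out_coords, x.coords, self.offsets, self.stride)
        y_feats = np.zeros((len(out_coords), self.out_channels))
        W = self.weight.data
        for k, (fine_rows, coarse_rows) in enumerate(maps):
            if len(fine_rows):
                y_feats[fine_rows] += x.feats[coarse_rows] @ W[k].T
        if self.bias is not None:
            y_feats += self.bias.data
        new_stride = max(1, x.stride // self.stride)
        y = SparseFeatureMap(out_coords, y_feats, stride=new_stride)

        if tape is not None:
            x_feats = x.feats

            def _backward() -> None:
                gy = y.grad
                if gy is None:
                    return
                gx = np.zeros_like(x_feats)
                for k, (fine_rows, coarse_rows) in enumerate(maps):
                    if len(fine_rows):
                        gx[coarse_rows] += gy[fine_rows] @ W[k]
                        self.weight.grad[k] += gy[fine_rows].T @ x_feats[coarse_rows]
                if self.bias is not None:
                    self.bias.grad += gy.sum(axis=0)
                x.accumulate_grad(gx)

            tape.push(_backward)
        return y


class BatchNorm:
    """Per-channel batch normalization over all occupied rows."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(
        self, x: SparseFeatureMap, training: bool = False, tape: Optional[Tape] = None
    ) -> SparseFeatureMap:
        if x.n_channels != self.channels:
            raise ValueError("channel mismatch in batch norm")
        n = len(x.feats)
        if n == 0:
            raise ValueError("batch norm over zero rows")
        if training:
            mean = x.feats.mean(axis=0)
            var = x.feats.var(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.feats - mean) * inv_std
        y = SparseFeatureMap(x.coords, xhat * self.gamma.data + self.beta.data, x.stride)

        if tape is not None:
            gamma = self.gamma.data.copy()

            def _backward() -> None:
                gy = y.grad
                if gy is None:
                    return
                self.gamma.grad += (gy * xhat).sum(axis=0)
                self.beta.grad += gy.sum(axis=0)
                gxhat = gy * gamma
                if training:
                    # full batch-statistics gradient
                    gx = (
                        inv_std
                        / n
                        * (
                            n * gxhat
                            - gxhat.sum(axis=0)
                            - xhat * (gxhat * xhat).sum(axis=0)
                        )
                    )
                else:
                    gx = gxhat * inv_std
                x.accumulate_grad(gx)

            tape.push(_backward)
        return y


def relu(x: SparseFeatureMap, tape: Optional[Tape] = None) -> SparseFeatureMap:
    mask = x.feats > 0
    y = SparseFeatureMap(x.coords, np.where(mask, x.feats, 0.0), x.stride)
    if tape is not None:

        def _backward() -> None:
            if y.grad is not None:
                x.accumulate_grad(np.where(mask, y.grad, 0.0))

        tape.push(_backward)
    return y


def add(a: SparseFeatureMap, b: SparseFeatureMap, tape: Optional[Tape] = None) -> SparseFeatureMap:
    """Residual addition; requires identical coordinate sets in identical order."""
    if a.feats.shape != b.feats.shape or not np.array_equal(a.coords, b.coords):
        raise ValueError("residual addition requires aligned coordinate rows")
    y = SparseFeatureMap(a.coords, a.feats + b.feats, a.stride)
    if tape is not None:

        def _backward() -> None:
            if y.grad is not None:
                a.accumulate_grad(y.grad)
                b.accumulate_grad(y.grad)

        tape.push(_backward)
    return y


def concat(a: SparseFeatureMap, b: SparseFeatureMap, tape: Optional[Tape] = None) -> SparseFeatureMap:
    """Channel concatenation of two maps on the same coordinates (skip fusion)."""
    if not np.array_equal(a.coords, b.coords):
        raise ValueError("concatenation requires identical coordinate rows")
    ca = a.n_channels
    y = SparseFeatureMap(a.coords, np.concatenate([a.feats, b.feats], axis=1), a.stride)
    if tape is not None:

        def _backward() -> None:
            if y.grad is not None:
                a.accumulate_grad(y.grad[:, :ca])
                b.accumulate_grad(y.grad[:, ca:])

        tape.push(_backward)
    return y


class BasicBlock:
    """ResNet basic block: out = relu(BN(conv(relu(BN(conv(in))))) + shortcut).

    Stride 1; when the channel count changes, the shortcut is a 1³ convolution
    followed by batch norm, otherwise the identity.  Coordinates (and row
    order) are preserved throughout.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        offsets: Optional[KernelOffsets] = None,
        norm_eps: float = 1e-5,
        norm_momentum: float = 0.1,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        offsets = offsets or KernelOffsets.cubic(3)
        self.conv1 = SparseConv(in_channels, out_channels, offsets, rng=rng)
        self.bn1 = BatchNorm(out_channels, norm_eps, norm_momentum)
        self.conv2 = SparseConv(out_channels, out_channels, offsets, rng=rng)
        self.bn2 = BatchNorm(out_channels, norm_eps, norm_momentum)
        if in_channels != out_channels:
            self.down_conv = SparseConv(
                in_channels, out_channels, KernelOffsets.identity(), rng=rng
            )
            self.down_bn = BatchNorm(out_channels, norm_eps, norm_momentum)
        else:
            self.down_conv = None
            self.down_bn = None

    def parameters(self) -> list[Parameter]:
        params = (
            self.conv1.parameters()
            + self.bn1.parameters()
            + self.conv2.parameters()
            + self.bn2.parameters()
        )
        if self.down_conv is not None:
            params += self.down_conv.parameters() + self.down_bn.parameters()
        return params

    def forward(
        self, x: SparseFeatureMap, training: bool = False, tape: Optional[Tape] = None
    ) -> SparseFeatureMap:
        h = self.conv1.forward(x, out_coords=x.coords, tape=tape)
        h = self.bn1.forward(h, training=training, tape=tape)
        h = relu(h, tape=tape)
        h = self.conv2.forward(h, out_coords=x.coords, tape=tape)
        h = self.bn2.forward(h, training=training, tape=tape)
        if self.down_conv is not None:
            shortcut = self.down_conv.forward(x, out_coords=x.coords, tape=tape)
            shortcut = self.down_bn.forward(shortcut, training=training, tape=tape)
        else:
            shortcut = x
        h = add(h, shortcut, tape=tape)
        return relu(h, tape=tape)
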