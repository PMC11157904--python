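"""Sparse-convolution engine vs independent dense oracles.

The dense oracle embeds a sparse tensor in a zero-padded dense grid,
evaluates the convolution by explicit summation over kernel offsets, and
restricts the result to the occupied output coordinates.  Sparse and dense
routes share the weights but nothing else.
"""

import numpy as np
import pytest

from sparsepocket.sparse import (
    BasicBlock,
    BatchNorm,
    KernelOffsets,
    SparseConv,
    SparseConvTranspose,
    SparseFeatureMap,
    Tape,
    add,
    build_kernel_map,
    downsample_coords,
    relu,
)

GRID = 8  # dense oracle cube edge


def random_sparse(rng, n_points, channels, grid=GRID):
    pts = rng.integers(0, grid, size=(n_points, 3))
    coords = np.unique(
        np.concatenate([pts, np.zeros((n_points, 2), dtype=int)], axis=1), axis=0
    )
    feats = rng.normal(size=(len(coords), channels))
    return SparseFeatureMap(coords, feats)


def dense_embed(x: SparseFeatureMap, grid=GRID) -> np.ndarray:
    dense = np.zeros((grid, grid, grid, x.n_channels))
    for (i, j, k, _, _), f in zip(x.coords, x.feats):
        dense[i, j, k] = f
    return dense


def dense_conv(dense, weights, offsets, stride=1):
    """Explicit-loop dense conv; zero outside the grid; coarse output grid."""
    grid = dense.shape[0]
    out_ch = weights.shape[1]
    out_grid = (grid + stride - 1) // stride
    out = np.zeros((out_grid, out_grid, out_grid, out_ch))
    for u in np.ndindex(out_grid, out_grid, out_grid):
        acc = np.zeros(out_ch)
        for w, off in zip(weights, offsets.offsets):
            p = np.array(u) * stride + off[:3]
            if np.all(p >= 0) and np.all(p < grid):
                acc += w @ dense[tuple(p)]
        out[u] = acc
    return out


class TestKernelOffsets:
    def test_cubic_contains_zero_and_unique(self):
        k = KernelOffsets.cubic(3)
        assert k.size == 27
        assert any(np.all(off == 0) for off in k.offsets)

    def test_hybrid_stem_size(self):
        assert KernelOffsets.hybrid_stem().size == 54

    def test_even_cubic_rejected(self):
        with pytest.raises(ValueError):
            KernelOffsets.cubic(2)

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(ValueError):
            KernelOffsets(np.zeros((2, 3), dtype=int))


class TestSparseConv:
    def test_identity_kernel_identity_weight(self, rng):
        x = random_sparse(rng, 30, 4)
        conv = SparseConv(4, 4, KernelOffsets.identity())
        conv.weight.data[0] = np.eye(4)
        y = conv.forward(x)
        np.testing.assert_allclose(y.feats, x.feats)
        np.testing.assert_array_equal(y.coords, x.coords)

    def test_single_point_full_kernel(self, rng):
        coords = np.array([[3, 3, 3, 0, 0]])
        feats = rng.normal(size=(1, 5))
        x = SparseFeatureMap(coords, feats)
        conv = SparseConv(5, 2, KernelOffsets.cubic(3), rng=rng)
        y = conv.forward(x)
        # the only contribution at the occupied output is the centre tap W_0
        centre = np.flatnonzero(np.all(conv.offsets.offsets == 0, axis=1))[0]
        np.testing.assert_allclose(y.feats[0], conv.weight.data[centre] @ feats[0])

    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_dense_oracle(self, rng, stride):
        for _ in range(20):
            x = random_sparse(rng, 40, 3)
            conv = SparseConv(3, 4, KernelOffsets.cubic(3), stride=stride, rng=rng)
            y = conv.forward(x)
            dense = dense_conv(dense_embed(x), conv.weight.data, conv.offsets, stride)
            for c, f in zip(y.coords, y.feats):
                np.testing.assert_allclose(f, dense[c[0], c[1], c[2]], atol=1e-10)

    def test_linearity_in_input(self, rng):
        x = random_sparse(rng, 25, 3)
        conv = SparseConv(3, 4, KernelOffsets.cubic(3), rng=rng)
        a = SparseFeatureMap(x.coords, 2.0 * x.feats)
        y1 = conv.forward(x).feats
        y2 = conv.forward(a).feats
        np.testing.assert_allclose(y2, 2.0 * y1, atol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        x = random_sparse(rng, 10, 3)
        with pytest.raises(ValueError, match="channel mismatch"):
            SparseConv(5, 2, KernelOffsets.cubic(3)).forward(x)

    def test_partition_key_blocks_cross_batch_mixing(self, rng):
        base = rng.integers(0, 6, size=(20, 3))
        c0 = np.concatenate([base, np.zeros((20, 2), int)], axis=1)
        c1 = c0.copy()
        c1[:, 4] = 1  # same spatial coords, different batch
        both = SparseFeatureMap(
            np.vstack([np.unique(c0, axis=0), np.unique(c1, axis=0)]),
            np.vstack([np.ones((len(np.unique(c0, axis=0)), 2)),
                       np.zeros((len(np.unique(c1, axis=0)), 2))]),
        )
        conv = SparseConv(2, 2, KernelOffsets.cubic(3), rng=rng)
        y = conv.forward(both)
        zero_rows = y.coords[:, 4] == 1
        np.testing.assert_allclose(y.feats[zero_rows], 0.0, atol=1e-12)


class TestSparseConvTranspose:
    def test_identity_kernel(self, rng):
        x = random_sparse(rng, 20, 3)
        tconv = SparseConvTranspose(3, 3, KernelOffsets.identity(), stride=1, rng=rng)
        tconv.weight.data[0] = np.eye(3)
        y = tconv.forward(x, out_coords=x.coords)
        np.testing.assert_allclose(y.feats, x.feats)

    def test_adjoint_identity(self, rng):
        """⟨conv(x), y⟩ = ⟨x, convT(y)⟩ with convT carrying the W_iᵀ."""
        for stride in (1, 2):
            x = random_sparse(rng, 35, 3)
            conv = SparseConv(3, 4, KernelOffsets.cubic(3), stride=stride, rng=rng)
            cx = conv.forward(x)
            y = SparseFeatureMap(cx.coords, rng.normal(size=cx.feats.shape))
            tconv = SparseConvTranspose(4, 3, KernelOffsets.cubic(3), stride=stride)
            tconv.weight.data = np.transpose(conv.weight.data, (0, 2, 1)).copy()
            ty = tconv.forward(y, out_coords=x.coords)
            lhs = float(np.sum(cx.feats * y.feats))
            rhs = float(np.sum(x.feats * ty.feats))
            assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_upsample_covers_exactly_kernel_image(self, rng):
        coarse = SparseFeatureMap(np.array([[1, 1, 1, 0, 0]]), np.ones((1, 2)))
        fine_coords = np.unique(
            np.concatenate(
                [rng.integers(0, 5, size=(60, 3)), np.zeros((60, 2), int)], axis=1
            ),
            axis=0,
        )
        tconv = SparseConvTranspose(2, 2, KernelOffsets.cubic(3), stride=2, rng=rng)
        y = tconv.forward(coarse, out_coords=fine_coords)
        image = {
            tuple(np.array([1, 1, 1]) * 2 + off[:3]): k
            for k, off in enumerate(tconv.offsets.offsets)
        }
        for c, f in zip(y.coords, y.feats):
            k = image.get(tuple(c[:3]))
            if k is None:  # outside the receptive image: strictly zero
                np.testing.assert_allclose(f, 0.0, atol=1e-12)
            else:
                np.testing.assert_allclose(f, tconv.weight.data[k] @ coarse.feats[0])


class TestNormAndActivation:
    def test_constant_input_train_mode_zero_before_affine(self):
        x = SparseFeatureMap(
            np.array([[0, 0, 0, 0, 0], [1, 0, 0, 0, 0]]), np.full((2, 3), 7.0)
        )
        bn = BatchNorm(3)
        y = bn.forward(x, training=True)
        np.testing.assert_allclose(y.feats, 0.0, atol=1e-9)

    def test_relu_clamps(self):
        x = SparseFeatureMap(np.array([[0, 0, 0, 0, 0]]), np.array([[-1.0, 2.0]]))
        np.testing.assert_allclose(relu(x).feats, [[0.0, 2.0]])

    def test_eval_mode_uses_running_stats(self, rng):
        x = random_sparse(rng, 30, 3)
        bn = BatchNorm(3, momentum=0.5)
        bn.forward(x, training=True)
        y = bn.forward(x, training=False)
        expected = (x.feats - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
        np.testing.assert_allclose(y.feats, expected, atol=1e-9)

    def test_zero_rows_raise(self):
        x = SparseFeatureMap(np.zeros((0, 5)), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            BatchNorm(3).forward(x)


class TestBasicBlock:
    def test_zero_convs_identity_norm_gives_relu(self, rng):
        x = random_sparse(rng, 25, 4)
        blk = BasicBlock(4, 4, rng=rng)
        blk.conv1.weight.data[:] = 0.0
        blk.conv2.weight.data[:] = 0.0
        y = blk.forward(x, training=False)
        np.testing.assert_allclose(y.feats, np.maximum(x.feats, 0.0), atol=1e-9)

    def test_preserves_coordinates(self, rng):
        x = random_sparse(rng, 25, 4)
        y = BasicBlock(4, 6, rng=rng).forward(x)
        np.testing.assert_array_equal(y.coords, x.coords)

    def test_matches_dense_resnet_oracle(self, rng):
        """Full-grid input: block output equals dense conv/norm-free ResNet."""
        grid = 4
        coords = np.array([[i, j, k, 0, 0] for i in range(grid) for j in range(grid) for k in range(grid)])
        feats = rng.normal(size=(len(coords), 3))
        x = SparseFeatureMap(coords, feats)
        blk = BasicBlock(3, 3, rng=rng)
        # freeze norms to identity so the oracle is a pure conv/relu network
        for bn in (blk.bn1, blk.bn2):
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 1.0 - bn.eps
        y = blk.forward(x, training=False)
        d = dense_embed(x, grid)
        h = dense_conv(d, blk.conv1.weight.data, blk.conv1.offsets)
        h = np.maximum(h, 0.0)
        h = dense_conv(h, blk.conv2.weight.data, blk.conv2.offsets)
        out = np.maximum(h + d, 0.0)
        for c, f in zip(y.coords, y.feats):
            np.testing.assert_allclose(f, out[c[0], c[1], c[2]], atol=1e-6)


class TestGradients:
    """Tape gradients vs central finite differences."""

    def _finite_diff(self, param, forward_loss, eps=1e-6):
        grad = np.zeros_like(param.data)
        it = np.nditer(param.data, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = param.data[idx]
            param.data[idx] = orig + eps
            lp = forward_loss()
            param.data[idx] = orig - eps
            lm = forward_loss()
            param.data[idx] = orig
            grad[idx] = (lp - lm) / (2 * eps)
            it.iternext()
        return grad

    def test_conv_weight_gradient(self, rng):
        x = random_sparse(rng, 15, 2)
        conv = SparseConv(2, 2, KernelOffsets.cubic(3), rng=rng)

        def loss():
            return float((conv.forward(x).feats ** 2).sum()) / 2.0

        tape = Tape()
        y = conv.forward(x, tape=tape)
        conv.weight.grad[:] = 0.0
        tape.backward(y, y.feats.copy())
        fd = self._finite_diff(conv.weight, loss)
        np.testing.assert_allclose(conv.weight.grad, fd, atol=1e-4)

    def test_batchnorm_input_gradient(self, rng):
        feats = rng.normal(size=(10, 2))
        coords = np.zeros((10, 5), dtype=int)
        coords[:, 0] = np.arange(10)
        bn = BatchNorm(2)

        x = SparseFeatureMap(coords, feats.copy())
        tape = Tape()
        y = bn.forward(x, training=True, tape=tape)
        tape.backward(y, y.feats.copy())
        analytic = x.grad.copy()

        eps = 1e-6
        fd = np.zeros_like(x.feats)
        for i in range(x.feats.shape[0]):
            for j in range(x.feats.shape[1]):
                for s, out in ((eps, 1), (-eps, -1)):
                    f2 = x.feats.copy()
                    f2[i, j] += s
                    x2 = SparseFeatureMap(x.coords, f2)
                    l2 = float((bn.forward(x2, training=True).feats ** 2).sum()) / 2.0
                    fd[i, j] += out * l2
                fd[i, j] /= 2 * eps
        np.testing.assert_allclose(analytic, fd, atol=1e-4)


class TestHelpers:
    def test_downsample_coords_floor_division(self):
        coords = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 0, 0], [2, 2, 2, 0, 0]])
        coarse = downsample_coords(coords, 2)
        assert {tuple(c) for c in coarse} == {(0, 0, 0, 0, 0), (1, 1, 1, 0, 0)}

    def test_kernel_map_bijective_per_offset(self, rng):
        x = random_sparse(rng, 30, 1)
        maps = build_kernel_map(x.coords, x.coords, KernelOffsets.cubic(3), 1)
        for ii, oo in maps:
            assert len(np.unique(ii)) == len(ii)
            assert len(np.unique(oo)) == len(oo)
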