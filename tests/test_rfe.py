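"""Block partition, strip extraction, fusion assembly and the full RFE layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfeunet import (PartitionError, RFELayer, assemble_fusion_input, correlate,
                     extract_strips, init_rfe_params, partition_blocks, reassemble_blocks,
                     rfe_block_transform, rfe_layer_forward, rfe_layer_reference)
from rfeunet.nn import SGD, Tensor
from rfeunet.nn.tensor import gelu_np


@pytest.fixture
def worked_example():
    """1x4x4 map whose entry at (i, j) is 10*i + j, mirroring the N(i, j) grid."""
    return (10 * np.arange(4)[:, None] + np.arange(4)[None, :]).astype(float)[None]


class TestPartition:
    def test_quadrants_of_worked_example(self, worked_example):
        g = partition_blocks(worked_example)
        np.testing.assert_array_equal(g.blocks["A"][0], [[0, 1], [10, 11]])
        np.testing.assert_array_equal(g.blocks["B"][0], [[2, 3], [12, 13]])
        np.testing.assert_array_equal(g.blocks["C"][0], [[20, 21], [30, 31]])
        np.testing.assert_array_equal(g.blocks["D"][0], [[22, 23], [32, 33]])

    def test_smallest_even_case(self):
        g = partition_blocks(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        assert [g.blocks[b].item() for b in "ABCD"] == [1.0, 2.0, 3.0, 4.0]

    def test_reassembly_is_inverse(self, rng):
        fmap = rng.normal(size=(3, 6, 6))
        g = partition_blocks(fmap)
        np.testing.assert_array_equal(reassemble_blocks(g.blocks), fmap)

    @pytest.mark.parametrize("shape,dim", [((1, 5, 4), "height"), ((1, 4, 7), "width")])
    def test_odd_dimension_rejected(self, shape, dim, rng):
        with pytest.raises(PartitionError, match=dim):
            partition_blocks(rng.normal(size=shape))


class TestStrips:
    def test_strips_of_block_a(self, worked_example):
        s = extract_strips(partition_blocks(worked_example).blocks["A"])
        np.testing.assert_array_equal(s.rows[0][0], [[0, 1]])
        np.testing.assert_array_equal(s.rows[1][0], [[10, 11]])
        np.testing.assert_array_equal(s.cols[0][0], [[0], [10]])
        np.testing.assert_array_equal(s.cols[1][0], [[1], [11]])

    def test_degenerate_single_element(self):
        s = extract_strips(np.array([[[5.0]]]))
        assert s.rows[0].item() == 5.0 and s.cols[0].item() == 5.0

    def test_concatenation_reconstructs_block(self, rng):
        block = rng.normal(size=(2, 3, 5))
        s = extract_strips(block)
        np.testing.assert_array_equal(np.concatenate(s.rows, axis=1), block)
        np.testing.assert_array_equal(np.concatenate(s.cols, axis=2), block)


class TestAssembly:
    def test_worked_example_operand_order(self, worked_example):
        asm = assemble_fusion_input(partition_blocks(worked_example), "A", "row", 0)
        # base A row-major, then first rows of B, C, D
        np.testing.assert_array_equal(asm.flat[0], [0, 1, 10, 11, 2, 3, 20, 21, 22, 23])
        assert asm.stacked_shape == (5, 2)

    def test_minimal_length(self, rng):
        g = partition_blocks(rng.normal(size=(1, 2, 2)))
        assert assemble_fusion_input(g, "C", "row", 0).flat.shape == (1, 4)
        assert assemble_fusion_input(g, "C", "col", 0).flat.shape == (1, 4)

    def test_column_assembly_matches_hand_gather(self, rng):
        fmap = rng.normal(size=(1, 6, 6))
        g = partition_blocks(fmap)
        asm = assemble_fusion_input(g, "A", "col", 1)
        assert asm.flat.shape == (1, 18)
        expected = list(fmap[0, :3, :3].ravel())
        for oi, oj in ((0, 1), (1, 0), (1, 1)):  # B, C, D quadrant offsets
            expected += [fmap[0, oi * 3 + i, oj * 3 + 1] for i in range(3)]
        np.testing.assert_allclose(asm.flat[0], expected)

    def test_strip_index_out_of_range(self, worked_example):
        g = partition_blocks(worked_example)
        with pytest.raises(IndexError):
            assemble_fusion_input(g, "A", "row", 2)


class TestCorrelate:
    def test_zero_weights_give_zero(self, worked_example):
        asm = assemble_fusion_input(partition_blocks(worked_example), "A", "row", 0)
        np.testing.assert_array_equal(correlate(asm, np.zeros((10, 4))), 0.0)

    def test_unit_weights_give_assembly_sum(self):
        fmap = np.arange(16, dtype=float).reshape(1, 4, 4)
        asm = assemble_fusion_input(partition_blocks(fmap), "A", "row", 0)
        # brute-force gather of the ten operands: 0,1,4,5 | 2,3 | 8,9 | 10,11
        expected = sum([0, 1, 4, 5, 2, 3, 8, 9, 10, 11])
        np.testing.assert_allclose(correlate(asm, np.ones((10, 4))), expected)

    def test_matches_per_element_loop(self, rng):
        fmap = rng.normal(size=(2, 4, 4))
        asm = assemble_fusion_input(partition_blocks(fmap), "B", "row", 1)
        weights = rng.normal(size=(10, 4))
        out = correlate(asm, weights)
        for c in range(2):
            for e in range(4):
                m = sum(asm.flat[c, t] * weights[t, e] for t in range(10))
                assert out[c, e // 2, e % 2] == pytest.approx(m, rel=1e-12)

    def test_shape_mismatch_rejected(self, worked_example):
        asm = assemble_fusion_input(partition_blocks(worked_example), "A", "row", 0)
        with pytest.raises(ValueError, match="weights shape"):
            correlate(asm, np.ones((9, 4)))


class TestBlockTransform:
    def test_residual_identity_with_zero_weights(self, rng):
        fmap = rng.normal(size=(3, 4, 4))
        g = partition_blocks(fmap)
        params = init_rfe_params(2, 2, rng=rng, weight_sigma=0.0)
        out = rfe_block_transform(g, "D", params)
        np.testing.assert_allclose(out, g.blocks["D"], atol=1e-12)

    def test_matches_manual_variant_average(self, rng):
        """Mean of the h+w correlate variants, MLP, residual — by hand, 7x7 blocks."""
        fmap = rng.normal(size=(1, 14, 14))
        g = partition_blocks(fmap)
        params = init_rfe_params(7, 7, rng=rng, weight_sigma=0.1)
        variants = [correlate(assemble_fusion_input(g, "A", "row", k),
                              params.correlation[("A", "row")]) for k in range(7)]
        variants += [correlate(assemble_fusion_input(g, "A", "col", k),
                               params.correlation[("A", "col")]) for k in range(7)]
        assert len(variants) == 14
        agg = np.mean(variants, axis=0).reshape(1, 49)
        w1, b1, w2, b2 = params.mlp["A"]
        manual = (gelu_np(agg @ w1 + b1) @ w2 + b2).reshape(1, 7, 7) + g.blocks["A"]
        np.testing.assert_allclose(rfe_block_transform(g, "A", params), manual, atol=1e-10)

    def test_two_by_two_has_four_variants(self, rng):
        """For 2x2 blocks the four manual variants reproduce the transform."""
        fmap = rng.normal(size=(2, 4, 4))
        g = partition_blocks(fmap)
        params = init_rfe_params(2, 2, rng=rng, weight_sigma=0.3)
        variants = [correlate(assemble_fusion_input(g, "B", d, k), params.correlation[("B", d)])
                    for d, n in (("row", 2), ("col", 2)) for k in range(n)]
        assert len(variants) == 4
        agg = np.mean(variants, axis=0).reshape(2, 4)
        w1, b1, w2, b2 = params.mlp["B"]
        manual = (gelu_np(agg @ w1 + b1) @ w2 + b2).reshape(2, 2, 2) + g.blocks["B"]
        np.testing.assert_allclose(rfe_block_transform(g, "B", params), manual, atol=1e-10)


class TestLayer:
    def test_scalar_oracle_agreement(self, rng):
        for _ in range(5):
            c = int(rng.integers(1, 4))
            h = 2 * int(rng.integers(1, 4))
            w = 2 * int(rng.integers(1, 4))
            fmap = rng.normal(size=(c, h, w))
            params = init_rfe_params(h // 2, w // 2, rng=rng, weight_sigma=0.2)
            np.testing.assert_allclose(
                rfe_layer_forward(fmap, params), rfe_layer_reference(fmap, params), atol=1e-9
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.integers(1, 4), hh=st.integers(1, 5), ww=st.integers(1, 5),
           seed=st.integers(0, 2**31 - 1))
    def test_shape_preserved(self, c, hh, ww, seed):
        rng = np.random.default_rng(seed)
        fmap = rng.normal(size=(c, 2 * hh, 2 * ww))
        params = init_rfe_params(hh, ww, rng=rng)
        assert rfe_layer_forward(fmap, params).shape == fmap.shape

    def test_channel_permutation_equivariance(self, rng):
        fmap = rng.normal(size=(5, 6, 6))
        params = init_rfe_params(3, 3, rng=rng, weight_sigma=0.15)
        perm = rng.permutation(5)
        out_then_perm = rfe_layer_forward(fmap, params)[perm]
        perm_then_out = rfe_layer_forward(fmap[perm], params)
        np.testing.assert_allclose(out_then_perm, perm_then_out, atol=1e-12)

    def test_block_size_mismatch_rejected(self, rng):
        params = init_rfe_params(2, 2, rng=rng)
        with pytest.raises(ValueError, match="blocks"):
            rfe_layer_forward(rng.normal(size=(1, 6, 6)), params)

    def test_trainable_layer_near_identity_and_learns(self, rng):
        layer = RFELayer(2, 2, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 3, 4, 4))
        y0 = layer(Tensor(x)).numpy()
        np.testing.assert_allclose(y0, x, atol=0.05)  # near-identity at init

        target = rng.normal(size=x.shape)
        opt = SGD(layer.parameters(), lr=0.05, momentum=0.0, weight_decay=0.0)
        losses = []
        for _ in range(5):
            out = layer(Tensor(x))
            loss = ((out - Tensor(target)) ** 2).mean()
            losses.append(loss.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0]
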