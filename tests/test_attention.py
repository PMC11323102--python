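"""Class-specific attention: loop oracles, algebraic properties, block contract."""

import numpy as np
import pytest

from ccgan.attention import (AttentionBlock, AttentionConfig, AttentionParams,
                             apply_attention, attention_map, class_scores,
                             class_semantic_map, transform)
from ccgan.autodiff import Tensor

CFG = AttentionConfig(channels_per_class=3, num_classes=2)


def _params(rng, cin, cout, bn=False):
    p = AttentionParams(
        depthwise=rng.standard_normal((3, 3, cin)) * 0.5,
        pointwise=rng.standard_normal((cin, cout)) * 0.5,
        bias=rng.standard_normal(cout) * 0.1,
    )
    if bn:
        p.bn_mean = rng.standard_normal(cout) * 0.1
        p.bn_var = rng.random(cout) + 0.5
        p.bn_gamma = rng.random(cout) + 0.5
        p.bn_beta = rng.standard_normal(cout) * 0.1
    return p


class TestTransform:
    def test_identity_configuration(self, rng):
        """Centre-tap depthwise + channel-replicating pointwise reproduce the input."""
        cfg = AttentionConfig(channels_per_class=1, num_classes=2)
        inp = rng.random((4, 4, 2))  # non-negative so ReLU is transparent
        dw = np.zeros((3, 3, 2))
        dw[1, 1, :] = 1.0
        params = AttentionParams(depthwise=dw, pointwise=np.eye(2), bias=np.zeros(2))
        np.testing.assert_allclose(transform(inp, cfg, params), inp, atol=1e-12)

    def test_output_nonnegative(self, rng):
        params = _params(rng, 4, CFG.out_channels, bn=True)
        out = transform(rng.standard_normal((5, 5, 4)), CFG, params)
        assert out.min() >= 0.0

    def test_matches_loop_oracle(self, rng):
        inp = rng.standard_normal((4, 4, 2))
        params = _params(rng, 2, CFG.out_channels, bn=True)
        got = transform(inp, CFG, params)
        xp = np.pad(inp, ((1, 1), (1, 1), (0, 0)))
        expected = np.zeros((4, 4, CFG.out_channels))
        for i in range(4):
            for j in range(4):
                dw = np.zeros(2)
                for dy in range(3):
                    for dx in range(3):
                        dw += xp[i + dy, j + dx] * params.depthwise[dy, dx]
                pre = dw @ params.pointwise + params.bias
                pre = (pre - params.bn_mean) / np.sqrt(params.bn_var + params.bn_eps)
                expected[i, j] = np.maximum(pre * params.bn_gamma + params.bn_beta, 0)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_nonfinite_rejected(self):
        bad = np.full((2, 2, 2), np.inf)
        with pytest.raises(ValueError, match="non-finite"):
            transform(bad, CFG, _params(np.random.default_rng(0), 2, CFG.out_channels))


class TestClassScores:
    def test_all_ones(self):
        cfg = AttentionConfig(2, 2)
        np.testing.assert_allclose(class_scores(np.ones((3, 3, 4)), cfg), [1.0, 1.0])

    def test_separated_groups(self):
        cfg = AttentionConfig(2, 2)
        fmap = np.zeros((3, 3, 4))
        fmap[:, :, 2:] = 5.0
        np.testing.assert_allclose(class_scores(fmap, cfg), [0.0, 5.0])

    def test_matches_loop_oracle(self, rng):
        fmap = rng.random((4, 4, 6))
        got = class_scores(fmap, CFG)
        for j in range(2):
            acc = 0.0
            for k in range(3):
                acc += fmap[:, :, j * 3 + k].max()
            assert got[j] == acc / 3

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            class_scores(rng.random((4, 4, 5)), CFG)

    def test_spatial_permutation_invariance(self, rng):
        fmap = rng.random((4, 4, 6))
        flat = fmap.reshape(16, 6)[rng.permutation(16)]
        np.testing.assert_allclose(
            class_scores(fmap, CFG), class_scores(flat.reshape(4, 4, 6), CFG)
        )


class TestSemanticMap:
    def test_x_equals_one_is_identity(self, rng):
        cfg = AttentionConfig(1, 3)
        fmap = rng.random((4, 4, 3))
        np.testing.assert_allclose(class_semantic_map(fmap, cfg), fmap)

    def test_group_mean(self):
        cfg = AttentionConfig(2, 2)
        fmap = np.concatenate(
            [2 * np.ones((3, 3, 1)), 4 * np.ones((3, 3, 1)), np.zeros((3, 3, 2))], axis=2
        )
        out = class_semantic_map(fmap, cfg)
        np.testing.assert_allclose(out[:, :, 0], 3.0)

    def test_matches_loop_oracle(self, rng):
        fmap = rng.random((4, 4, 6))
        got = class_semantic_map(fmap, CFG)
        for j in range(2):
            np.testing.assert_allclose(got[:, :, j], fmap[:, :, 3 * j : 3 * j + 3].mean(axis=2))


class TestAttentionMap:
    def test_single_class_unit_score(self, rng):
        semantic = rng.random((4, 4, 1))
        np.testing.assert_allclose(attention_map([1.0], semantic), semantic[:, :, 0])

    def test_zero_scores(self, rng):
        np.testing.assert_array_equal(attention_map(np.zeros(3), rng.random((4, 4, 3))), 0.0)

    def test_matches_loop_oracle(self, rng):
        scores = rng.random(3)
        semantic = rng.random((5, 5, 3))
        got = attention_map(scores, semantic)
        expected = sum(scores[j] * semantic[:, :, j] for j in range(3)) / 3
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="planes"):
            attention_map(np.ones(2), rng.random((4, 4, 3)))


class TestApplyAttention:
    def test_unit_map_identity(self, rng):
        inp = rng.random((4, 4, 5))
        np.testing.assert_array_equal(apply_attention(inp, np.ones((4, 4))), inp)

    def test_zero_map(self, rng):
        np.testing.assert_array_equal(
            apply_attention(rng.random((4, 4, 5)), np.zeros((4, 4))), 0.0
        )

    def test_matches_loop_oracle(self, rng):
        inp, att = rng.random((3, 3, 2)), rng.random((3, 3))
        got = apply_attention(inp, att)
        for c in range(2):
            np.testing.assert_allclose(got[:, :, c], inp[:, :, c] * att)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="spatial"):
            apply_attention(rng.random((4, 4, 2)), np.ones((3, 3)))


def test_scaling_degrees(rng):
    """Scores scale as lambda, semantic as lambda, attention map as lambda^2."""
    fmap = rng.random((4, 4, 6))
    lam = 2.5
    s1, s2 = class_scores(fmap, CFG), class_scores(lam * fmap, CFG)
    np.testing.assert_allclose(s2, lam * s1)
    m1, m2 = class_semantic_map(fmap, CFG), class_semantic_map(lam * fmap, CFG)
    np.testing.assert_allclose(m2, lam * m1)
    np.testing.assert_allclose(
        attention_map(s2, m2), lam**2 * attention_map(s1, m1), rtol=1e-10
    )


class TestAttentionBlock:
    def test_output_shape_preserved(self, rng):
        block = AttentionBlock(8, AttentionConfig(2, 2), np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        assert block(x).shape == x.shape

    def test_block_matches_functional_pipeline(self, rng):
        """The trainable block equals the numpy reference composition."""
        cfg = AttentionConfig(2, 2)
        block = AttentionBlock(4, cfg, np.random.default_rng(1)).eval()
        x = rng.standard_normal((6, 6, 4)).astype(np.float32)
        out = block(Tensor(x[None])).data[0]
        params = AttentionParams(
            depthwise=block.conv.depthwise.data,
            pointwise=block.conv.pointwise.weight.data[0, 0],
            bias=block.conv.pointwise.bias.data,
            bn_mean=block.bn.running_mean,
            bn_var=block.bn.running_var,
            bn_gamma=block.bn.gamma.data,
            bn_beta=block.bn.beta.data,
        )
        transformed = transform(x, cfg, params)
        att = attention_map(class_scores(transformed, cfg),
                            class_semantic_map(transformed, cfg))
        np.testing.assert_allclose(out, apply_attention(x, att), rtol=1e-4, atol=1e-5)
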