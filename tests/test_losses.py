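"""Loss functions against naive scalar oracles and their degenerate limits."""

import itertools
import math

import numpy as np
import pytest

from ccgan.autodiff import Tensor
from ccgan.losses import (CorrectionMaps, EmbeddingBatch, adversarial_seg_loss,
                          corrected_mask, correction_maps, final_objective,
                          l1_seg_loss, l1_seg_loss_t, scoln_contrastive_loss,
                          scoln_contrastive_loss_t, two_c_loss, two_c_loss_t)


def _batch(rng, n=4, d=8, n_classes=2, t=3.0):
    proj = rng.standard_normal((n, d))
    proj /= np.linalg.norm(proj, axis=1, keepdims=True)
    embed = {c: rng.standard_normal(d) for c in range(n_classes)}
    labels = rng.integers(0, n_classes, n)
    return EmbeddingBatch(proj, embed, labels, temperature=t)


def _two_c_oracle(batch: EmbeddingBatch, i: int) -> float:
    """Naive pairwise evaluation of the conditional contrastive loss."""
    proj, labels, t = batch.image_proj, batch.labels, batch.temperature
    num = math.exp(proj[i] @ batch.class_embed[int(labels[i])] / t)
    den = num
    for j in range(len(labels)):
        if j == i:
            continue
        s = math.exp(proj[i] @ proj[j] / t)
        den += s
        if labels[j] == labels[i]:
            num += s
    return -math.log(num / den)


class TestTwoCLoss:
    def test_single_sample_is_zero(self, rng):
        batch = _batch(rng, n=1)
        assert two_c_loss(batch) == pytest.approx(0.0, abs=1e-12)

    def test_same_class_batch_is_zero(self, rng):
        batch = _batch(rng, n=5)
        batch.labels[:] = 1
        assert two_c_loss(batch) == pytest.approx(0.0, abs=1e-10)

    def test_matches_pairwise_oracle(self, rng):
        batch = _batch(rng, n=4, d=8, t=3.0)
        expected = np.mean([_two_c_oracle(batch, i) for i in range(4)])
        assert two_c_loss(batch) == pytest.approx(expected, abs=1e-6)

    def test_nonnegative_on_random_batches(self, rng):
        for _ in range(1000):
            batch = _batch(rng, n=int(rng.integers(1, 9)), d=4,
                           n_classes=int(rng.integers(2, 4)))
            assert two_c_loss(batch) >= -1e-9

    def test_class_relabelling_invariance(self, rng):
        batch = _batch(rng, n=6, n_classes=3)
        perm = np.array([2, 0, 1])
        permuted = EmbeddingBatch(
            batch.image_proj,
            {int(perm[c]): v for c, v in batch.class_embed.items()},
            perm[batch.labels],
            batch.temperature,
        )
        assert two_c_loss(batch) == pytest.approx(two_c_loss(permuted), abs=1e-10)

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError, match="temperature"):
            _batch(rng, t=0.0)

    def test_autodiff_twin_matches(self, rng):
        batch = _batch(rng, n=6, d=8, n_classes=3)
        embed = np.stack([batch.class_embed[c] for c in range(3)])
        got = two_c_loss_t(
            Tensor(batch.image_proj.astype(np.float32)),
            Tensor(embed.astype(np.float32)),
            batch.labels,
            batch.temperature,
        ).item()
        assert got == pytest.approx(two_c_loss(batch), abs=1e-5)

    def test_anchor_argument(self, rng):
        batch = _batch(rng, n=4)
        assert two_c_loss(batch, anchor=2) == pytest.approx(_two_c_oracle(batch, 2), abs=1e-8)


class TestL1SegLoss:
    def test_identical_maps(self, rng):
        pred = rng.random((6, 6, 2))
        assert l1_seg_loss(pred, pred) == 0.0

    def test_constant_offset(self, rng):
        target = rng.random((6, 6, 2))
        assert l1_seg_loss(target + 0.5, target) == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        pred, target = rng.random((4, 4, 2)), rng.random((4, 4, 2))
        expected = np.mean([abs(pred[i, j, c] - target[i, j, c])
                            for i in range(4) for j in range(4) for c in range(2)])
        assert l1_seg_loss(pred, target) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            l1_seg_loss(rng.random((4, 4, 2)), rng.random((4, 4, 3)))

    def test_autodiff_twin(self, rng):
        pred, target = rng.random((4, 4, 2)), rng.random((4, 4, 2))
        got = l1_seg_loss_t(Tensor(pred.astype(np.float32)),
                            Tensor(target.astype(np.float32))).item()
        assert got == pytest.approx(l1_seg_loss(pred, target), abs=1e-6)


def test_adversarial_seg_loss():
    assert adversarial_seg_loss(1.0, 0.2, 1.0) == pytest.approx(1.2)
    assert adversarial_seg_loss(0.7, 0.0, 1.0) == pytest.approx(0.7)
    assert adversarial_seg_loss(0.3, 0.4, 10.0) == pytest.approx(4.3)


class TestScolnContrastive:
    def test_perfect_separation_limit(self):
        anchor = np.array([10.0, 0.0, 0.0])
        positives = np.tile(anchor * 10, (3, 1))
        negatives = np.tile([0.0, 10.0, 0.0], (3, 1))
        # dot similarity with a large scale: positives dominate, loss -> 0
        assert scoln_contrastive_loss(anchor, positives, negatives, sim="dot") < 1e-8

    def test_swapping_sets_increases_loss(self, rng):
        anchor = np.ones(4)
        positives = np.tile(anchor, (3, 1)) + rng.normal(0, 0.05, (3, 4))
        negatives = -np.tile(anchor, (3, 1)) + rng.normal(0, 0.05, (3, 4))
        good = scoln_contrastive_loss(anchor, positives, negatives)
        bad = scoln_contrastive_loss(anchor, negatives, positives)
        assert bad > good

    def test_matches_scalar_loop_oracle(self, rng):
        anchor = rng.standard_normal(8)
        pos = rng.standard_normal((3, 8))
        neg = rng.standard_normal((3, 8))
        got = scoln_contrastive_loss(anchor, pos, neg, sim="dot")
        sp = sum(math.exp(anchor @ p) for p in pos)
        sn = sum(math.exp(anchor @ n) for n in neg)
        assert got == pytest.approx(-math.log(sp / (sp + sn)), abs=1e-8)

    def test_empty_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            scoln_contrastive_loss(np.ones(3), np.empty((0, 3)), rng.random((2, 3)))

    def test_as_printed_form(self, rng):
        """The uncorrected published form is log(pos softmax) + log(neg softmax)."""
        anchor = rng.standard_normal(5)
        pos, neg = rng.standard_normal((2, 5)), rng.standard_normal((3, 5))
        got = scoln_contrastive_loss(anchor, pos, neg, sim="dot", as_printed=True)
        sp = sum(math.exp(anchor @ p) for p in pos)
        sn = sum(math.exp(anchor @ n) for n in neg)
        assert got == pytest.approx(math.log(sp / (sp + sn)) + math.log(sn / (sp + sn)),
                                    abs=1e-8)

    def test_autodiff_twin(self, rng):
        anchor = rng.standard_normal(6).astype(np.float32)
        pos = rng.standard_normal((3, 6)).astype(np.float32)
        neg = rng.standard_normal((2, 6)).astype(np.float32)
        got = scoln_contrastive_loss_t(Tensor(anchor), Tensor(pos), Tensor(neg)).item()
        assert got == pytest.approx(scoln_contrastive_loss(anchor, pos, neg), abs=1e-5)


class TestCorrectionMaps:
    def test_perfect_prediction_zero_maps(self, rng):
        g = (rng.random((6, 6)) > 0.8).astype(float)
        maps = correction_maps(g, g)
        assert maps.fn_map.sum() == 0 and maps.fp_map.sum() == 0

    def test_single_missed_pixel(self):
        g = np.zeros((4, 4))
        g[1, 2] = 1.0
        maps = correction_maps(np.zeros((4, 4)), g)
        assert maps.fn_map[1, 2] == 1.0
        assert maps.fn_map.sum() == 1.0
        assert maps.fp_map.sum() == 0.0

    def test_maps_partition_absolute_error(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(float)
        g = (rng.random((8, 8)) > 0.8).astype(float)
        maps = correction_maps(pred, g)
        np.testing.assert_allclose(maps.fn_map + maps.fp_map, np.abs(pred - g))
        assert np.all(maps.fn_map * maps.fp_map == 0)  # disjoint supports

    def test_out_of_range_prediction_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            correction_maps(np.full((2, 2), 1.5), np.zeros((2, 2)))


class TestFinalObjective:
    def test_zero_maps(self):
        maps = CorrectionMaps(np.zeros((3, 3)), np.zeros((3, 3)))
        assert final_objective(0.8, maps) == pytest.approx(0.8)

    def test_mean_counts(self):
        maps = CorrectionMaps(np.full((5, 5), 0.2), np.full((5, 5), 0.1))
        assert final_objective(1.0, maps) == pytest.approx(1.1)

    def test_raw_counts_option(self, rng):
        fn = (rng.random((4, 4)) > 0.5).astype(float)
        fp = np.zeros((4, 4))
        maps = CorrectionMaps(fn, fp)
        assert final_objective(0.0, maps, raw_counts=True) == pytest.approx(fn.sum())


class TestCorrectedMask:
    def test_zero_maps_is_plain_thresholding(self, rng):
        pred = rng.random((6, 6))
        maps = CorrectionMaps(np.zeros((6, 6)), np.zeros((6, 6)))
        np.testing.assert_array_equal(
            corrected_mask(pred, maps, 0.5), (pred >= 0.5).astype(int)
        )

    def test_oracle_maps_reproduce_truth(self, rng):
        for _ in range(20):
            pred = rng.random((5, 5))
            g = (rng.random((5, 5)) > 0.7).astype(float)
            maps = correction_maps(pred, g)
            np.testing.assert_array_equal(corrected_mask(pred, maps, 0.5), g.astype(int))

    def test_exhaustive_binary_preds_small_grid(self):
        g = np.array([[1, 0], [0, 1]], dtype=float)
        for bits in itertools.product([0, 1], repeat=4):
            pred = np.array(bits, dtype=float).reshape(2, 2)
            maps = correction_maps(pred, g)
            np.testing.assert_array_equal(corrected_mask(pred, maps, 0.5), g.astype(int))
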