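"""Confusion counts, Eq-style metrics, IoU loss: oracle and identity checks."""

import numpy as np
import pytest
from itertools import product

from consegnet import (Metrics, PixelConfusion, compute_metrics,
                       normalized_confusion_report, pixel_confusion, soft_iou_loss)
from consegnet.errors import DataError, ShapeError


def _brute_confusion(pred, gt):
    """Oracle: per-pixel python loop tally."""
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestPixelConfusion:
    def test_perfect_positive(self):
        ones = np.ones((4, 4), np.uint8)
        c = pixel_confusion(ones, ones)
        assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)

    def test_total_miss(self):
        c = pixel_confusion(np.zeros((4, 4), np.uint8), np.ones((4, 4), np.uint8))
        assert c.fn == 16 and c.tp == c.fp == c.tn == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_tally(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = pixel_confusion(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == _brute_confusion(pred, gt)
        assert c.total == 256

    def test_non_binary_rejected(self):
        with pytest.raises(DataError):
            pixel_confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestComputeMetrics:
    def test_hand_arithmetic_case(self):
        m = compute_metrics(PixelConfusion(tp=3, fp=1, fn=1, tn=10))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.dice == pytest.approx(0.75)
        assert m.iou == pytest.approx(0.6)

    def test_perfect_prediction_all_ones(self):
        m = compute_metrics(PixelConfusion(tp=10, fp=0, fn=0, tn=5))
        assert (m.precision, m.recall, m.dice, m.iou) == (1, 1, 1, 1)

    def test_empty_empty_convention(self):
        m = compute_metrics(PixelConfusion(0, 0, 0, 16))
        assert m.dice == m.iou == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_dice_iou_identity_and_order(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(300):
            tp, fp, fn, tn = rng.integers(0, 50, 4)
            m = compute_metrics(PixelConfusion(int(tp), int(fp), int(fn), int(tn)))
            if m.iou > 0:
                assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou))
            assert m.dice >= m.iou
            both_degenerate = m.dice in (0.0, 1.0)
            assert (m.dice == m.iou) == both_degenerate or m.iou == 0

    def test_scale_invariance(self):
        a = compute_metrics(PixelConfusion(3, 1, 1, 10))
        b = compute_metrics(PixelConfusion(30, 10, 10, 100))
        assert a == b

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            PixelConfusion(-1, 0, 0, 0)


class TestSoftIouLoss:
    def test_perfect_overlap_is_zero(self):
        m = np.array([[1, 0], [0, 1]], np.float32)
        assert soft_iou_loss(m, m) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_sets_near_one(self):
        p = np.array([1, 1, 0, 0], np.float32)
        g = np.array([0, 0, 1, 1], np.float32)
        eps = 1e-6
        assert soft_iou_loss(p, g, eps) == pytest.approx(1 - eps / (4 + eps))

    def test_partial_overlap_known_value(self):
        p = np.array([1, 1, 0, 0], np.float32)
        g = np.array([0, 1, 1, 0], np.float32)
        # intersection 1, union 3
        assert soft_iou_loss(p, g) == pytest.approx(2 / 3, abs=1e-5)

    def test_exhaustive_2x2_binary_grids_equal_one_minus_iou(self):
        # all 256 (pred, target) pairs of 2x2 binary grids, epsilon-limit
        for bits_p, bits_g in product(range(16), range(16)):
            p = np.array([(bits_p >> k) & 1 for k in range(4)], np.float32).reshape(2, 2)
            g = np.array([(bits_g >> k) & 1 for k in range(4)], np.float32).reshape(2, 2)
            inter = int((p * g).sum())
            union = int(p.sum() + g.sum() - inter)
            exact = 1.0 - (inter / union if union else 1.0)
            assert soft_iou_loss(p, g, epsilon=1e-9) == pytest.approx(exact, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            soft_iou_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_fractional_pred_differentiability_value(self):
        p = np.full((2, 2), 0.5, np.float32)
        g = np.ones((2, 2), np.float32)
        # I = 2, U = 2 + 4 - 2 = 4
        assert soft_iou_loss(p, g) == pytest.approx(0.5, abs=1e-6)


class TestNormalizedConfusion:
    def test_published_table_layout(self):
        table = normalized_confusion_report(PixelConfusion(tp=96, fn=4, fp=12, tn=88))
        assert np.allclose(table.values, [[96, 4], [12, 88]])
        assert np.allclose(table.sum(axis=1), [100, 100])  # class rows sum to 100%

    def test_perfect_prediction_identity(self):
        table = normalized_confusion_report(PixelConfusion(tp=5, fn=0, fp=0, tn=11))
        assert np.allclose(table.values, [[100, 0], [0, 100]])

    @pytest.mark.parametrize("seed", range(3))
    def test_rates_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((16, 16)) > 0.4).astype(np.uint8)
        gt = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        tp, fp, fn, tn = _brute_confusion(pred, gt)
        table = normalized_confusion_report(pixel_confusion(pred, gt))
        assert table.values[0, 0] == pytest.approx(100 * tp / (tp + fn))
        assert table.values[1, 1] == pytest.approx(100 * tn / (tn + fp))

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            normalized_confusion_report(PixelConfusion(tp=4, fn=0, fp=0, tn=0))
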