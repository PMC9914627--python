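"""Dice loss, thresholding, confusion counts and the six indicators."""

import numpy as np
import pytest

from prunet.metrics import (
    ConfusionCounts,
    DiceLossValue,
    aggregate_metrics,
    binarize,
    confusion_counts,
    metric_record,
    overlap_metrics,
    pixel_metrics,
    record_from_counts,
    records_to_table,
    soft_dice_loss,
)
from prunet.nn import Tensor


@pytest.fixture
def fixture_masks():
    """4x4 pair: GT has 3 foreground pixels, SR has 3, overlapping in 2.

    Enumerating pixel by pixel: TP=2, FP=1, FN=1, TN=12.
    """
    gt = np.zeros((4, 4), dtype=np.uint8)
    gt[1, 1] = gt[1, 2] = gt[2, 1] = 1
    sr = np.zeros((4, 4), dtype=np.uint8)
    sr[1, 1] = sr[1, 2] = sr[3, 3] = 1
    return sr, gt


class TestDiceLoss:
    def test_perfect_prediction_gives_zero(self):
        g = np.zeros((6, 6)); g[2:4, 2:4] = 1
        assert soft_dice_loss(g, g, epsilon=1e-9).ldice == pytest.approx(0.0, abs=1e-8)

    def test_disjoint_supports_give_one(self):
        p = np.zeros((4, 4)); p[0, 0] = 1.0
        g = np.zeros((4, 4)); g[3, 3] = 1
        assert soft_dice_loss(p, g, epsilon=1e-9).ldice == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_direct_substitution(self):
        """|GT|=4, |SR|=4, overlap 2 -> 1 - 2*2/(4+4) = 0.5."""
        g = np.zeros((4, 4)); g[0, :4] = 1
        p = np.zeros((4, 4)); p[0, 2:] = 1.0; p[1, :2] = 1.0
        assert soft_dice_loss(p, g, epsilon=1e-12).ldice == pytest.approx(0.5)

    def test_tensor_input_returns_differentiable_scalar(self):
        rng = np.random.default_rng(0)
        p = Tensor(rng.random((2, 1, 4, 4)), requires_grad=True)
        g = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.uint8)
        loss = soft_dice_loss(p, g)
        assert loss.shape == ()
        loss.backward()
        assert p.grad is not None and np.isfinite(p.grad).all()

    def test_loss_decreases_as_probs_approach_truth(self):
        rng = np.random.default_rng(1)
        g = (rng.random((8, 8)) > 0.6).astype(np.uint8)
        p = rng.random((8, 8))
        prev = soft_dice_loss(p, g, epsilon=1e-6).ldice
        for t in (0.25, 0.5, 0.75, 1.0):
            cur = soft_dice_loss(p + t * (g - p), g, epsilon=1e-6).ldice
            assert cur <= prev + 1e-12
            prev = cur

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            soft_dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_returns_epsilon_used(self):
        out = soft_dice_loss(np.full((2, 2), 0.5), np.ones((2, 2), np.uint8),
                             epsilon=2.0)
        assert isinstance(out, DiceLossValue) and out.epsilon == 2.0


class TestBinarize:
    def test_threshold_is_inclusive_at_boundary(self):
        assert binarize(np.array([0.5]), 0.5).tolist() == [1]
        assert binarize(np.full((3, 3), 0.6), 0.5).all()

    def test_raising_threshold_never_adds_foreground(self):
        probs = np.random.default_rng(2).random((16, 16))
        masks = [binarize(probs, t) for t in (0.2, 0.4, 0.6, 0.8)]
        for lo, hi in zip(masks, masks[1:]):
            assert not (hi & ~lo).any()

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 0.0)


class TestCountsAndRatios:
    def test_fixture_counts_by_enumeration(self, fixture_masks):
        sr, gt = fixture_masks
        c = confusion_counts(sr, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 12)
        assert c.total == 16

    def test_fixture_pixel_metrics_hand_evaluated(self, fixture_masks):
        sr, gt = fixture_masks
        acc, se, pre, f1 = pixel_metrics(confusion_counts(sr, gt))
        assert acc == pytest.approx(14 / 16)
        assert se == pre == pytest.approx(2 / 3)
        assert f1 == pytest.approx(2 / 3)

    def test_fixture_overlap_metrics_hand_evaluated(self, fixture_masks):
        sr, gt = fixture_masks
        js, dc = overlap_metrics(sr, gt)
        assert js == pytest.approx(2 / 4)
        assert dc == pytest.approx(2 / 3)

    def test_perfect_and_complement_predictions(self):
        gt = np.zeros((5, 5), np.uint8); gt[1:3, 1:3] = 1
        c = confusion_counts(gt, gt)
        assert c.fp == c.fn == 0
        assert pixel_metrics(c) == (1.0, 1.0, 1.0, 1.0)
        assert overlap_metrics(gt, gt) == (1.0, 1.0)
        comp = confusion_counts(1 - gt, gt)
        assert comp.tp == comp.tn == 0

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.full((2, 2), 0.7), np.zeros((2, 2)))

    def test_zero_over_zero_conventions(self):
        empty = np.zeros((4, 4), np.uint8)
        acc, se, pre, f1 = pixel_metrics(confusion_counts(empty, empty))
        assert (se, pre, f1) == (0.0, 0.0, 0.0)  # logged 0/0 convention
        assert overlap_metrics(empty, empty) == (1.0, 1.0)  # empty = empty


class TestAlgebraicIdentities:
    def _random_pairs(self, n=1000, size=8):
        rng = np.random.default_rng(7)
        for _ in range(n):
            yield ((rng.random((size, size)) > rng.uniform(0.2, 0.8)).astype(np.uint8),
                   (rng.random((size, size)) > rng.uniform(0.2, 0.8)).astype(np.uint8))

    def test_f1_equals_dice_on_single_pairs(self):
        """Eqs for F1 from counts and DC from overlaps coincide:
        both equal 2TP/(2TP+FP+FN)."""
        for sr, gt in self._random_pairs():
            c = confusion_counts(sr, gt)
            _, _, _, f1 = pixel_metrics(c)
            _, dc = overlap_metrics(sr, gt)
            if c.tp + c.fp + c.fn == 0:
                continue  # the one case where the conventions diverge
            assert f1 == pytest.approx(dc, abs=1e-12)

    def test_dice_jaccard_bijection(self):
        for sr, gt in self._random_pairs():
            js, dc = overlap_metrics(sr, gt)
            assert dc == pytest.approx(2 * js / (1 + js), abs=1e-12)
            assert js <= dc

    def test_all_metrics_within_unit_interval(self):
        for sr, gt in self._random_pairs(200):
            rec = metric_record(sr, gt)
            assert ((rec.as_array() >= 0) & (rec.as_array() <= 1)).all()


class TestAggregation:
    def test_mean_of_two_records(self):
        r1 = metric_record(np.ones((2, 2), np.uint8), np.ones((2, 2), np.uint8))
        gt = np.zeros((2, 2), np.uint8); gt[0] = 1
        sr = np.zeros((2, 2), np.uint8); sr[0, 0] = 1
        r2 = metric_record(sr, gt)
        agg = aggregate_metrics([r1, r2])
        assert agg.dc == pytest.approx((r1.dc + r2.dc) / 2)
        assert agg.scope == "per_image_mean"

    def test_identical_records_aggregate_to_themselves(self):
        gt = np.zeros((3, 3), np.uint8); gt[0] = 1
        recs = [metric_record(gt, gt) for _ in range(4)]
        assert np.allclose(aggregate_metrics(recs).as_array(),
                           recs[0].as_array())

    def test_pooled_scope_differs_from_per_image_mean(self):
        """A perfect small image plus an imperfect large one: the pooled-count
        Dice is pulled toward the large image, the per-image mean is not."""
        small_gt = np.ones((2, 2), np.uint8)
        big_gt = np.zeros((8, 8), np.uint8); big_gt[:4] = 1
        big_sr = np.zeros((8, 8), np.uint8); big_sr[:2] = 1
        recs = [metric_record(small_gt, small_gt), metric_record(big_sr, big_gt)]
        mean_dc = aggregate_metrics(recs).dc
        pooled = record_from_counts(
            confusion_counts(small_gt, small_gt) + confusion_counts(big_sr, big_gt))
        assert pooled.scope == "global"
        assert abs(pooled.dc - mean_dc) > 0.05

    def test_empty_aggregation_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics([])

    def test_table_layout_and_average_row(self):
        gt = np.zeros((3, 3), np.uint8); gt[1] = 1
        recs = [metric_record(gt, gt, fold=f) for f in (1, 2)]
        df = records_to_table(recs)
        assert list(df.columns) == ["k-Fold", "ACC", "PRE", "SE",
                                    "F1-Score", "JS", "DC"]
        assert df["k-Fold"].tolist() == ["1-fold", "2-fold", "Average"]
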