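"""Loss values, metric formulas, confusion counting and the paired t-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mfnet.autodiff import Tensor
from mfnet.losses_metrics import (MetricsReport,
                                  aggregate_mean_sd, bce_loss,
                                  confusion_counts, dice_loss, joint_loss,
                                  joint_loss_per_sample, metrics_from_counts,
                                  paired_ttest, segmentation_metrics)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class TestDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        y = (rng.random((8, 8)) > 0.5).astype(np.float64)
        assert dice_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_masks_approach_one(self):
        x = np.ones((8, 8))
        y = np.zeros((8, 8))
        assert dice_loss(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_hand_worked_overlap(self):
        # |X ∩ Y| = 2, |X| = |Y| = 3  ->  1 - 4/6
        x = np.zeros(8)
        y = np.zeros(8)
        x[:3] = 1
        y[1:4] = 1
        assert dice_loss(x, y) == pytest.approx(1 - 4 / 6, abs=1e-6)

    def test_range_and_differentiability(self, rng):
        x = Tensor(rng.random((4, 4)), requires_grad=True)
        y = (rng.random((4, 4)) > 0.5).astype(np.float64)
        loss = dice_loss(x, y)
        assert 0.0 <= loss.item() <= 1.0
        loss.backward()
        assert x.grad is not None and np.isfinite(x.grad).all()

    def test_agrees_with_dsc_on_binary_input(self, rng):
        for _ in range(20):
            x = (rng.random((16, 16)) > 0.6).astype(np.uint8)
            y = (rng.random((16, 16)) > 0.6).astype(np.uint8)
            dsc = segmentation_metrics(x.astype(float), y)[0]
            assert dice_loss(x.astype(float), y) == pytest.approx(
                1 - dsc / 100, abs=1e-4)


class TestBceLoss:
    def test_uniform_half_gives_ln2(self, rng):
        y = (rng.random((6, 6)) > 0.5).astype(np.float64)
        assert bce_loss(np.full((6, 6), 0.5), y) == pytest.approx(
            np.log(2), abs=1e-6)

    def test_perfect_prediction_is_near_zero(self, rng):
        y = (rng.random((6, 6)) > 0.5).astype(np.float64)
        assert bce_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_monotone_decreasing_in_confidence_on_positives(self):
        y = np.ones((3, 3))
        losses = [bce_loss(np.full((3, 3), p), y) for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]


class TestJointLoss:
    def test_is_exact_sum_of_components(self, rng):
        x = rng.random((5, 5))
        y = (rng.random((5, 5)) > 0.5).astype(np.float64)
        assert joint_loss(x, y) == pytest.approx(
            dice_loss(x, y) + bce_loss(x, y), abs=1e-10)

    def test_hand_worked_sum(self):
        x = np.zeros(8)
        y = np.zeros(8)
        x[:3] = 1
        y[1:4] = 1
        x_soft = np.where(x > 0, 1 - 1e-7, 1e-7)
        # dice 1 - 4/6 = 0.3333...; bce of 2 wrong pixels out of 8
        expected_dice = 1 / 3
        expected_bce = -(6 * np.log(1 - 1e-7) + 2 * np.log(1e-7)) / 8
        assert joint_loss(x_soft, y) == pytest.approx(
            expected_dice + expected_bce, rel=1e-4)

    def test_dominates_each_component(self, rng):
        x = rng.random((4, 4))
        y = (rng.random((4, 4)) > 0.5).astype(np.float64)
        assert joint_loss(x, y) >= max(dice_loss(x, y), bce_loss(x, y))

    def test_per_sample_batch_matches_singles(self, rng):
        x = rng.random((3, 1, 4, 4))
        y = (rng.random((3, 1, 4, 4)) > 0.5).astype(np.float64)
        vec = joint_loss_per_sample(x, y).data
        for i in range(3):
            assert vec[i] == pytest.approx(joint_loss(x[i], y[i]), abs=1e-10)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

def _bruteforce_counts(pred, gt):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and gt[i, j]:
                tp += 1
            elif pred[i, j] and not gt[i, j]:
                fp += 1
            elif not pred[i, j] and gt[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def test_confusion_trivial_identities(rng):
    g = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    same = confusion_counts(g, g)
    assert same.fp == same.fn == 0
    flipped = confusion_counts(1 - g, g)
    assert flipped.tp == flipped.tn == 0


def test_confusion_two_by_two_worked_example():
    pred = np.array([[1, 1], [1, 0]])
    gt = np.array([[1, 0], [1, 1]])
    c = confusion_counts(pred, gt)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 0)
    dsc, sen, jsc = metrics_from_counts(c)
    assert dsc == pytest.approx(66.67, abs=0.01)
    assert sen == pytest.approx(66.67, abs=0.01)
    assert jsc == pytest.approx(50.00, abs=0.01)


def test_vectorised_counts_match_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        pred = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
        gt = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == _bruteforce_counts(pred, gt)
        assert c.total == 256


def test_nonbinary_mask_rejected():
    with pytest.raises(ValueError, match="binary"):
        confusion_counts(np.array([[0, 2]]), np.array([[0, 1]]))


def test_perfect_prediction_scores_hundred(rng):
    g = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    assert segmentation_metrics(g.astype(float), g) == (100.0, 100.0, 100.0)


def test_empty_mask_conventions():
    z = np.zeros((4, 4), dtype=np.uint8)
    o = np.ones((4, 4), dtype=np.uint8)
    assert segmentation_metrics(z.astype(float), z) == (100.0, 100.0, 100.0)
    # empty ground truth, non-empty prediction: SEN denominator is 0 -> 0
    assert segmentation_metrics(o.astype(float), z) == (0.0, 0.0, 0.0)
    # empty prediction, non-empty ground truth
    dsc, sen, jsc = segmentation_metrics(z.astype(float), o)
    assert (dsc, sen, jsc) == (0.0, 0.0, 0.0)


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
def test_jaccard_dice_identity(pbits, gbits):
    """JSC = DSC / (2 - DSC) on the 0..1 scale, for any mask pair."""
    pred = np.array([(pbits >> i) & 1 for i in range(16)]).reshape(4, 4)
    gt = np.array([(gbits >> i) & 1 for i in range(16)]).reshape(4, 4)
    dsc, _, jsc = segmentation_metrics(pred.astype(float), gt.astype(np.uint8))
    d, j = dsc / 100, jsc / 100
    assert j == pytest.approx(d / (2 - d), abs=1e-12)


def test_metrics_report_mean_sd():
    rep = MetricsReport(per_image=[(90, 90, 80), (91, 92, 81),
                                   (92, 94, 82), (93, 96, 83)], fold_id=2)
    assert rep.mean[0] == pytest.approx(91.5)
    assert rep.sd[0] == pytest.approx(1.2909944, abs=1e-6)
    assert rep.fold_id == 2
    mean, sd = aggregate_mean_sd([90, 91, 92, 93])
    assert (mean, round(sd, 2)) == (91.5, 1.29)


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def test_identical_vectors_give_p_one():
    assert paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0


def test_constant_nonzero_difference_gives_smallest_positive():
    p = paired_ttest([1, 2, 3, 4], [2, 3, 4, 5])
    assert 0 < p <= np.finfo(float).tiny


def test_p_value_matches_closed_form_t_cdf():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([1.1, 2.3, 2.7, 4.4])
    d = a - b
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
    assert paired_ttest(a, b) == pytest.approx(expected, rel=1e-10)


def test_bad_inputs_rejected():
    with pytest.raises(ValueError):
        paired_ttest([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        paired_ttest([1], [2])
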