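"""Loss and metric semantics: hand-worked values, algebraic identities,
bounds, symmetry and aggregation conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgfinet import (ConfusionCounts, alt_loss, bce_loss, confusion_counts,
                     dice_loss, dice_score, evaluate, evaluate_predictions,
                     hausdorff_loss, iou_loss, jaccard_score, mcc_score,
                     tversky_loss)
from conftest import naive_counts

counts_st = st.integers(min_value=0, max_value=10_000)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_dice_loss_hand_values():
    assert dice_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]),
                     eps=0) == pytest.approx(1 / 3, abs=1e-12)
    assert dice_loss(np.array([1.0, 0, 0, 0]), np.array([1.0, 1, 0, 0]),
                     eps=0) == pytest.approx(1 / 3, abs=1e-12)
    t = np.array([1.0, 0, 1, 1])
    assert dice_loss(t, t, eps=0) == pytest.approx(0.0, abs=1e-12)
    # all-empty pair is defined as perfect
    z = np.zeros(6)
    assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-9)


def test_dice_loss_validates_inputs():
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        dice_loss(np.array([1.5]), np.array([1.0]))


def test_soft_iou_hand_value():
    got = iou_loss(np.array([1.0, 0, 0, 0]), np.array([1.0, 1, 0, 0]), eps=0)
    assert got == pytest.approx(0.5, abs=1e-12)


def test_tversky_at_half_equals_dice_on_binary():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = (rng.random(50) > 0.6).astype(float)
        t = (rng.random(50) > 0.6).astype(float)
        if p.sum() + t.sum() == 0:
            continue
        assert tversky_loss(p, t, 0.5, 0.5, eps=0) == pytest.approx(
            dice_loss(p, t, eps=0), abs=1e-9
        )


def test_bce_is_near_zero_for_perfect_binary_prediction():
    t = np.array([1.0, 0, 1, 0])
    assert bce_loss(t, t) <= -np.log(1 - 1e-7) + 1e-9


def test_hausdorff_surrogate_zero_iff_perfect_and_grows_with_distance():
    t = np.zeros((16, 16))
    t[4:8, 4:8] = 1
    assert hausdorff_loss(t, t) == pytest.approx(0.0, abs=1e-12)
    near, far = t.copy(), t.copy()
    near[8, 5] = 1.0   # false positive adjacent to the lesion
    far[14, 14] = 1.0  # false positive far from it
    assert 0 < hausdorff_loss(near, t) < hausdorff_loss(far, t)


def test_alt_loss_dispatch_and_unknown_kind():
    p, t = np.array([0.5, 0.5]), np.array([1.0, 0.0])
    assert alt_loss("dice", p, t, {"eps": 0}) == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="dice.*bce.*hausdorff.*iou.*tversky"):
        alt_loss("focal", p, t)


def test_loss_metric_identity_on_binary_predictions():
    rng = np.random.default_rng(7)
    for _ in range(25):
        p = (rng.random((8, 8)) > 0.5).astype(float)
        t = (rng.random((8, 8)) > 0.7).astype(float)
        c = confusion_counts(p, t, 0.5)
        assert dice_loss(p, t, eps=0) == pytest.approx(1 - dice_score(c),
                                                       abs=1e-9)


# ---------------------------------------------------------------------------
# confusion counts and scores
# ---------------------------------------------------------------------------

def test_confusion_counts_hand_values():
    t = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    p = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    c = confusion_counts(p, t, 0.5)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 0, 7)
    z = np.zeros(12)
    c0 = confusion_counts(z, z)
    assert (c0.tp, c0.fp, c0.fn, c0.tn) == (0, 0, 0, 12)
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(np.zeros(3), np.zeros((3, 1)))


def test_threshold_uses_greater_equal_rule():
    c = confusion_counts(np.array([0.5, 0.49]), np.array([1.0, 1.0]), 0.5)
    assert (c.tp, c.fn) == (1, 1)


def test_scores_hand_values():
    c = ConfusionCounts(tp=2, fp=1, fn=1, tn=6)
    assert dice_score(c) == pytest.approx(2 / 3, abs=1e-12)
    assert jaccard_score(c) == pytest.approx(1 / 2, abs=1e-12)
    assert mcc_score(c) == pytest.approx(11 / 21, abs=1e-12)
    perfect = ConfusionCounts(tp=40, fp=0, fn=0, tn=60)
    assert (dice_score(perfect), jaccard_score(perfect),
            mcc_score(perfect)) == (1.0, 1.0, 1.0)


def test_degenerate_conventions():
    empty = ConfusionCounts(0, 0, 0, 25)
    assert dice_score(empty) == 1.0 and jaccard_score(empty) == 1.0
    assert mcc_score(empty) == 0.0  # zero marginal -> defined as 0


@settings(max_examples=300, derandomize=True)
@given(tp=counts_st, fp=counts_st, fn=counts_st, tn=counts_st)
def test_score_bounds_and_dice_jaccard_identity(tp, fp, fn, tn):
    c = ConfusionCounts(tp, fp, fn, tn)
    d, j, m = dice_score(c), jaccard_score(c), mcc_score(c)
    assert 0.0 <= d <= 1.0 and 0.0 <= j <= 1.0 and -1.0 <= m <= 1.0
    assert d >= j
    assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(tp=counts_st, fp=counts_st, fn=counts_st, tn=counts_st)
def test_more_true_positives_never_hurt(tp, fp, fn, tn):
    a = ConfusionCounts(tp, fp, fn, tn)
    b = ConfusionCounts(tp + 5, fp, fn, tn)
    assert dice_score(b) >= dice_score(a)
    assert jaccard_score(b) >= jaccard_score(a)
    assert mcc_score(b) >= mcc_score(a) - 1e-12


@settings(max_examples=200, derandomize=True)
@given(tp=counts_st, fp=counts_st, fn=counts_st, tn=counts_st)
def test_mcc_class_swap_symmetry(tp, fp, fn, tn):
    a = ConfusionCounts(tp, fp, fn, tn)
    b = ConfusionCounts(tp=tn, fp=fn, fn=fp, tn=tp)
    assert mcc_score(a) == pytest.approx(mcc_score(b), abs=1e-12)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_per_image_mean_averages_per_sample_metrics():
    t1 = np.array([[1.0, 1], [0, 0]])
    p1 = np.array([[1.0, 0], [1, 0]])  # dice 0.5
    t2 = np.array([[1.0, 0], [0, 0]])
    p2 = t2.copy()                     # dice 1.0
    rep = evaluate_predictions([p1, p2], [t1, t2],
                               aggregation="per_image_mean")
    assert rep.dice == pytest.approx(0.75)
    assert rep.n_samples == 2 and rep.aggregation == "per_image_mean"


def test_global_pool_equals_summed_counts_oracle():
    rng = np.random.default_rng(3)
    preds = [rng.random((6, 6)) for _ in range(20)]
    targs = [(rng.random((6, 6)) > 0.5).astype(float) for _ in range(20)]
    rep = evaluate_predictions(preds, targs, aggregation="global_pool")
    tot = np.zeros(4, dtype=int)
    for p, t in zip(preds, targs):
        tot += np.array(naive_counts(p, t))
    c = ConfusionCounts(*tot)
    assert rep.dice == pytest.approx(dice_score(c), abs=1e-12)
    assert rep.mcc == pytest.approx(mcc_score(c), abs=1e-12)
    assert rep.jaccard == pytest.approx(jaccard_score(c), abs=1e-12)


class _OracleModel:
    """Stub that predicts each sample's own mask perfectly."""

    def predict(self, images, batch_size=8):
        return images  # images already hold the masks in this test


def test_evaluate_perfect_model_reports_ones():
    from dgfinet.synthetic import SegmentationSample

    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[2:5, 2:5] = 1
    s = SegmentationSample(image=mask.astype(float), mask=mask, id="s0")
    rep = evaluate(_OracleModel(), [s])
    assert (rep.dice, rep.mcc, rep.jaccard) == (1.0, 1.0, 1.0)
    with pytest.raises(ValueError, match="empty"):
        evaluate(_OracleModel(), [])
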