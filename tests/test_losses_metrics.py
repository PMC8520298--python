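"""Closed-form loss values, metric identities, and conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msaunet.autograd import Tensor
from msaunet.losses import (LossWeights, bce_loss, binarize, dice_loss,
                            total_loss)
from msaunet.metrics import MetricsReport, segmentation_metrics


# ----------------------------------------------------------------------
# closed-form values (hand arithmetic)
# ----------------------------------------------------------------------

def test_bce_perfect_prediction_near_zero():
    assert bce_loss(np.ones((2, 2)), np.full((2, 2), 0.999999)) < 1e-5


def test_bce_coin_flip_is_ln2():
    assert bce_loss(np.ones((3, 3)), np.full((3, 3), 0.5)) == pytest.approx(
        np.log(2.0), abs=1e-12)


def test_bce_two_pixel_hand_value():
    y = np.array([1.0, 0.0])
    p = np.array([0.8, 0.4])
    expected = (-np.log(0.8) - np.log(0.6)) / 2
    assert bce_loss(y, p) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.3669846, abs=1e-6)


def test_dice_perfect_overlap_zero():
    y = np.ones((2, 2))
    assert dice_loss(y, y.copy()) == pytest.approx(0.0, abs=1e-6)


def test_dice_disjoint_is_one():
    assert dice_loss(np.zeros(4), np.ones(4)) == pytest.approx(1.0, abs=1e-5)


def test_dice_half_confidence_hand_value():
    y = np.array([1.0, 1.0, 0.0, 0.0])
    p = np.full(4, 0.5)
    assert dice_loss(y, p) == pytest.approx(0.5, abs=1e-6)


def test_total_loss_hand_value_with_default_weights():
    y = np.array([1.0, 1.0, 0.0, 0.0])
    p = np.full(4, 0.5)
    assert total_loss(y, p) == pytest.approx(0.846574, abs=1e-5)


def test_total_loss_alpha_zero_reduces_to_dice():
    y = np.array([1.0, 0.0, 1.0, 1.0])
    p = np.array([0.7, 0.2, 0.9, 0.4])
    w = LossWeights(alpha=0.0, beta=1.0)
    assert total_loss(y, p, w) == pytest.approx(dice_loss(y, p), abs=1e-12)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(-0.1, 1.0)
    with pytest.raises(ValueError):
        LossWeights(0.0, 0.0)


def test_loss_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        bce_loss(np.ones((2, 2)), np.ones((2, 3)) * 0.5)
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.ones(4), np.ones(5) * 0.5)


def test_tensor_and_numpy_paths_agree_and_differentiate():
    """The autograd loss equals the numpy loss and its gradient is exact."""
    rng = np.random.default_rng(0)
    y = (rng.random((6, 6)) > 0.6).astype(float)
    p = rng.uniform(0.05, 0.95, size=(6, 6))
    t = Tensor(p.copy(), requires_grad=True)
    loss_t = total_loss(y, t)
    assert float(loss_t.data) == pytest.approx(total_loss(y, p), abs=1e-12)
    loss_t.backward()

    from conftest import finite_difference_grad

    numeric = finite_difference_grad(lambda arr: total_loss(y, arr), p, eps=1e-7)
    np.testing.assert_allclose(t.grad, numeric, rtol=1e-4, atol=1e-8)


# ----------------------------------------------------------------------
# binarization
# ----------------------------------------------------------------------

def test_binarize_strict_inequality_at_threshold():
    p = np.array([0.5, 0.51, 0.4])
    np.testing.assert_array_equal(binarize(p), [0, 1, 0])


def test_binarize_rejects_bad_threshold():
    with pytest.raises(ValueError):
        binarize(np.array([0.5]), threshold=1.0)
    with pytest.raises(ValueError):
        binarize(np.array([0.5]), threshold=0.0)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def test_metrics_perfect_segmentation_all_one():
    g = np.zeros((8, 8), dtype=np.uint8)
    g[2:5, 2:5] = 1
    r = segmentation_metrics(g, g.copy())
    assert (r.dsc, r.iou, r.precision, r.recall) == (1.0, 1.0, 1.0, 1.0)


def test_metrics_hand_worked_example():
    """|G|=10, |P|=8, overlap 6 -> DSC 2/3, IOU 0.5, prec 0.75, rec 0.6."""
    g = np.zeros(20, dtype=np.uint8)
    p = np.zeros(20, dtype=np.uint8)
    g[:10] = 1
    p[4:12] = 1  # overlap = indices 4..9 -> 6
    r = segmentation_metrics(g, p)
    assert r.dsc == pytest.approx(12 / 18, abs=1e-12)
    assert r.iou == pytest.approx(0.5, abs=1e-12)
    assert r.precision == pytest.approx(0.75, abs=1e-12)
    assert r.recall == pytest.approx(0.6, abs=1e-12)


def test_metrics_disjoint_nonempty_all_zero():
    g = np.array([[1, 0], [0, 0]], dtype=np.uint8)
    p = np.array([[0, 0], [0, 1]], dtype=np.uint8)
    r = segmentation_metrics(g, p)
    assert (r.dsc, r.iou, r.precision, r.recall) == (0.0, 0.0, 0.0, 0.0)


def test_metrics_empty_conventions():
    empty = np.zeros((4, 4), dtype=np.uint8)
    full = np.ones((4, 4), dtype=np.uint8)
    both = segmentation_metrics(empty, empty.copy())
    assert (both.dsc, both.iou, both.precision, both.recall) == (1.0,) * 4
    pred_only = segmentation_metrics(empty, full)
    assert pred_only.recall == 0.0 and pred_only.precision == 0.0


def test_metrics_reject_nonbinary_and_mismatched():
    with pytest.raises(ValueError, match="binary"):
        segmentation_metrics(np.array([0, 2]), np.array([0, 1]))
    with pytest.raises(ValueError, match="shapes"):
        segmentation_metrics(np.zeros((2, 2)), np.zeros((3, 3)))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_dsc_iou_and_harmonic_mean_identities(seed):
    """DSC = 2*IOU/(1+IOU) and DSC = 2PR/(P+R) on random mask pairs."""
    rng = np.random.default_rng(seed)
    g = (rng.random((16, 16)) > rng.uniform(0.2, 0.8)).astype(np.uint8)
    p = (rng.random((16, 16)) > rng.uniform(0.2, 0.8)).astype(np.uint8)
    r = segmentation_metrics(g, p)
    assert r.dsc == pytest.approx(2 * r.iou / (1 + r.iou), abs=1e-12)
    if r.precision + r.recall > 0:
        hmean = 2 * r.precision * r.recall / (r.precision + r.recall)
        assert r.dsc == pytest.approx(hmean, abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metrics_symmetric_under_transposition(seed):
    rng = np.random.default_rng(seed)
    g = (rng.random((8, 12)) > 0.5).astype(np.uint8)
    p = (rng.random((8, 12)) > 0.5).astype(np.uint8)
    a = segmentation_metrics(g, p)
    b = segmentation_metrics(g.T, p.T)
    assert (a.dsc, a.iou, a.precision, a.recall) == (b.dsc, b.iou, b.precision, b.recall)


def test_dice_loss_on_binarized_perfect_prediction_complements_dsc():
    rng = np.random.default_rng(7)
    y = (rng.random((12, 12)) > 0.5).astype(float)
    dl = dice_loss(y, y)
    dsc = segmentation_metrics(y.astype(np.uint8), y.astype(np.uint8)).dsc
    assert abs(dl - (1.0 - dsc)) <= 1e-5


def test_report_aggregates_match_hand_computation():
    report = MetricsReport()
    g = np.zeros((4, 4), dtype=np.uint8)
    g[:2] = 1
    report.add(segmentation_metrics(g, g, case_id="a"))
    p = np.zeros_like(g)
    report.add(segmentation_metrics(g, p, case_id="b"))
    assert report.mean["dsc"] == pytest.approx(0.5)
    assert report.std["dsc"] == pytest.approx(0.5)
    df = report.to_dataframe()
    assert list(df["case_id"]) == ["a", "b"]
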