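"""Losses and metrics: worked examples, oracles, algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from dentseg.losses_metrics import (
    ConfusionCounts, accuracy, boundary_pixels, ce_loss, composite_loss,
    confusion, dice_loss, dsc, evaluate_dataset, hd95, iou, kappa, mcc,
)
from dentseg.nn import Tensor


def hd95_all_pairs_oracle(pred, true, q=95.0):
    """Brute-force all-pairs boundary distances, pooled percentile."""
    pb, tb = boundary_pixels(pred), boundary_pixels(true)
    if len(pb) == 0 or len(tb) == 0:
        return float("nan")
    D = cdist(pb, tb)
    pooled = np.concatenate([D.min(axis=1), D.min(axis=0)])
    return float(np.percentile(pooled, q))


@pytest.fixture
def constructed_pair():
    """pred 6 px, truth 4 px, overlap 3 px on a 4x4 grid."""
    pred = np.zeros((4, 4), dtype=bool)
    pred[0] = True
    pred[1, :2] = True
    true = np.zeros((4, 4), dtype=bool)
    true[0, :3] = True
    true[2, 0] = True
    assert pred.sum() == 6 and true.sum() == 4 and (pred & true).sum() == 3
    return pred, true


class TestLosses:
    def test_dice_loss_zero_at_perfect_overlap(self):
        mask = np.zeros((6, 6))
        mask[2:4, 2:4] = 1.0
        assert dice_loss(mask, mask) < 0.05  # epsilon-smoothed

    def test_dice_loss_one_at_disjoint_supports(self):
        a = np.zeros((6, 6)); a[0, 0] = 1.0
        b = np.zeros((6, 6)); b[5, 5] = 1.0
        assert dice_loss(a, b, smooth=0.0) == pytest.approx(1.0)

    def test_dice_loss_half_overlap_worked_example(self):
        pred = np.zeros((4, 4)); pred[0, :2] = 1.0   # 2 px
        true = np.zeros((4, 4)); true[0, 1:3] = 1.0  # 2 px, overlap 1
        assert dice_loss(pred, true, smooth=0.0) == pytest.approx(0.5)

    def test_ce_loss_ln2_at_half(self):
        y = np.random.default_rng(0).integers(0, 2, (5, 5))
        assert ce_loss(np.full((5, 5), 0.5), y) == pytest.approx(np.log(2), abs=1e-9)

    def test_ce_loss_ln4_worked_example(self):
        assert ce_loss(np.array([[0.25]]), np.array([[1]])) == \
            pytest.approx(np.log(4), abs=1e-9)

    def test_ce_loss_near_zero_for_perfect_prediction(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert ce_loss(y, y) < 1e-6

    def test_composite_is_weighted_sum(self, rng):
        p = rng.random((8, 8))
        y = (rng.random((8, 8)) > 0.5).astype(float)
        total = composite_loss(p, y)
        assert total == pytest.approx(dice_loss(p, y) + ce_loss(p, y))
        boosted = composite_loss(p, y, w_ce=2.0)
        assert boosted == pytest.approx(dice_loss(p, y) + 2 * ce_loss(p, y))

    def test_losses_differentiable_via_tensor(self, rng):
        p = Tensor(rng.uniform(0.1, 0.9, (4, 4)), requires_grad=True)
        y = (rng.random((4, 4)) > 0.5).astype(float)
        loss = composite_loss(p, y)
        loss.backward()
        assert p.grad is not None and np.all(np.isfinite(p.grad))


class TestConfusion:
    def test_perfect_prediction(self, rng):
        truth = np.zeros((10, 10), dtype=bool)
        truth.ravel()[:30] = True
        c = confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (30, 70, 0, 0)

    def test_total_disagreement(self, rng):
        t = rng.random((8, 8)) > 0.5
        c = confusion(~t, t)
        assert c.tp == 0 and c.tn == 0

    def test_counts_partition_pixels(self, rng):
        p = rng.random((13, 7)) > 0.4
        t = rng.random((13, 7)) > 0.6
        assert confusion(p, t).total == 13 * 7

    def test_threshold_at_half(self):
        probs = np.array([[0.49, 0.51]])
        c = confusion(probs, np.array([[1, 1]]))
        assert (c.tp, c.fn) == (1, 1)


class TestOverlapMetrics:
    def test_identical_masks_100(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert dsc(m, m) == 100.0 and iou(m, m) == 100.0

    def test_worked_example_60_percent(self, constructed_pair):
        pred, true = constructed_pair
        assert dsc(pred, true) == pytest.approx(60.0)
        assert iou(pred, true) == pytest.approx(100 * 3 / 7)

    def test_dsc_iou_duality_on_worked_example(self, constructed_pair):
        pred, true = constructed_pair
        i = iou(pred, true)
        assert dsc(pred, true) == pytest.approx(200 * i / (100 + i), abs=1e-9)

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4), dtype=bool); a[0, 0] = True
        b = np.zeros((4, 4), dtype=bool); b[3, 3] = True
        assert iou(a, b) == 0.0 and dsc(a, b) == 0.0

    def test_both_empty_convention(self):
        empty = np.zeros((4, 4), dtype=bool)
        assert dsc(empty, empty) == 100.0 and iou(empty, empty) == 100.0

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_duality_and_symmetry_properties(self, seed):
        r = np.random.default_rng(seed)
        p = r.random((12, 12)) > 0.5
        t = r.random((12, 12)) > 0.5
        i = iou(p, t)
        assert dsc(p, t) == pytest.approx(200 * i / (100 + i), abs=1e-9)
        assert dsc(p, t) == pytest.approx(dsc(t, p))
        assert iou(p, t) == pytest.approx(iou(t, p))


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = rng.random((16, 16)) > 0.6
        if m.any():
            assert hd95(m, m) == 0.0

    def test_singletons_five_apart(self):
        a = np.zeros((8, 8), dtype=bool); a[3, 1] = True
        b = np.zeros((8, 8), dtype=bool); b[3, 6] = True
        assert hd95(a, b) == pytest.approx(5.0)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(25):
            p = rng.random((32, 32)) < 0.3
            t = rng.random((32, 32)) < 0.3
            got, want = hd95(p, t), hd95_all_pairs_oracle(p, t)
            assert got == pytest.approx(want, abs=1e-9)

    def test_empty_mask_undefined(self):
        empty = np.zeros((8, 8), dtype=bool)
        full = ~empty
        assert np.isnan(hd95(empty, full))
        assert np.isnan(hd95(full, empty))

    def test_le_exact_hausdorff(self, rng):
        for _ in range(10):
            p = rng.random((20, 20)) < 0.4
            t = rng.random((20, 20)) < 0.4
            h95 = hd95(p, t)
            h100 = hd95(p, t, percentile=100.0)
            if not np.isnan(h95):
                assert h95 <= h100 + 1e-12

    def test_symmetry(self, rng):
        p = rng.random((16, 16)) < 0.3
        t = rng.random((16, 16)) < 0.3
        assert hd95(p, t) == pytest.approx(hd95(t, p))


class TestConfusionMetrics:
    def test_worked_example_40_40_10_10(self):
        c = ConfusionCounts(tp=40, tn=40, fp=10, fn=10)
        assert accuracy(c) == pytest.approx(80.0)
        assert kappa(c) == pytest.approx(60.0)   # p_o=0.8, p_e=0.5
        assert mcc(c) == pytest.approx(60.0)     # (1600-100)/2500

    def test_perfect_prediction_100(self, rng):
        t = rng.random((10, 10)) > 0.5
        c = confusion(t, t)
        assert kappa(c) == pytest.approx(100.0)
        assert mcc(c) == pytest.approx(100.0)

    def test_all_positive_vs_half_truth_is_chance_level(self):
        pred = np.ones((10, 10), dtype=bool)
        true = np.zeros((10, 10), dtype=bool)
        true[:5] = True
        assert kappa(confusion(pred, true)) == pytest.approx(0.0)

    def test_mcc_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=0, tn=50, fp=0, fn=50)) == 0.0

    def test_kappa_mcc_match_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score, matthews_corrcoef
        for _ in range(10):
            a = rng.integers(0, 2, 150)
            b = rng.integers(0, 2, 150)
            c = confusion(a.astype(bool).reshape(10, 15),
                          b.astype(bool).reshape(10, 15))
            assert kappa(c) / 100 == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)
            assert mcc(c) / 100 == pytest.approx(matthews_corrcoef(b, a), abs=1e-9)

    def test_mcc_equals_kappa_on_balanced_margins(self):
        # equal row and column margins => kappa == mcc
        c = ConfusionCounts(tp=35, tn=35, fp=15, fn=15)
        assert mcc(c) == pytest.approx(kappa(c))


class TestEvaluateDataset:
    def test_all_perfect(self, rng):
        m = rng.random((8, 8)) > 0.5
        report = evaluate_dataset([(m, m), (m, m)])
        assert report.mean("dsc") == 100.0 and report.sd("dsc") == 0.0

    def test_mean_and_sample_sd(self, constructed_pair):
        pred, true = constructed_pair
        m = np.ones((4, 4), dtype=bool)
        report = evaluate_dataset([(pred, true), (m, m)])  # dsc 60 and 100
        assert report.mean("dsc") == pytest.approx(80.0)
        assert report.sd("dsc") == pytest.approx(np.sqrt(2) * 20, abs=1e-9)
        population = evaluate_dataset([(pred, true), (m, m)], sample_sd=False)
        assert population.sd("dsc") == pytest.approx(20.0)

    def test_csv_has_summary_row(self, tmp_path, rng):
        masks = [rng.random((8, 8)) > 0.5 for _ in range(3)]
        report = evaluate_dataset([(m, m) for m in masks])
        out = tmp_path / "report.csv"
        report.to_csv(out)
        assert len(out.read_text().strip().splitlines()) == 5  # header + 3 + mean

    def test_hd95_undefined_excluded_and_counted(self):
        empty = np.zeros((6, 6), dtype=bool)
        full = np.ones((6, 6), dtype=bool)
        report = evaluate_dataset([(empty, empty), (full, full)])
        assert report.hd95_undefined == 1
        assert report.mean("hd95") == 0.0  # only the defined image counts
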