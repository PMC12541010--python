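"""Losses and evaluation metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from acunet import (ConfusionCounts, LossWeights, assd, combined_loss,
                    confusion_counts, cross_entropy_loss, dice_loss,
                    evaluate_regions, hd95, overlap_metrics)
from acunet.metrics import surface_pixels

RNG = np.random.default_rng(99)


def brute_force_counts(pred, gt):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = pred[i, j], gt[i, j]
            tp += p and g
            fp += p and not g
            fn += (not p) and g
            tn += (not p) and (not g)
    return tp, fp, fn, tn


def brute_force_surface_distances(a, b, spacing):
    """All-pairs Euclidean distances between two boundary point sets."""
    pa = np.argwhere(surface_pixels(a)).astype(float) * spacing
    pb = np.argwhere(surface_pixels(b)).astype(float) * spacing
    d_ab = [min(np.hypot(*(p - q)) for q in pb) for p in pa]
    d_ba = [min(np.hypot(*(q - p)) for p in pa) for q in pb]
    return np.array(d_ab), np.array(d_ba)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        g = (RNG.random((8, 8)) > 0.5).astype(float)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_give_one(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([0.0, 0.0, 1.0, 1.0])
        assert dice_loss(p, g) == pytest.approx(1.0, abs=1e-7)

    def test_uniform_half_worked_case(self):
        p = np.full(4, 0.5)
        g = np.array([1.0, 1.0, 0.0, 0.0])
        assert dice_loss(p, g) == pytest.approx(0.5, abs=1e-7)

    def test_monotone_improvement_towards_target(self):
        g = (RNG.random((6, 6)) > 0.6).astype(float)
        start = RNG.random((6, 6))
        losses = [dice_loss(start + t * (g - start), g)
                  for t in np.linspace(0, 1, 11)]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(3), np.zeros(4))


class TestCrossEntropy:
    def test_single_pixel_half_is_ln2(self):
        assert cross_entropy_loss(np.array([0.5]), np.array([1.0])) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_binary_prediction_near_zero(self):
        g = (RNG.random((5, 5)) > 0.5).astype(float)
        assert cross_entropy_loss(g, g) < 1e-9

    def test_mean_is_sum_over_n(self):
        p, g = RNG.random((7, 3)), (RNG.random((7, 3)) > 0.5).astype(float)
        total = cross_entropy_loss(p, g, reduction="sum")
        assert cross_entropy_loss(p, g, reduction="mean") == total / 21


class TestCombinedLoss:
    def test_weighted_sum_for_random_draws(self):
        for _ in range(20):
            lam_d, lam_c = RNG.random(2) + 1e-3
            p = RNG.random((4, 4))
            g = (RNG.random((4, 4)) > 0.5).astype(float)
            w = LossWeights(lam_d, lam_c)
            expected = lam_d * dice_loss(p, g) + lam_c * cross_entropy_loss(p, g)
            assert combined_loss(p, g, w) == pytest.approx(expected, rel=1e-12)

    def test_projections_onto_components(self):
        p = RNG.random((3, 3))
        g = (RNG.random((3, 3)) > 0.5).astype(float)
        assert combined_loss(p, g, LossWeights(1, 0)) == dice_loss(p, g)
        assert combined_loss(p, g, LossWeights(0, 1)) == \
            cross_entropy_loss(p, g)

    def test_both_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0)


class TestConfusionAndOverlap:
    def test_counts_match_double_loop_on_random_pairs(self):
        for _ in range(25):
            pred = RNG.random((8, 8)) > 0.5
            gt = RNG.random((8, 8)) > 0.5
            c = confusion_counts(pred.astype(int), gt.astype(int))
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(pred, gt)
            assert c.total == 64

    def test_all_ones_and_all_zeros_cases(self):
        ones, zeros = np.ones((2, 2), int), np.zeros((2, 2), int)
        assert confusion_counts(ones, ones) == ConfusionCounts(4, 0, 0, 0)
        assert confusion_counts(ones, zeros).fp == 4

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([[2]]), np.array([[1]]))

    def test_hand_worked_metrics(self):
        m = overlap_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=4))
        assert m["dice"] == pytest.approx(4 / 6)
        assert m["jaccard"] == pytest.approx(0.5)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(2 / 3)

    def test_both_empty_convention(self):
        m = overlap_metrics(ConfusionCounts(0, 0, 0, 16))
        assert m["dice"] == 1.0 and m["specificity"] == 1.0
        assert m["jaccard"] == 1.0 and m["f1"] == 1.0

    def test_identities_on_random_counts(self):
        for _ in range(100):
            tp, fp, fn, tn = RNG.integers(0, 50, 4)
            if tp + fp + fn == 0:
                continue
            m = overlap_metrics(ConfusionCounts(int(tp), int(fp), int(fn),
                                                int(tn)))
            assert abs(m["f1"] - m["dice"]) < 1e-12
            assert abs(m["jaccard"] - m["dice"] / (2 - m["dice"])) < 1e-12


class TestSurfaceDistances:
    def test_identical_masks_give_zero(self):
        m = np.zeros((9, 9), int)
        m[2:6, 3:7] = 1
        assert hd95(m, m) == 0.0
        assert assd(m, m) == 0.0

    def test_single_pixels_three_apart(self):
        a, b = np.zeros((4, 6), int), np.zeros((4, 6), int)
        a[0, 0], b[0, 3] = 1, 1
        assert hd95(a, b) == pytest.approx(3.0)
        assert assd(a, b) == pytest.approx(3.0)

    def test_matches_exhaustive_oracle_on_random_masks(self):
        from scipy import ndimage
        for trial in range(100):
            pred = ndimage.binary_dilation(RNG.random((10, 10)) > 0.92)
            gt = ndimage.binary_dilation(RNG.random((10, 10)) > 0.92)
            if not pred.any() or not gt.any():
                continue
            spacing = (1.0, 1.0) if trial % 2 == 0 else (2.0, 0.5)
            d_pg, d_gp = brute_force_surface_distances(pred, gt, spacing)
            expected_hd = max(np.percentile(d_pg, 95),
                              np.percentile(d_gp, 95))
            expected_assd = (d_pg.sum() + d_gp.sum()) / (len(d_pg) + len(d_gp))
            assert hd95(pred, gt, spacing) == pytest.approx(expected_hd,
                                                            abs=1e-9)
            assert assd(pred, gt, spacing) == pytest.approx(expected_assd,
                                                            abs=1e-9)

    def test_empty_conventions(self):
        empty, full = np.zeros((4, 4), int), np.ones((4, 4), int)
        assert hd95(empty, empty) == 0.0
        assert np.isnan(hd95(full, empty))
        assert np.isnan(assd(empty, full))

    def test_spacing_linearity(self):
        a, b = np.zeros((6, 6), int), np.zeros((6, 6), int)
        a[1, 1], b[4, 1] = 1, 1
        assert assd(a, b, (2.0, 2.0)) == pytest.approx(2 * assd(a, b))

    def test_symmetry(self):
        pred = RNG.random((12, 12)) > 0.8
        gt = RNG.random((12, 12)) > 0.8
        assert hd95(pred, gt) == hd95(gt, pred)
        assert assd(pred, gt) == assd(gt, pred)


class TestEvaluateRegions:
    def make_labels(self):
        lab = np.zeros((16, 16), dtype=np.int16)
        lab[2:12, 2:12] = 2
        lab[4:10, 4:10] = 1
        lab[6:8, 6:8] = 4
        return lab

    def test_identical_maps_score_one_everywhere(self):
        lab = self.make_labels()
        rep = evaluate_regions(lab, lab)
        for region in ("WT", "TC", "ET"):
            assert rep[region]["dice"] == 1.0
            assert rep[region]["hd95_mm"] == 0.0

    def test_missing_et_prediction_flags_undefined_distance(self):
        gt = self.make_labels()
        pred = gt.copy()
        pred[pred == 4] = 1                     # predicts no enhancing tumor
        rep = evaluate_regions(pred, gt)
        assert rep["ET"]["dice"] == 0.0
        assert np.isnan(rep["ET"]["hd95_mm"])
        assert rep.n_undefined_surface == 1

    def test_average_row_is_mean_of_regions(self):
        gt = self.make_labels()
        pred = np.roll(gt, 1, axis=0)
        rep = evaluate_regions(pred, gt)
        sub = rep.table.loc[["WT", "TC", "ET"]]
        np.testing.assert_allclose(rep.table.loc["Average"].to_numpy(),
                                   sub.mean(axis=0).to_numpy())

    def test_report_serialisation(self, tmp_path):
        rep = evaluate_regions(self.make_labels(), self.make_labels())
        rep.to_csv(tmp_path / "m.csv")
        rep.to_json(tmp_path / "m.json")
        import pandas as pd
        loaded = pd.read_csv(tmp_path / "m.csv", index_col="region")
        assert list(loaded.index) == ["WT", "TC", "ET", "Average"]
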