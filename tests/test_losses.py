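import numpy as np
import pytest

from fbrseg.augment import augment_eightfold
from fbrseg.losses import (
    BoundaryWeightMap,
    ClassBalance,
    background_importance,
    boundary_weight_map,
    class_balance_coefficients,
    class_boundary_weights,
    custom_metric,
    iou,
    multiclass_dice_grad,
    multiclass_dice_loss,
    total_loss,
    weighted_bce_loss,
)
from fbrseg.preprocess import MulticlassMask


class TestClassBalance:
    def test_sum_is_one(self, rng):
        masks = [MulticlassMask(rng.integers(0, 3, (32, 32)), n_classes=3) for _ in range(4)]
        assert class_balance_coefficients(masks).alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_frequencies_give_uniform_alpha(self):
        lab = np.repeat(np.arange(3), 12).reshape(6, 6)
        alpha = class_balance_coefficients([MulticlassMask(lab, n_classes=3)]).alpha
        assert np.allclose(alpha, 1.0 / 3.0)

    def test_inverse_frequency_two_classes(self):
        lab = np.zeros((4, 4), dtype=int)
        lab[0] = 1  # frequencies 0.75 / 0.25
        alpha = class_balance_coefficients([MulticlassMask(lab, n_classes=2)]).alpha
        assert np.allclose(alpha, [0.25, 0.75])

    def test_absent_class_named_in_error(self):
        lab = np.zeros((4, 4), dtype=int)
        lab[0] = 1  # classes 0 and 1 present, class 2 absent
        with pytest.raises(ValueError, match="class 2"):
            class_balance_coefficients([MulticlassMask(lab, n_classes=3)])


class TestMulticlassDice:
    def test_perfect_prediction_is_zero(self, rng):
        y = MulticlassMask(rng.integers(0, 3, (8, 8)), n_classes=3).one_hot()
        bal = ClassBalance(np.full(3, 1 / 3))
        assert multiclass_dice_loss(y, y, bal) == pytest.approx(0.0, abs=1e-5)

    def test_total_disagreement_is_one(self):
        y = np.zeros((2, 4, 4))
        y[0] = 1.0
        yhat = np.zeros_like(y)
        yhat[1] = 1.0
        bal = ClassBalance([0.5, 0.5])
        assert multiclass_dice_loss(y, yhat, bal) == pytest.approx(1.0, abs=1e-5)

    def test_hand_worked_example(self):
        # 16-px image, 4 px of class 1, uniform 0.5 prediction, alpha=(0.25, 0.75)
        lab = np.zeros((4, 4), dtype=int)
        lab[0] = 1
        y = MulticlassMask(lab, n_classes=2).one_hot()
        yhat = np.full((2, 4, 4), 0.5)
        loss = multiclass_dice_loss(y, yhat, ClassBalance([0.25, 0.75]))
        assert loss == pytest.approx(0.6, abs=1e-4)

    def test_bounded_and_grad_descends(self, rng):
        y = MulticlassMask(rng.integers(0, 2, (8, 8)), n_classes=2).one_hot()
        p = rng.uniform(0.1, 0.9, (2, 8, 8))
        p = p / p.sum(axis=0)
        bal = ClassBalance([0.5, 0.5])
        loss = multiclass_dice_loss(y, p, bal)
        assert 0.0 <= loss <= 1.0
        g = multiclass_dice_grad(y, p, bal)
        stepped = np.clip(p - 1e-3 * g, 1e-6, 1.0)
        assert multiclass_dice_loss(y, stepped, bal) < loss


class TestTotalLoss:
    def test_l2_term_arithmetic(self):
        w = np.array([1.0, 1.0])  # ||w||^2 = 2
        assert total_loss(0.3, w, lam=0.01) == pytest.approx(0.31)
        assert total_loss(0.3, w, lam=0.0) == pytest.approx(0.3)
        assert total_loss(0.3, np.zeros(5), lam=0.01) == pytest.approx(0.3)


class TestBoundaryWeights:
    def test_gaussian_of_summed_distances(self):
        lab = np.zeros((11, 11), dtype=int)
        lab[5, 0] = 1
        lab[5, 7] = 1
        wm = boundary_weight_map(lab)
        # pixel (5,3): d1=3 to the left cell, d2=4 to the right cell
        assert wm.w_b[5, 3] == pytest.approx(100.0 * np.exp(-0.98), abs=1e-9)

    def test_zero_on_foreground_and_peak_amplitude(self):
        lab = np.zeros((9, 9), dtype=int)
        lab[2, 2] = 1
        lab[2, 6] = 1
        wm = boundary_weight_map(lab)
        assert np.all(wm.w_b[lab > 0] == 0.0)
        assert wm.w_b.max() <= 100.0
        # the formula at d1+d2 -> 0 gives the full amplitude
        assert 100.0 * np.exp(-0.0) == pytest.approx(100.0)

    def test_single_cell_duplicates_distance(self):
        lab = np.zeros((7, 7), dtype=int)
        lab[3, 3] = 1
        wm = boundary_weight_map(lab)
        # d2 = d1, so w = 100 exp(-(2 d)^2 / 50)
        assert wm.w_b[3, 5] == pytest.approx(100.0 * np.exp(-16.0 / 50.0))

    def test_no_cells_gives_zero_map(self):
        wm = boundary_weight_map(np.zeros((5, 5), dtype=int))
        assert np.all(wm.w_b == 0.0)

    def test_d4_equivariance(self, rng):
        lab = np.zeros((24, 24), dtype=int)
        lab[4:8, 3:9] = 1
        lab[14:20, 12:16] = 1
        base = boundary_weight_map(lab).w_b
        for v_lab, v_w in augment_eightfold((lab, base)):
            assert np.allclose(boundary_weight_map(v_lab).w_b, v_w, atol=1e-9)

    def test_class_boundary_offsets(self):
        lab = np.array([[0, 0], [0, 0]])
        wm = BoundaryWeightMap(np.array([[0.0, 100.0], [0.0, 100.0]]))
        i_b = background_importance([lab], [wm])
        assert i_b == pytest.approx(51.0)
        lab2 = np.array([[1, 0]])
        wm2 = BoundaryWeightMap(np.array([[0.0, 37.531]]))
        out = class_boundary_weights(lab2, wm2, i_b)
        assert out.w_cb[0, 0] == pytest.approx(1.0)       # foreground importance is 1
        assert out.w_cb[0, 1] == pytest.approx(88.531)

    def test_foreground_importance_is_unity_by_construction(self):
        # w_B vanishes on foreground, so mean(w_B + 1) over foreground is 1
        lab = np.zeros((16, 16), dtype=int)
        lab[2:6, 2:6] = 1
        lab[10:14, 10:14] = 1
        wm = boundary_weight_map(lab)
        assert np.mean(wm.w_b[lab > 0] + 1.0) == pytest.approx(1.0)


class TestWeightedBCE:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0.0]])
        assert weighted_bce_loss(y, y, np.ones_like(y)) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_weights_equal_plain_bce(self, rng):
        y = rng.integers(0, 2, (6, 6)).astype(float)
        p = rng.uniform(0.05, 0.95, (6, 6))
        plain = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
        assert weighted_bce_loss(y, p, np.full_like(y, 7.3)) == pytest.approx(plain)

    def test_hand_worked_example(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        w = np.array([[1.0, 3.0]])
        assert weighted_bce_loss(y, p, w) == pytest.approx(np.log(2.0))


class TestCustomMetric:
    @pytest.mark.parametrize("kind,expected", [("perfect", 1.0), ("inverted", 0.0), ("uniform", 0.5)])
    def test_reference_points(self, rng, kind, expected):
        y = rng.integers(0, 2, (8, 8)).astype(float)
        w = rng.uniform(1.0, 50.0, (8, 8))
        p = {"perfect": y, "inverted": 1.0 - y, "uniform": np.full_like(y, 0.5)}[kind]
        assert custom_metric(y, p, w) == pytest.approx(expected, abs=1e-6)

    def test_label_flip_symmetry(self, rng):
        y = rng.integers(0, 2, (8, 8)).astype(float)
        p = rng.uniform(0, 1, (8, 8))
        w = rng.uniform(1, 10, (8, 8))
        assert custom_metric(y, p, w) == pytest.approx(custom_metric(1 - y, 1 - p, w))


class TestIoU:
    def test_reference_cases(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        assert iou(a, b) == 1.0  # both empty: perfect agreement
        a[0, :2] = True
        assert iou(a, a) == 1.0
        b[3, :2] = True
        assert iou(a, b) == 0.0

    def test_counting_example(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0:4] = True          # area 4
        b[0, 2:4] = b[1, 2:4] = True  # area 4, overlap 2
        assert iou(a, b) == pytest.approx(1.0 / 3.0)
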