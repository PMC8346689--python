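"""Loss functions: hand-computed oracles, identities, gradients."""
import math

import numpy as np
import pytest

from priorseg.losses import (
    ClassWeights,
    cce_loss,
    median_frequency_weights,
    one_hot,
    soft_dice_loss,
    wcce_loss,
)
from priorseg.nn.autograd import Tensor, numeric_gradient


def _soft_dice_oracle(probs, target, eps=1e-5):
    """Direct summation over a toy tensor."""
    total = 0.0
    C = probs.shape[0]
    for c in range(C):
        p, t = probs[c].ravel(), target[c].ravel()
        total += (2 * float((p * t).sum()) + eps) / (float(p.sum()) + float(t.sum()) + eps)
    return 1.0 - total / C


class TestSoftDice:
    def test_perfect_prediction_near_zero(self):
        t = one_hot(np.array([[[1, 2], [3, 4]]]), 6, include_background=False)
        assert float(soft_dice_loss(t, t).data) < 1e-4

    def test_anti_perfect_near_one(self):
        # two balanced classes, prediction = 1 - target
        target = np.zeros((2, 2, 2, 1), dtype=np.float64)
        target[0, 0], target[1, 1] = 1.0, 1.0
        probs = 1.0 - target
        assert float(soft_dice_loss(probs, target).data) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_half_vs_bruteforce_oracle(self, rng):
        target = one_hot(rng.integers(0, 7, (4, 4, 4)), 6, include_background=False)
        probs = np.full_like(target, 0.5)
        got = float(soft_dice_loss(probs, target).data)
        assert got == pytest.approx(_soft_dice_oracle(probs, target), abs=1e-10)

    def test_random_vs_oracle(self, rng):
        target = one_hot(rng.integers(0, 7, (4, 4, 4)), 6, include_background=False)
        probs = rng.random(target.shape)
        got = float(soft_dice_loss(probs, target).data)
        assert got == pytest.approx(_soft_dice_oracle(probs, target), abs=1e-10)

    def test_monotone_toward_target(self, rng):
        target = one_hot(rng.integers(0, 7, (3, 3, 3)), 6, include_background=False)
        start = rng.random(target.shape)
        losses = []
        for alpha in np.linspace(0, 1, 7):
            p = (1 - alpha) * start + alpha * target
            losses.append(float(soft_dice_loss(p, target).data))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((6, 2, 2, 2)), np.zeros((6, 2, 2, 3)))


class TestCCE:
    def test_perfect_prediction(self):
        t = one_hot(np.array([[[0, 3]]]), 7, include_background=True)
        assert float(cce_loss(t, t).data) < 1e-5

    def test_uniform_prediction_ln7(self):
        t = one_hot(np.array([[[0, 1, 2, 6]]]), 7, include_background=True)
        p = np.full(t.shape, 1 / 7, dtype=np.float64)
        assert float(cce_loss(p, t).data) == pytest.approx(math.log(7), abs=1e-9)

    def test_two_voxel_manual_arithmetic(self):
        # voxel A true class 0 with p=0.7; voxel B true class 2 with p=0.2
        p = np.zeros((3, 2, 1, 1))
        t = np.zeros((3, 2, 1, 1))
        p[:, 0] = np.array([0.7, 0.2, 0.1]).reshape(3, 1, 1)[:, :, 0:1]
        p[:, 1] = np.array([0.5, 0.3, 0.2]).reshape(3, 1, 1)[:, :, 0:1]
        t[0, 0] = 1.0
        t[2, 1] = 1.0
        want = -(math.log(0.7) + math.log(0.2)) / 2
        assert float(cce_loss(p, t).data) == pytest.approx(want, abs=1e-12)


class TestWeights:
    def test_single_map_worked_example(self):
        # counts {bg:100, c1:10, c2:50} -> w = {1, 10, 2}
        lab = np.zeros((4, 40, 1), dtype=int)
        lab[0, :10, 0] = 1
        lab[1, :25, 0] = 2
        lab[2, :25, 0] = 2
        # bg = 160 - 60 = 100
        w = median_frequency_weights([lab], n_classes=3)
        assert w.weights == {0: 1.0, 1: 10.0, 2: 2.0}

    def test_equal_counts_all_ones(self):
        lab = np.array([[[0, 1, 2]]])
        w = median_frequency_weights([lab], n_classes=3)
        assert all(v == 1.0 for v in w.weights.values())

    def test_median_across_three_maps(self):
        # c1 counts (10, 20, 30), bg (100, 100, 100) -> w_c1 = 100/20 = 5
        maps = []
        for n1 in (10, 20, 30):
            lab = np.zeros((100 + n1, 1, 1), dtype=int)
            lab[:n1] = 1
            maps.append(lab)
        w = median_frequency_weights(maps, n_classes=2)
        assert w.weights[1] == pytest.approx(100 / 20)

    def test_absent_class_raises(self):
        lab = np.zeros((4, 4, 4), dtype=int)
        with pytest.raises(ValueError, match="classes \\[1"):
            median_frequency_weights([lab], n_classes=2)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            ClassWeights({0: 1.0, 1: 0.0})


class TestWCCE:
    def test_unit_weights_equal_cce(self, rng):
        t = one_hot(rng.integers(0, 7, (3, 3, 3)), 7, include_background=True)
        p = rng.random(t.shape)
        p /= p.sum(axis=0, keepdims=True)
        w = ClassWeights({c: 1.0 for c in range(7)})
        assert float(wcce_loss(p, t, w).data) == float(cce_loss(p, t).data)

    def test_linearity_in_weights(self, rng):
        t = one_hot(rng.integers(0, 3, (3, 3, 3)), 3, include_background=True)
        p = rng.random(t.shape)
        p /= p.sum(axis=0, keepdims=True)
        w1 = ClassWeights({0: 1.0, 1: 2.0, 2: 0.5})
        w2 = ClassWeights({0: 2.0, 1: 4.0, 2: 1.0})
        assert float(wcce_loss(p, t, w2).data) == pytest.approx(
            2 * float(wcce_loss(p, t, w1).data), rel=1e-12)

    def test_two_voxel_weighted_manual(self):
        p = np.zeros((2, 2, 1, 1))
        t = np.zeros((2, 2, 1, 1))
        p[:, 0, 0, 0] = [0.8, 0.2]
        p[:, 1, 0, 0] = [0.4, 0.6]
        t[0, 0, 0, 0] = 1.0
        t[1, 1, 0, 0] = 1.0
        w = ClassWeights({0: 1.0, 1: 3.0})
        want = -(1.0 * math.log(0.8) + 3.0 * math.log(0.6)) / 2
        assert float(wcce_loss(p, t, w).data) == pytest.approx(want, abs=1e-12)

    def test_missing_weight_for_present_class(self, rng):
        t = one_hot(rng.integers(0, 3, (2, 2, 2)), 3, include_background=True)
        p = np.full_like(t, 1 / 3)
        with pytest.raises(KeyError):
            wcce_loss(p, t, ClassWeights({0: 1.0, 1: 1.0}))


class TestGradients:
    """Finite-difference agreement on 2-cube toys (float64)."""

    @pytest.mark.parametrize("loss_name", ["dice", "cce", "wcce"])
    def test_gradcheck(self, loss_name, rng):
        n_ch = 6 if loss_name == "dice" else 7
        t = one_hot(rng.integers(0, n_ch + (0 if loss_name == "dice" else 0),
                                 (2, 2, 2)), n_ch,
                    include_background=loss_name != "dice")
        p0 = np.clip(rng.random((n_ch, 2, 2, 2)), 0.05, 0.95)
        w = ClassWeights({c: 1.0 + c for c in range(n_ch)})

        def fn(arr):
            pt = Tensor(arr)
            if loss_name == "dice":
                return float(soft_dice_loss(pt, t).data)
            if loss_name == "cce":
                return float(cce_loss(pt, t).data)
            return float(wcce_loss(pt, t, w).data)

        pt = Tensor(p0, requires_grad=True)
        loss = {"dice": lambda: soft_dice_loss(pt, t),
                "cce": lambda: cce_loss(pt, t),
                "wcce": lambda: wcce_loss(pt, t, w)}[loss_name]()
        loss.backward()
        num = numeric_gradient(fn, p0)
        denom = max(np.abs(num).max(), 1e-12)
        assert np.abs(num - pt.grad).max() / denom < 1e-3

    def test_losses_finite_and_nonnegative(self, rng):
        t6 = one_hot(rng.integers(0, 7, (3, 3, 3)), 6, include_background=False)
        t7 = one_hot(rng.integers(0, 7, (3, 3, 3)), 7, include_background=True)
        p6 = rng.random(t6.shape)
        p7 = rng.random(t7.shape)
        p7 /= p7.sum(axis=0, keepdims=True)
        for val in (float(soft_dice_loss(p6, t6).data), float(cce_loss(p7, t7).data)):
            assert np.isfinite(val) and val >= 0


def test_class_weights_json_roundtrip():
    w = ClassWeights({0: 1.0, 1: 2.5, 6: 0.75})
    assert ClassWeights.from_json(w.to_json()).weights == w.weights
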