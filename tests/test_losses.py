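"""Loss correctness: analytic cross-entropy values, the Lovász–Softmax
surrogate against two independent oracles (per-class Jaccard loss on
hard assignments; the threshold-integral form of the Lovász extension
on soft ones), and the composite/comparison losses."""

from itertools import product

import numpy as np
import pytest

from marblingnet.losses import (LossConfig, ce_ls, cross_entropy, dice_loss,
                                evaluate, focal_loss, lovasz_softmax)


def _hard_probs(pred):
    return np.eye(2)[np.asarray(pred)]


def jaccard_loss_mean(pred, target, n_classes=2):
    """Independent oracle: mean per-class Jaccard loss of a hard labeling."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    total = 0.0
    for c in range(n_classes):
        inter = np.sum((pred == c) & (target == c))
        union = np.sum((pred == c) | (target == c))
        total += 0.0 if union == 0 else 1.0 - inter / union
    return total / n_classes


def lovasz_integral_oracle(probs, targets):
    """Threshold-integral form of the Lovász extension, exact piecewise
    integration over the breakpoints of the error vector."""
    probs = np.asarray(probs, float)
    targets = np.asarray(targets)
    total = 0.0
    n_classes = probs.shape[1]
    for c in range(n_classes):
        fg = (targets == c).astype(float)
        m = np.abs(fg - probs[:, c])
        breakpoints = np.unique(np.concatenate([[0.0, 1.0], m]))
        acc = 0.0
        for a, b in zip(breakpoints[:-1], breakpoints[1:]):
            mis = m > (a + b) / 2
            inter = np.sum(fg * ~mis)
            union = fg.sum() + np.sum(mis & (fg == 0))
            delta = 0.0 if union == 0 else 1.0 - inter / union
            acc += (b - a) * delta
        total += acc
    return total / n_classes


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        probs = _hard_probs([0, 1, 1, 0]).astype(float)
        # clamp makes log(1)=0 exact
        assert cross_entropy(probs, [0, 1, 1, 0]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_ln2(self):
        probs = np.full((10, 2), 0.5)
        assert cross_entropy(probs, [0, 1] * 5) == pytest.approx(np.log(2), rel=1e-12)

    def test_two_pixel_hand_value(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert cross_entropy(probs, [0, 1]) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((3, 2)), [0, 1])


class TestLovaszSoftmax:
    @pytest.mark.parametrize("n", range(1, 9))
    def test_hard_assignments_equal_jaccard_exhaustively(self, n):
        """All 2^n predictions against several labelings for each n <= 8."""
        rng = np.random.default_rng(n)
        labelings = {tuple(rng.integers(0, 2, n)) for _ in range(4)}
        labelings |= {tuple([0] * n), tuple([1] * n)}
        for target in labelings:
            for pred in product([0, 1], repeat=n):
                got = lovasz_softmax(_hard_probs(pred), np.array(target))
                want = jaccard_loss_mean(pred, target)
                assert got == pytest.approx(want, abs=1e-12), (pred, target)

    def test_inverted_hard_prediction_on_mixed_mask_is_one(self):
        target = np.array([0, 0, 1, 1])
        assert lovasz_softmax(_hard_probs(1 - target), target) == pytest.approx(1.0)

    def test_soft_batches_match_threshold_integral_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 65))
            p1 = rng.random(n)
            probs = np.stack([1 - p1, p1], axis=1)
            targets = rng.integers(0, 2, n)
            got = lovasz_softmax(probs, targets)
            want = lovasz_integral_oracle(probs, targets)
            assert got == pytest.approx(want, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p1 = rng.random(20)
        probs = np.stack([1 - p1, p1], axis=1)
        targets = rng.integers(0, 2, 20)
        perm = rng.permutation(20)
        for fn in (lovasz_softmax, cross_entropy, dice_loss, focal_loss):
            assert fn(probs, targets) == pytest.approx(fn(probs[perm], targets[perm]))

    def test_piecewise_linear_between_breakpoints(self):
        """Interpolating probabilities between nearby points on the same
        linear piece interpolates the loss exactly."""
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.1, 0.9, 8)
        targets = rng.integers(0, 2, 8)
        direction = rng.normal(0, 1, 8) * 1e-4

        def at(t):
            q1 = p1 + t * direction
            return lovasz_softmax(np.stack([1 - q1, q1], 1), targets)

        mid = at(0.5)
        assert mid == pytest.approx((at(0.0) + at(1.0)) / 2, abs=1e-9)


class TestCompositeAndComparison:
    def _batch(self):
        rng = np.random.default_rng(3)
        p1 = rng.random(4)
        return np.stack([1 - p1, p1], 1), rng.integers(0, 2, 4)

    def test_lambda_zero_reduces_to_cross_entropy(self):
        probs, t = self._batch()
        assert ce_ls(probs, t, lam=0.0) == pytest.approx(cross_entropy(probs, t))

    def test_lambda_one_is_direct_sum(self):
        probs, t = self._batch()
        assert ce_ls(probs, t, lam=1.0) == pytest.approx(
            cross_entropy(probs, t) + lovasz_softmax(probs, t))

    def test_half_lambda_weighted_combination(self):
        probs, t = self._batch()
        assert ce_ls(probs, t, lam=0.5) == pytest.approx(
            cross_entropy(probs, t) + 0.5 * lovasz_softmax(probs, t))

    def test_negative_lambda_rejected(self):
        probs, t = self._batch()
        with pytest.raises(ValueError):
            ce_ls(probs, t, lam=-0.1)
        with pytest.raises(ValueError):
            LossConfig(kind="ce_ls", lam=-1)

    def test_perfect_predictions_zero_for_dice_and_focal(self):
        probs = _hard_probs([0, 1, 0, 1]).astype(float)
        t = np.array([0, 1, 0, 1])
        assert dice_loss(probs, t) == pytest.approx(0.0, abs=1e-12)
        assert focal_loss(probs, t) == pytest.approx(0.0, abs=1e-10)

    def test_focal_gamma_zero_is_cross_entropy(self):
        probs, t = self._batch()
        assert focal_loss(probs, t, gamma=0.0) == pytest.approx(cross_entropy(probs, t))

    def test_four_pixel_hand_arithmetic(self):
        probs = np.array([[0.7, 0.3], [0.4, 0.6], [0.2, 0.8], [0.9, 0.1]])
        t = np.array([0, 1, 1, 0])
        p1, g1 = probs[:, 1], (t == 1).astype(float)
        dice_expected = 1 - 2 * (p1 * g1).sum() / (p1.sum() + g1.sum())
        assert dice_loss(probs, t) == pytest.approx(dice_expected, rel=1e-12)
        p_t = probs[np.arange(4), t]
        focal_expected = np.mean(-(1 - p_t) ** 2 * np.log(p_t))
        assert focal_loss(probs, t, gamma=2.0) == pytest.approx(focal_expected, rel=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(kind="tversky")

    def test_evaluate_dispatches_each_kind(self):
        probs, t = self._batch()
        assert evaluate(probs, t, LossConfig("ce")) == pytest.approx(cross_entropy(probs, t))
        assert evaluate(probs, t, LossConfig("ls")) == pytest.approx(lovasz_softmax(probs, t))
        assert evaluate(probs, t, LossConfig("dice")) == pytest.approx(dice_loss(probs, t))
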