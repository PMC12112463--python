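"""Box losses: Gaussian modelling, Wasserstein distance, CIoU, NWD, WWIoU."""

import math

import numpy as np
import pytest

from conftest import random_box
from rdwkit.boxes import BoxXYWH, InvalidBoxError
from rdwkit.geometry_loss import (
    CIoUTerms,
    GaussianBB,
    InvalidCovarianceError,
    LossConfig,
    box_to_gaussian,
    ciou_loss,
    ciou_terms,
    fit_box,
    iou,
    nwd,
    nwd_loss,
    wasserstein2_squared,
    wasserstein2_squared_diag,
    wwiou_grad,
    wwiou_loss,
    wwiou_loss_batch,
)

from _oracles import corner_iou


class TestGaussianModel:
    @pytest.mark.parametrize(
        "box, mu, diag",
        [
            (BoxXYWH(0, 0, 2, 2), (0, 0), (1, 1)),
            (BoxXYWH(3, 4, 4, 6), (3, 4), (4, 9)),
        ],
    )
    def test_box_to_gaussian(self, box, mu, diag):
        g = box_to_gaussian(box)
        assert np.allclose(g.mu, mu)
        assert np.allclose(g.sigma, np.diag(diag))
        assert np.allclose(g.sigma, g.sigma.T)
        assert np.linalg.eigvalsh(g.sigma).min() >= 0

    def test_invalid_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            BoxXYWH(0, 0, -1, 2)
        with pytest.raises(InvalidBoxError):
            BoxXYWH(0, 0, 1, 0)

    def test_non_diagonal_covariance_rejected(self):
        with pytest.raises(InvalidCovarianceError):
            GaussianBB(mu=[0, 0], sigma=[[1, 0.1], [0.1, 1]])
        with pytest.raises(InvalidCovarianceError):
            GaussianBB(mu=[0, 0], sigma=[[-1, 0], [0, 1]])

    def test_corner_round_trip(self, rng):
        for _ in range(100):
            b = random_box(rng)
            assert BoxXYWH.from_corners(*b.to_corners()).as_tuple() == pytest.approx(
                b.as_tuple(), rel=1e-12
            )


class TestWasserstein:
    def test_identity_is_zero(self):
        a = BoxXYWH(1, 2, 3, 4)
        assert wasserstein2_squared_diag(a, a) == 0.0
        g = box_to_gaussian(a)
        assert wasserstein2_squared(g, g) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            # equal sizes: pure mean term 3^2 + 4^2
            (BoxXYWH(0, 0, 2, 2), BoxXYWH(3, 4, 2, 2), 25.0),
            # same center: pure size term (1-2)^2 + (1-2)^2
            (BoxXYWH(0, 0, 2, 2), BoxXYWH(0, 0, 4, 4), 2.0),
        ],
    )
    def test_closed_form_examples(self, a, b, expected):
        assert wasserstein2_squared_diag(a, b) == pytest.approx(expected, rel=1e-12)
        assert wasserstein2_squared(
            box_to_gaussian(a), box_to_gaussian(b)
        ) == pytest.approx(expected, rel=1e-12)

    def test_diag_matches_matrix_form_on_random_pairs(self, rng):
        for _ in range(1000):
            a, b = random_box(rng), random_box(rng)
            d = wasserstein2_squared_diag(a, b)
            m = wasserstein2_squared(box_to_gaussian(a), box_to_gaussian(b))
            assert abs(d - m) <= 1e-9 * max(1.0, abs(m))

    def test_symmetry(self, rng):
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            ga, gb = box_to_gaussian(a), box_to_gaussian(b)
            assert wasserstein2_squared(ga, gb) == pytest.approx(
                wasserstein2_squared(gb, ga), rel=1e-12, abs=1e-12
            )

    def test_monotone_in_translation(self):
        base = BoxXYWH(0, 0, 2, 3)
        cfg = LossConfig(c_norm=5.0)
        prev_w2, prev_nwd = -1.0, 2.0
        for shift in np.linspace(0.5, 10, 20):
            other = BoxXYWH(shift, 0, 2, 3)
            w2 = wasserstein2_squared_diag(base, other)
            s = nwd(base, other, cfg)
            assert w2 > prev_w2 and s < prev_nwd
            prev_w2, prev_nwd = w2, s


class TestNWD:
    def test_identical_boxes_give_one(self):
        a = BoxXYWH(5, 5, 2, 7)
        for c in (0.5, 5.0, 12.8):
            assert nwd(a, a, LossConfig(c_norm=c)) == 1.0

    def test_distance_mode_example(self):
        # W2^2 = 25, sqrt = 5, c = 5 -> exp(-1)
        v = nwd(BoxXYWH(0, 0, 2, 2), BoxXYWH(3, 4, 2, 2), LossConfig(c_norm=5.0))
        assert v == pytest.approx(math.exp(-1), rel=1e-12)

    def test_squared_mode_example(self):
        v = nwd(
            BoxXYWH(0, 0, 2, 2),
            BoxXYWH(3, 4, 2, 2),
            LossConfig(c_norm=5.0, nwd_exponent="squared_distance"),
        )
        assert v == pytest.approx(math.exp(-5.0), rel=1e-12)

    def test_vanishes_for_distant_boxes(self):
        v = nwd(BoxXYWH(0, 0, 1, 1), BoxXYWH(1e6, 0, 1, 1), LossConfig(c_norm=1.0))
        assert 0.0 <= v < 1e-100

    def test_scale_invariance_distance_mode(self, rng):
        """Scaling boxes and c together leaves the similarity unchanged."""
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            s = float(rng.uniform(0.1, 100))
            cfg1 = LossConfig(c_norm=3.0)
            cfg2 = LossConfig(c_norm=3.0 * s)
            a2 = BoxXYWH(a.cx * s, a.cy * s, a.w * s, a.h * s)
            b2 = BoxXYWH(b.cx * s, b.cy * s, b.w * s, b.h * s)
            assert nwd(a2, b2, cfg2) == pytest.approx(nwd(a, b, cfg1), rel=1e-9)

    def test_bounds(self, rng):
        cfg = LossConfig()
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            assert 0.0 < nwd(a, b, cfg) <= 1.0
            assert 0.0 <= nwd_loss(a, b, cfg) < 1.0
            assert nwd_loss(a, b, cfg) == pytest.approx(1.0 - nwd(a, b, cfg), rel=1e-15)


class TestIoU:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (BoxXYWH(0, 0, 2, 2), BoxXYWH(0, 0, 2, 2), 1.0),
            (BoxXYWH(0, 0, 2, 2), BoxXYWH(10, 10, 2, 2), 0.0),
            (BoxXYWH(0, 0, 2, 2), BoxXYWH(1, 0, 2, 2), 1.0 / 3.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected, rel=1e-12)

    def test_matches_corner_oracle(self, rng):
        for _ in range(300):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(
                corner_iou(a.as_tuple(), b.as_tuple()), rel=1e-12, abs=1e-15
            )


class TestCIoU:
    def test_identity_is_zero(self):
        a = BoxXYWH(2, 3, 4, 5)
        assert ciou_loss(a, a) == 0.0

    def test_shifted_same_shape(self):
        """Equal aspect ratios kill the alpha*v term: loss = 1 - IoU + offset^2/d^2."""
        pred, gt = BoxXYWH(1, 0, 2, 2), BoxXYWH(0, 0, 2, 2)
        t = ciou_terms(pred, gt)
        assert t.v == pytest.approx(0.0, abs=1e-12)
        # enclosing box 3 x 2 -> d^2 = 13, offset^2 = 1
        expected = 1.0 - 1.0 / 3.0 + 1.0 / 13.0
        assert ciou_loss(pred, gt) == pytest.approx(expected, rel=1e-9)

    def test_term_by_term_oracle(self, rng):
        """Each CIoU ingredient recomputed independently from first principles."""
        for _ in range(100):
            pred, gt = random_box(rng), random_box(rng)
            t = ciou_terms(pred, gt)
            px1, py1, px2, py2 = pred.to_corners()
            gx1, gy1, gx2, gy2 = gt.to_corners()
            center_sq = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
            ex = max(px2, gx2) - min(px1, gx1)
            ey = max(py2, gy2) - min(py1, gy1)
            v = (4 / math.pi**2) * (
                math.atan(gt.w / (gt.h + 1e-9)) - math.atan(pred.w / (pred.h + 1e-9))
            ) ** 2
            i = corner_iou(pred.as_tuple(), gt.as_tuple())
            alpha = v / ((1 - i) + v + 1e-9)
            expected = 1 - i + center_sq / (ex**2 + ey**2) + alpha * v
            assert ciou_loss(pred, gt) == pytest.approx(expected, rel=1e-9)
            assert t.center_dist_sq <= t.diag_sq  # centers inside enclosing box

    def test_bounds(self, rng):
        for _ in range(300):
            pred, gt = random_box(rng), random_box(rng)
            t = ciou_terms(pred, gt)
            assert 0.0 <= t.iou <= 1.0
            assert 0.0 <= t.center_dist_sq / t.diag_sq <= 1.0
            assert 0.0 <= t.alpha * t.v <= 1.0
            assert 0.0 <= ciou_loss(pred, gt) <= 3.0


class TestWWIoU:
    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5, 1.0])
    def test_identity_is_zero(self, r):
        a = BoxXYWH(0.4, 0.6, 0.2, 0.3)
        assert wwiou_loss(a, a, LossConfig(r_weight=r)) == 0.0

    def test_degenerate_mixing(self, rng):
        for _ in range(50):
            pred, gt = random_box(rng), random_box(rng)
            cfg1 = LossConfig(r_weight=1.0)
            cfg0 = LossConfig(r_weight=0.0)
            assert wwiou_loss(pred, gt, cfg1) == pytest.approx(ciou_loss(pred, gt), rel=1e-12)
            assert wwiou_loss(pred, gt, cfg0) == pytest.approx(
                nwd_loss(pred, gt, cfg0), rel=1e-12
            )

    def test_mixture_is_convex_combination(self, rng):
        for _ in range(50):
            pred, gt = random_box(rng), random_box(rng)
            cfg = LossConfig(r_weight=0.3)
            expected = 0.3 * ciou_loss(pred, gt) + 0.7 * nwd_loss(pred, gt, cfg)
            assert wwiou_loss(pred, gt, cfg) == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        cfg = LossConfig()
        checked = 0
        while checked < 40:
            pred, gt = random_box(rng), random_box(rng)
            if iou(pred, gt) < 0.05:  # keep away from the disjoint kink
                continue
            _, grad = wwiou_grad(pred, gt, cfg)
            eps = 1e-6
            t = list(pred.as_tuple())
            fd = np.zeros(4)
            for i in range(4):
                hi, lo = t.copy(), t.copy()
                hi[i] += eps
                lo[i] -= eps
                fd[i] = (
                    wwiou_loss(BoxXYWH(*hi), gt, cfg) - wwiou_loss(BoxXYWH(*lo), gt, cfg)
                ) / (2 * eps)
            scale = max(np.abs(grad).max(), 1e-8)
            assert np.abs(grad - fd).max() / scale < 1e-4
            checked += 1

    def test_batch_reductions(self, rng):
        cfg = LossConfig()
        preds = [random_box(rng) for _ in range(5)]
        gts = [random_box(rng) for _ in range(5)]
        per = wwiou_loss_batch(preds, gts, cfg, reduction="none")
        assert per.shape == (5,)
        assert per == pytest.approx([wwiou_loss(p, g, cfg) for p, g in zip(preds, gts)])
        assert wwiou_loss_batch(preds, gts, cfg, "sum") == pytest.approx(5 * wwiou_loss_batch(preds, gts, cfg, "mean"))
        assert wwiou_loss_batch(preds, preds, cfg, "mean") == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            wwiou_loss_batch(preds, gts[:3], cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(r_weight=1.5)
        with pytest.raises(ValueError):
            LossConfig(c_norm=0.0)
        with pytest.raises(ValueError):
            LossConfig(nwd_exponent="cubed")


class TestFitBox:
    def test_already_at_target(self):
        t = BoxXYWH(0.5, 0.5, 0.2, 0.2)
        traj = fit_box(t, t, steps=10)
        assert traj[-1]["iou"] == pytest.approx(1.0, abs=1e-9)

    def test_recovers_displaced_box(self):
        traj = fit_box(BoxXYWH(0.3, 0.3, 0.1, 0.1), BoxXYWH(0.6, 0.6, 0.2, 0.2), steps=500)
        assert traj[-1]["iou"] > 0.99

    def test_pure_iou_loss_stalls_when_disjoint(self):
        init, tgt = BoxXYWH(0.2, 0.2, 0.02, 0.02), BoxXYWH(0.5, 0.5, 0.02, 0.02)
        traj = fit_box(init, tgt, steps=100, loss="iou")
        assert all(r["iou"] == 0.0 for r in traj)
        assert traj[-1]["cx"] == init.cx and traj[-1]["cy"] == init.cy
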