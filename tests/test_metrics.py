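"""Metric and loss oracles: closed forms, brute-force tallies, skimage."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from deblurseg import losses, metrics
from deblurseg.nn.tensor import Tensor

M, N = 2.55, 7.5


class TestSSIM:
    @pytest.mark.parametrize("mode", ["windowed", "global"])
    def test_identical_images_score_one(self, mode, rng):
        x = rng.uniform(0, 255, size=(32, 32))
        p = metrics.SSIMParams(mode=mode)
        assert metrics.ssim(x, x, p) == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["windowed", "global"])
    def test_symmetry_and_upper_bound(self, mode, rng):
        p = metrics.SSIMParams(mode=mode)
        x = rng.uniform(0, 255, size=(32, 32))
        y = np.clip(x + rng.normal(0, 20, size=x.shape), 0, 255)
        assert metrics.ssim(x, y, p) == pytest.approx(metrics.ssim(y, x, p))
        assert metrics.ssim(x, y, p) <= 1.0

    @pytest.mark.parametrize("mode", ["windowed", "global"])
    def test_constant_images_match_closed_form(self, mode):
        """With zero variances the score collapses to the luminance term."""
        c1, c2 = 100.0, 110.0
        got = metrics.ssim(np.full((16, 16), c1), np.full((16, 16), c2),
                           metrics.SSIMParams(mode=mode))
        want = (2 * c1 * c2 + M ** 2) / (c1 ** 2 + c2 ** 2 + M ** 2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_windowed_matches_skimage(self, rng):
        """Independent implementation agreement (stabilizers translated
        into skimage's K1/K2 parametrization)."""
        x = rng.uniform(0, 255, size=(48, 48))
        y = np.clip(x + rng.normal(0, 12, size=x.shape), 0, 255)
        mine = metrics.ssim(x, y, metrics.SSIMParams())
        ref = sk_ssim(x, y, data_range=255, gaussian_weights=True, sigma=1.5,
                      use_sample_covariance=False, K1=M / 255, K2=N / 255)
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_default_stabilizers(self):
        p = metrics.SSIMParams()
        assert (p.m, p.n) == (2.55, 7.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics.ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPSNR:
    def test_full_scale_error_is_zero_db(self):
        assert metrics.psnr(np.zeros((4, 4)), np.full((4, 4), 255.0)) == 0.0

    def test_one_grey_level_closed_form(self):
        got = metrics.psnr(np.zeros((8, 8, 3)), np.ones((8, 8, 3)))
        assert got == pytest.approx(10 * np.log10(255 ** 2))

    def test_identical_images_are_infinite(self, rng):
        x = rng.uniform(0, 255, size=(8, 8, 3))
        assert metrics.psnr(x, x) == np.inf

    def test_monotone_in_noise_amplitude(self, rng):
        x = rng.uniform(60, 200, size=(32, 32, 3))
        noise = rng.normal(0, 1, size=x.shape)
        values = [metrics.psnr(x + a * noise, x) for a in (1, 2, 5, 10, 20)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestConfusionAndSegMetrics:
    def test_perfect_prediction(self, rng):
        gt = rng.integers(0, 3, size=(16, 16))
        cc = metrics.confusion(gt, gt)
        assert (cc.fp == 0).all() and (cc.fn == 0).all()
        m = metrics.seg_metrics(gt, gt)
        assert m.miou == 1.0 and m.f1 == 1.0

    def test_counts_partition_pixels(self, rng):
        pred = rng.integers(0, 3, size=(9, 9))
        gt = rng.integers(0, 3, size=(9, 9))
        cc = metrics.confusion(pred, gt)
        total = pred.size
        for c in range(3):
            assert cc.tp[c] + cc.fp[c] + cc.fn[c] + cc.tn[c] == total

    def test_toy_map_hand_counts(self):
        pred = np.array([[0, 1], [1, 2]])
        gt = np.array([[0, 1], [2, 2]])
        cc = metrics.confusion(pred, gt)
        np.testing.assert_array_equal(cc.tp, [1, 1, 1])
        np.testing.assert_array_equal(cc.fp, [0, 1, 0])
        np.testing.assert_array_equal(cc.fn, [0, 0, 1])

    def test_absent_class_scores_one(self):
        """All-0 prediction vs all-1 truth: class 2 is vacuously perfect."""
        pred = np.zeros((2, 2), int)
        gt = np.ones((2, 2), int)
        m = metrics.seg_metrics(pred, gt)
        np.testing.assert_allclose(m.per_class_iou, [0.0, 0.0, 1.0])
        assert m.miou == pytest.approx(1 / 3)
        # recall: class0 vacuous? gt has no 0s but pred does -> 0; class1 0/4;
        # class2 absent everywhere -> 1
        assert m.recall == pytest.approx((0 + 0 + 1) / 3)
        assert m.precision == pytest.approx((0 + 0 + 1) / 3)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            metrics.confusion(np.array([[3]]), np.array([[0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_tally(self, seed):
        """Vectorized counts equal a per-pixel Python loop on random maps."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            pred = rng.integers(0, 3, size=(8, 8))
            gt = rng.integers(0, 3, size=(8, 8))
            cc = metrics.confusion(pred, gt)
            for c in range(3):
                tp = fp = fn = 0
                for i in range(8):
                    for j in range(8):
                        if pred[i, j] == c and gt[i, j] == c:
                            tp += 1
                        elif pred[i, j] == c:
                            fp += 1
                        elif gt[i, j] == c:
                            fn += 1
                assert (cc.tp[c], cc.fp[c], cc.fn[c]) == (tp, fp, fn)
            m = metrics.seg_metrics(pred, gt)
            assert m.miou == pytest.approx(np.mean(m.per_class_iou))
            assert 0.0 <= m.f1 <= 1.0


class TestLosses:
    def test_restoration_loss_zero_on_match(self, rng):
        x = rng.uniform(-1, 1, size=(1, 3, 24, 24))
        for lam in (0.0, 0.5, 0.84, 1.0):
            assert losses.restoration_loss(Tensor(x), x, lam).item() \
                == pytest.approx(0.0, abs=1e-12)

    def test_lambda_extremes(self, rng):
        x = rng.uniform(-1, 1, size=(1, 3, 24, 24))
        y = np.clip(x + rng.normal(0, 0.1, size=x.shape), -1, 1)
        pure_ssim = losses.restoration_loss(Tensor(x), y, 1.0).item()
        xs, ys = (x + 1) * 127.5, (y + 1) * 127.5
        assert pure_ssim == pytest.approx(
            1.0 - losses.ssim_windowed(Tensor(xs), Tensor(ys)).item())
        pure_l1 = losses.restoration_loss(Tensor(x), y, 0.0).item()
        assert pure_l1 == pytest.approx(np.abs(x - y).mean())

    def test_lambda_out_of_range_rejected(self, rng):
        x = rng.uniform(-1, 1, size=(1, 3, 16, 16))
        with pytest.raises(ValueError):
            losses.restoration_loss(Tensor(x), x, 1.2)

    def test_windowed_ssim_loss_matches_metric_on_valid_region(self, rng):
        """The differentiable SSIM and the metric implementation agree on
        an image whose border effects vanish (constant borders)."""
        x = np.full((1, 1, 40, 40), 120.0)
        y = np.full((1, 1, 40, 40), 140.0)
        got = losses.ssim_windowed(Tensor(x), Tensor(y)).item()
        want = metrics.ssim(x[0, 0], y[0, 0], metrics.SSIMParams())
        assert got == pytest.approx(want, abs=1e-9)

    def test_dice_perfect_and_disjoint(self, rng):
        lab = rng.integers(0, 3, size=(8, 8))
        oh = losses.one_hot(lab)
        assert losses.dice_loss(Tensor(oh), oh).item() == pytest.approx(0.0, abs=1e-5)
        disjoint = losses.one_hot((lab + 1) % 3)
        assert losses.dice_loss(Tensor(disjoint), oh).item() \
            == pytest.approx(1.0, abs=1e-5)

    def test_dice_two_pixel_hand_computation(self):
        """One of two pixels overlaps in class 0; per-class Dice by hand."""
        gt = np.array([[0, 0]])
        pred_lab = np.array([[0, 1]])
        P = losses.one_hot(pred_lab)
        L = losses.one_hot(gt)
        # class0: inter 1, sums 2+1 -> dice 2/3; class1: 0/(1+0);
        # class2: empty -> eps/eps = 1
        want = 1.0 - (2 / 3 + 0.0 + 1.0) / 3
        assert losses.dice_loss(Tensor(P), L).item() == pytest.approx(want,
                                                                      abs=1e-4)

    def test_dice_bounded(self, rng):
        for _ in range(5):
            p = rng.dirichlet(np.ones(3), size=(6, 6)).transpose(2, 0, 1)[None]
            oh = losses.one_hot(rng.integers(0, 3, size=(6, 6)))
            v = losses.dice_loss(Tensor(p), oh).item()
            assert 0.0 <= v <= 1.0
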