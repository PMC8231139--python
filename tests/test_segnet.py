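"""U-Net architecture, losses, schedule, and the numpy layer engine."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from carpo.nn import (Adam, BatchNorm2d, Conv2d, MaxPool2x2, MultiStepLR, ReLU,
                      UpsampleNearest2x, softmax)
from carpo.segnet import (TrainConfig, UNetSpec, build_unet, combined_loss_grad,
                          dice_loss, hausdorff_loss, load_model, predict_sequence,
                          save_model, train)


# ---------------------------------------------------------------------------
# Layer engine
# ---------------------------------------------------------------------------


def _numeric_input_grad(layer, x, eps=1e-6):
    y = layer.forward(x, train=True)
    gx = layer.backward(2.0 * y)
    num = np.zeros_like(x)
    flat, nflat = x.ravel(), num.ravel()
    for k in range(x.size):
        orig = flat[k]
        flat[k] = orig + eps
        l1 = (layer.forward(x, train=True) ** 2).sum()
        flat[k] = orig - eps
        l2 = (layer.forward(x, train=True) ** 2).sum()
        flat[k] = orig
        nflat[k] = (l1 - l2) / (2 * eps)
    return gx, num


class TestLayers:
    def test_conv_matches_scipy_correlation(self):
        rng = np.random.default_rng(0)
        conv = Conv2d(3, 5, 3, rng)
        x = rng.standard_normal((2, 6, 6, 3))
        y = conv.forward(x, train=False)
        for n in range(2):
            for o in range(5):
                oracle = sum(correlate2d(x[n, :, :, i], conv.w[o, i], mode="same")
                             for i in range(3)) + conv.b[o]
                np.testing.assert_allclose(y[n, :, :, o], oracle, atol=1e-5)

    @pytest.mark.parametrize("layer_fn,shape", [
        (lambda rng: Conv2d(3, 4, 3, rng), (2, 6, 6, 3)),
        (lambda rng: Conv2d(3, 4, 1, rng), (2, 6, 6, 3)),
        (lambda rng: BatchNorm2d(3), (2, 6, 6, 3)),
        (lambda rng: ReLU(), (2, 6, 6, 3)),
        (lambda rng: UpsampleNearest2x(), (2, 4, 4, 3)),
        (lambda rng: MaxPool2x2(), (2, 6, 6, 3)),
    ])
    def test_backward_matches_numeric_gradient(self, layer_fn, shape):
        rng = np.random.default_rng(1)
        layer = layer_fn(rng)
        x = rng.standard_normal(shape)  # continuous values: no pooling ties
        gx, num = _numeric_input_grad(layer, x)
        np.testing.assert_allclose(gx, num, rtol=1e-4, atol=1e-6)

    def test_adam_minimizes_quadratic(self):
        p = np.array([5.0, -3.0], dtype=np.float32)
        g = np.zeros_like(p)
        opt = Adam([(p, g)], lr=0.1)
        for _ in range(300):
            g[...] = 2 * p
            opt.step()
        np.testing.assert_allclose(p, 0.0, atol=1e-3)


class TestSchedule:
    def test_reference_milestones_give_expected_lrs(self):
        cfg = TrainConfig()
        sched = MultiStepLR(cfg.lr, cfg.milestones, cfg.gamma)
        assert sched.lr_at(1) == pytest.approx(0.1)
        assert sched.lr_at(60) == pytest.approx(0.001)  # two drops: 10, 50
        assert sched.lr_at(500) == pytest.approx(0.1 * 0.1 ** 5)

    def test_schedule_nonincreasing_with_drops_exactly_at_milestones(self):
        sched = MultiStepLR(0.1, (10, 50, 100, 150, 250), 0.1)
        lrs = [sched.lr_at(e) for e in range(1, 501)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        drops = {e + 1 for e in range(len(lrs) - 1) if lrs[e + 1] < lrs[e]}
        assert drops == {9, 49, 99, 149, 249}  # 0-based positions of epochs 10..250

    def test_unsorted_milestones_rejected(self):
        with pytest.raises(ValueError):
            MultiStepLR(0.1, (50, 10))
        with pytest.raises(ValueError):
            TrainConfig(milestones=(10, 600), epochs=500)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------


class TestUNet:
    def test_output_shape_contract(self):
        model = build_unet(UNetSpec(depth=2, base_channels=4))
        out = model.forward(np.zeros((1, 1, 32, 32), dtype=np.float32), train=False)
        assert out.shape == (1, 9, 32, 32)

    def test_depth1_toy_net(self):
        model = build_unet(UNetSpec(depth=1, base_channels=2))
        out = model.forward(np.zeros((2, 1, 8, 8), dtype=np.float32), train=False)
        assert out.shape == (2, 9, 8, 8)

    def test_indivisible_size_rejected(self):
        model = build_unet(UNetSpec(depth=2, base_channels=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 30, 30), dtype=np.float32))

    def test_parameter_count_matches_hand_computation(self):
        # depth 1, base 2, 1 input channel, 8+1 output channels:
        # encoder: conv 1->2 (2*1*9+2) + bn(2*2) + conv 2->2 (2*2*9+2) + bn(4)
        # bottleneck: conv 2->4 (4*2*9+4) + bn(8) + conv 4->4 (4*4*9+4) + bn(8)
        # decoder: conv 6->2 (2*6*9+2) + bn(4) + conv 2->2 (38) + bn(4)
        # head: 1x1 conv 2->9 (9*2+9)
        expected = (20 + 4 + 38 + 4) + (76 + 8 + 148 + 8) + (110 + 4 + 38 + 4) + 27
        model = build_unet(UNetSpec(depth=1, base_channels=2))
        assert model.n_parameters() == expected

    def test_full_model_gradients(self):
        """End-to-end backprop against numeric differentiation (cross-entropy
        head to keep the objective smooth)."""
        rng = np.random.default_rng(0)
        model = build_unet(UNetSpec(depth=1, base_channels=3), seed=2)
        x = rng.standard_normal((2, 1, 8, 8))
        t = rng.integers(0, 9, (2, 8, 8))

        def ce(logits):
            p = softmax(logits.astype(np.float64), axis=1)
            onehot = np.eye(9)[t].transpose(0, 3, 1, 2)
            return (-(onehot * np.log(p + 1e-12)).sum() / t.size,
                    (p - onehot) / t.size)

        _, dlog = ce(model.forward(x, train=True))
        model.backward(dlog)
        rels = []
        for p, g in model.params:
            gs = g.copy()
            for k in range(0, p.size, max(1, p.size // 3)):
                f = p.ravel()
                orig = f[k]
                f[k] = orig + 1e-4
                l1, _ = ce(model.forward(x, train=True))
                f[k] = orig - 1e-4
                l2, _ = ce(model.forward(x, train=True))
                f[k] = orig
                num = (l1 - l2) / 2e-4
                rels.append(abs(num - gs.ravel()[k])
                            / max(1e-5, abs(num) + abs(gs.ravel()[k])))
        # max-pool ties at ReLU zeros make a few subgradients branch-dependent;
        # the bulk of the parameters must match tightly
        assert np.median(rels) < 1e-3
        assert np.mean(np.array(rels) < 0.05) > 0.9


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _one_hot(target, n=9):
    return np.eye(n)[target].transpose(2, 0, 1)


class TestDiceLoss:
    def test_perfect_one_hot_is_zero(self):
        t = np.zeros((8, 8), dtype=int)
        t[2:6, 2:6] = 3
        assert dice_loss(_one_hot(t), t) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_scores_closed_form(self):
        # uniform 1/9 scores vs a single class covering every pixel:
        # 1 - 2*(N/9)/(N/9 + N) = 0.8
        t = np.full((8, 8), 5, dtype=int)
        scores = np.full((9, 8, 8), 1 / 9)
        assert dice_loss(scores, t) == pytest.approx(0.8, abs=1e-6)

    def test_disjoint_hard_prediction_is_one(self):
        t = np.zeros((8, 8), dtype=int)
        t[:4] = 2
        pred = np.zeros((8, 8), dtype=int)
        pred[4:] = 2
        assert dice_loss(_one_hot(pred), t) == pytest.approx(1.0, abs=1e-5)


class TestHausdorffLoss:
    def test_perfect_match_is_zero(self):
        t = np.zeros((8, 8), dtype=int)
        t[1:4, 1:4] = 7
        assert hausdorff_loss(_one_hot(t), t) == 0.0

    def test_single_misplaced_pixel_weighted_by_squared_distance(self):
        # false positive at distance d from the target: its weight is
        # d^2 (target distance map) + 1 (it forms its own 1-px boundary),
        # averaged over the image
        t = np.zeros((16, 16), dtype=int)
        t[6:10, 0:4] = 1
        for d in (3, 6):
            pred = t.copy()
            pred[7, 3 + d] = 1  # horizontal distance d to the target
            loss = hausdorff_loss(_one_hot(pred), t)
            assert loss == pytest.approx((d ** 2 + 1) / t.size, rel=1e-6)

    def test_monotone_in_distance(self):
        t = np.zeros((16, 16), dtype=int)
        t[6:10, 0:4] = 1
        losses = []
        for d in (2, 4, 6, 8):
            pred = t.copy()
            pred[7, 3 + d] = 1
            losses.append(hausdorff_loss(_one_hot(pred), t))
        assert all(a < b for a, b in zip(losses, losses[1:]))

    def test_combined_loss_zero_iff_exact(self):
        t = np.zeros((8, 8), dtype=int)
        t[2:5, 3:7] = 4
        logits = 50.0 * (_one_hot(t) - 0.5)  # saturated softmax -> one-hot
        loss, _ = combined_loss_grad(logits[None], t[None])
        assert loss == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------


class TestTraining:
    def test_zero_epochs_returns_untrained_model(self):
        x = np.zeros((2, 8, 8), dtype=np.float32)
        y = np.zeros((2, 8, 8), dtype=np.uint8)
        model, hist = train((x, y), None, UNetSpec(depth=1, base_channels=2),
                            TrainConfig(epochs=0, milestones=()))
        assert hist["epoch"] == []
        assert model.n_parameters() > 0

    def test_tiny_run_decreases_loss(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (8, 16, 16)).astype(np.float32)
        y = np.zeros((8, 16, 16), dtype=np.uint8)
        y[:, 4:12, 4:12] = 1
        x[:, 4:12, 4:12] += 2.0
        _, hist = train((x, y), None, UNetSpec(depth=1, base_channels=4),
                        TrainConfig(lr=1e-2, epochs=10, milestones=(), seed=1))
        losses = hist["train_loss"]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_predict_sequence_stateless_and_shaped(self):
        model = build_unet(UNetSpec(depth=1, base_channels=2), seed=0)
        frames = np.random.default_rng(2).normal(0, 1, (3, 16, 16))
        frames[2] = frames[0]
        scores, labels = predict_sequence(model, frames)
        assert scores.shape == (3, 9, 16, 16)
        assert labels.shape == (3, 16, 16)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_array_equal(labels[0], labels[2])
        np.testing.assert_array_equal(labels, scores.argmax(axis=1))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_unet(UNetSpec(depth=1, base_channels=2), seed=3)
        frames = np.random.default_rng(4).normal(0, 1, (2, 16, 16))
        _, before = predict_sequence(model, frames)
        save_model(model, tmp_path / "ckpt")
        restored = load_model(tmp_path / "ckpt")
        _, after = predict_sequence(restored, frames)
        np.testing.assert_array_equal(before, after)
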