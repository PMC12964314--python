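"""U-Net architecture, loss functions, training machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from planistem import _nn
from planistem.segnet import (TINY_CONFIG, TrainConfig, UNet, UNetConfig,
                              augment_pair, build_unet, combined_loss,
                              dice_coefficient, dice_loss, load_model,
                              predict, save_model, train, weight_map,
                              weighted_ce)


def hand_counted_params(widths, in_ch=1):
    """Independent arithmetic oracle for the parameter count."""

    def conv(cin, cout, k):
        return (cin * k * k + 1) * cout

    total = 0
    cin = in_ch
    for wdt in widths[:-1]:
        total += conv(cin, wdt, 3) + conv(wdt, wdt, 3)
        cin = wdt
    total += conv(cin, widths[-1], 3) + conv(widths[-1], widths[-1], 3)
    cin = widths[-1]
    for wdt in reversed(widths[:-1]):
        total += conv(cin, wdt, 2)  # 2x2 up-convolution
        total += conv(2 * wdt, wdt, 3) + conv(wdt, wdt, 3)
        cin = wdt
    total += conv(cin, 2, 3) + conv(2, 1, 1)
    return total


class TestArchitecture:
    def test_canonical_parameter_count(self):
        desc = build_unet(UNetConfig())
        assert desc["total_params"] == 31_031_685
        assert desc["total_params"] == hand_counted_params(
            [64, 128, 256, 512, 1024])

    def test_tiny_config_matches_oracle_and_arrays(self):
        desc = build_unet(TINY_CONFIG)
        assert desc["total_params"] == hand_counted_params([8, 16, 32])
        net = UNet(TINY_CONFIG, seed=0)
        assert net.n_params() == desc["total_params"]

    def test_output_shape_equals_input_shape(self):
        cfg = UNetConfig(input_shape=(32, 32), depth=3, base_width=4)
        net = UNet(cfg, seed=0)
        x = np.random.default_rng(0).random((2, 1, 32, 32),
                                            dtype=np.float32)
        assert net.forward(x).shape == (2, 1, 32, 32)

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_unet(UNetConfig(input_shape=(100, 100), depth=4))


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        g = np.zeros((16, 16))
        g[4:9, 4:9] = 1
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-2)

    def test_all_ones_vs_uniform_half_is_one_third(self):
        g = np.ones((128, 128))
        p = np.full((128, 128), 0.5)
        assert dice_loss(g, p) == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_disjoint_is_one(self):
        g = np.zeros((8, 8))
        g[:2] = 1
        p = np.zeros((8, 8))
        p[6:] = 1.0
        assert dice_loss(g, p) == pytest.approx(1.0, abs=0.05)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.ones((4, 4)), np.ones((5, 5)))


class TestWeightMap:
    def test_single_foreground_pixel_example(self):
        g = np.zeros((4, 4), dtype=bool)
        g[1, 1] = True
        w = weight_map(g)
        # |I| = 16, |I1| = |C1| = 1 -> log(1 + 16 + 16)
        assert w[1, 1] == pytest.approx(np.log(33.0))
        # interior background pixel not adjacent to the structure
        assert w[3, 3] == pytest.approx(np.log(1 + 16 / 15))
        # background contour pixel: |C0| = 4
        assert w[0, 1] == pytest.approx(np.log(1 + 16 / 15 + 4.0))

    def test_minority_class_outweighs_majority_off_contour(self):
        g = np.zeros((32, 32), dtype=bool)
        g[10:14, 10:14] = True
        w = weight_map(g)
        assert w[g].min() > w[0, 0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            weight_map(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            weight_map(np.ones((4, 4), dtype=bool))

    def test_connectivity_8_grows_contours(self):
        g = np.zeros((16, 16), dtype=bool)
        g[4:10, 4:10] = True
        w4 = weight_map(g, connectivity=4)
        w8 = weight_map(g, connectivity=8)
        assert w4.shape == w8.shape
        assert not np.array_equal(w4, w8)


class TestWeightedCE:
    def test_single_pixel_arithmetic(self):
        val = weighted_ce(np.array([[1.0]]), np.array([[0.5]]),
                          np.array([[2.0]]))
        assert val == pytest.approx(2.0 * np.log(2.0))

    def test_confident_correct_is_near_zero(self):
        g = np.zeros((8, 8))
        g[2:5, 2:5] = 1
        assert weighted_ce(g, g, np.full((8, 8), 3.0)) < 1e-4

    def test_strictly_decreasing_in_correct_probability(self):
        g = np.array([[1.0]])
        w = np.array([[1.5]])
        losses = [weighted_ce(g, np.array([[p]]), w)
                  for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            weighted_ce(np.ones((2, 2)), np.ones((2, 2)), np.ones((3, 3)))


class TestCombinedLoss:
    def test_is_sum_of_components(self):
        rng = np.random.default_rng(1)
        g = rng.random((16, 16)) > 0.8
        p = rng.random((16, 16))
        expected = dice_loss(g, p) + weighted_ce(g, p, weight_map(g))
        assert combined_loss(g, p) == pytest.approx(expected)

    def test_matches_independent_recomputation_8x8(self):
        """Scalar re-derivation of the full loss from first principles."""
        g = np.zeros((8, 8))
        g[2:5, 3:6] = 1.0
        rng = np.random.default_rng(7)
        p = np.clip(g * 0.8 + rng.random((8, 8)) * 0.2, 0, 1)

        # Dice term
        num = 2 * (g * p).sum() + 1.0
        den = g.sum() + p.sum() + 1.0
        l_dice = 1 - num / den
        # weight map by direct set arithmetic
        n = 64
        fg = {(r, c) for r in range(8) for c in range(8) if g[r, c] == 1}
        bg = {(r, c) for r in range(8) for c in range(8)} - fg

        def neighbors(rc):
            r, c = rc
            return {(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)}

        c1 = {p_ for p_ in fg if neighbors(p_) - fg}
        c0 = {p_ for p_ in bg if neighbors(p_) & fg}
        l_wce = 0.0
        eps = 1e-7
        for r in range(8):
            for c in range(8):
                w = n / len(fg) if (r, c) in fg else n / len(bg)
                if (r, c) in c1:
                    w += n / len(c1)
                elif (r, c) in c0:
                    w += n / len(c0)
                w = np.log1p(w)
                pc = min(max(p[r, c], eps), 1 - eps)
                l_wce -= w * (g[r, c] * np.log(pc)
                              + (1 - g[r, c]) * np.log(1 - pc))
        assert combined_loss(g, p) == pytest.approx(l_dice + l_wce,
                                                    rel=1e-9)

    def test_perfect_prediction_near_zero(self):
        g = np.zeros((16, 16))
        g[5:9, 5:9] = 1
        assert combined_loss(g, g) < 0.01


class TestAugmentation:
    def test_transform_preserves_image_mask_overlap(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((128, 128), dtype=bool)
        mask[40:80, 50:90] = True
        cfg = TrainConfig()
        for _ in range(10):
            img_t, mask_t = augment_pair(mask.astype(np.float32), mask,
                                         rng, cfg)
            d = dice_coefficient(img_t > 0.5, mask_t)
            assert d >= 0.95


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        from planistem.segnet import _loss_and_grad
        cfg = UNetConfig(input_shape=(16, 16), depth=2, base_width=3)
        net = UNet(cfg, seed=1)
        net.params = {k: v.astype(np.float64)
                      for k, v in net.params.items()}
        rng = np.random.default_rng(0)
        x = rng.random((1, 1, 16, 16))
        g = rng.random((16, 16)) > 0.7
        w = weight_map(g)

        def loss_val():
            p = _nn.sigmoid(net.forward(x))[0, 0]
            return dice_loss(g, p) + weighted_ce(g, p, w)

        logits, cache = net.forward(x, want_cache=True)
        p = _nn.sigmoid(logits)[0, 0]
        _, dlog = _loss_and_grad(g.astype(float), p, w)
        grads = net.backward(dlog[None, None].astype(np.float64), cache)
        for name in ("enc0_conv1.w", "bottleneck_conv2.w", "dec0_upconv.w",
                     "head_conv1x1.w"):
            arr = net.params[name]
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            eps, old = 1e-6, arr[idx]
            arr[idx] = old + eps
            lp = loss_val()
            arr[idx] = old - eps
            lm = loss_val()
            arr[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-3,
                                                     abs=1e-8)


@pytest.fixture(scope="module")
def tiny_run():
    cfg = UNetConfig(input_shape=(32, 32), depth=2, base_width=4)
    rng = np.random.default_rng(5)
    pairs = []
    for _ in range(10):
        m = np.zeros((32, 32), dtype=bool)
        r, c = rng.integers(6, 20, 2)
        m[r:r + 8, c:c + 8] = True
        img = m * 0.6 + 0.2 + rng.normal(0, 0.02, (32, 32))
        pairs.append((img.astype(np.float32), m))
    tcfg = TrainConfig(epochs=4, batch_size=2, shift_px=3,
                       rotation_deg=5, seed=3)
    net = UNet(cfg, seed=2)
    state, history = train(net, pairs[:8], pairs[8:], tcfg)
    return net, state, history, pairs, tcfg, cfg


class TestTrainContracts:
    def test_history_length_equals_epochs(self, tiny_run):
        _, _, history, _, tcfg, _ = tiny_run
        assert len(history) == tcfg.epochs

    def test_returned_weights_are_best_validation(self, tiny_run):
        net, _, history, pairs, _, _ = tiny_run
        from planistem.segnet import _evaluate
        val_loss, _, _ = _evaluate(net, pairs[8:])
        assert val_loss == pytest.approx(
            min(h["val_loss"] for h in history), rel=1e-6)

    def test_deterministic_given_seed(self, tiny_run):
        _, _, history, pairs, tcfg, cfg = tiny_run
        net2 = UNet(cfg, seed=2)
        _, history2 = train(net2, pairs[:8], pairs[8:], tcfg)
        assert history == history2

    def test_empty_dataset_rejected(self, tiny_run):
        *_, tcfg, cfg = tiny_run
        with pytest.raises(ValueError):
            train(UNet(cfg, seed=0), [], [], tcfg)


class TestPredict:
    def test_threshold_semantics(self):
        net = UNet(UNetConfig(input_shape=(32, 32), depth=2, base_width=4),
                   seed=0)
        img = np.random.default_rng(0).random((32, 32))
        prob, mask = predict(net, img, threshold=0.5)
        assert np.array_equal(mask, prob >= 0.5)
        _, all_on = predict(net, img, threshold=0.0)
        assert all_on.all()
        # binarization is idempotent on an already binary mask
        binary = (prob >= 0.5).astype(float)
        assert np.array_equal(binary >= 0.5, binary.astype(bool))

    def test_shape_mismatch(self):
        net = UNet(UNetConfig(input_shape=(32, 32), depth=2, base_width=4),
                   seed=0)
        with pytest.raises(ValueError):
            predict(net, np.zeros((16, 16)))


def test_save_load_round_trip(tmp_path):
    net = UNet(UNetConfig(input_shape=(32, 32), depth=2, base_width=4),
               seed=4)
    img = np.random.default_rng(1).random((32, 32))
    prob, _ = predict(net, img)
    save_model(net, tmp_path / "model.npz", history=[{"epoch": 0}])
    net2 = load_model(tmp_path / "model.npz")
    prob2, _ = predict(net2, img)
    assert np.array_equal(prob, prob2)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(g=hnp.arrays(bool, (8, 8)),
       p=hnp.arrays(np.float64, (8, 8),
                    elements=st.floats(0, 1, allow_nan=False)))
def test_dice_loss_bounds(g, p):
    assert 0.0 <= dice_loss(g, p) <= 1.0


@settings(derandomize=True, max_examples=20, deadline=None)
@given(g=hnp.arrays(bool, (12, 12)))
def test_weight_map_lower_bound(g):
    """Every pixel receives at least its class term, so w >= log 2."""
    if not g.any() or g.all():
        return
    w = weight_map(g)
    assert (w > 0).all()
    assert w.min() >= np.log(2.0) - 1e-12
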