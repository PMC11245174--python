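"""Network architecture contract, gradients, augmentation, training basics."""

import numpy as np
import pytest

from carotid_xsec.annotation import LabelMask
from carotid_xsec.geometry import CrossSection, PlaneSpec
from carotid_xsec.model import (
    AugmentConfig,
    NetConfig,
    ResUNet,
    TrainConfig,
    augment,
    build_unet,
    one_hot,
    predict,
    train,
)
from carotid_xsec.nnet import Adam, bce_with_logits, softmax_cross_entropy


def _plane(n_px=64, pixel_mm=0.39):
    return PlaneSpec(
        np.zeros(3),
        np.array([0.0, 0, 1]),
        np.array([1.0, 0, 0]),
        np.array([0.0, 1, 0]),
        fov_mm=n_px * pixel_mm,
        pixel_mm=pixel_mm,
        n_px=n_px,
    )


class TestArchitecture:
    def test_shape_contract_full_scale(self):
        net = build_unet(NetConfig(depth=6, base_filters=16, n_px=128))
        y = net.forward(np.zeros((1, 1, 128, 128), dtype=np.float32), train=False)
        assert y.shape == (1, 3, 128, 128)
        assert np.all(np.isfinite(y))

    def test_deepest_feature_map_side(self):
        net = build_unet(NetConfig(depth=6, base_filters=16, n_px=128))
        x = np.zeros((1, 1, 128, 128), dtype=np.float32)
        for block in net.encoder:
            x = block.forward(x, train=False)
        assert x.shape[-2:] == (4, 4)  # 128 / 2^5

    def test_channel_widths_double_per_level(self):
        net = build_unet(NetConfig(depth=6, base_filters=16, n_px=128))
        widths = [b.conv1.W.value.shape[0] for b in net.encoder]
        assert widths == [16, 32, 64, 128, 256, 512]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(depth=6, n_px=100)

    def test_parameter_count_invariant_to_seed(self):
        cfg = NetConfig(depth=4, base_filters=8, n_px=64)
        assert build_unet(cfg, seed=0).n_parameters() == build_unet(cfg, seed=99).n_parameters()

    def test_wrong_input_size_rejected(self):
        net = build_unet(NetConfig(depth=4, base_filters=8, n_px=64))
        with pytest.raises(ValueError, match="64"):
            net.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = NetConfig(depth=3, base_filters=2, n_px=8, dropout=0.0, dtype="float64")
        net = build_unet(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1, 8, 8))
        t = np.zeros((2, 3, 8, 8))
        t[:, 0] = 1

        def loss_of():
            return bce_with_logits(net.forward(x, train=True), t)

        loss, g = loss_of()
        for p in net.params():
            p.grad[...] = 0
        net.backward(g)
        params = net.params()
        for pi in [0, 5, 15, len(params) - 1]:
            p = params[pi]
            flat = p.value.ravel()
            for k in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[k]
                eps = 1e-6
                flat[k] = old + eps
                lp, _ = loss_of()
                flat[k] = old - eps
                lm, _ = loss_of()
                flat[k] = old
                numeric = (lp - lm) / (2 * eps)
                assert p.grad.ravel()[k] == pytest.approx(numeric, abs=1e-7, rel=1e-4)

    def test_perfect_prediction_loss_near_zero(self):
        t = np.zeros((1, 3, 8, 8))
        t[:, 2] = 1
        logits = np.where(t > 0.5, 30.0, -30.0)
        loss, _ = bce_with_logits(logits, t)
        assert loss <= 1e-5
        loss_sm, _ = softmax_cross_entropy(logits, t)
        assert loss_sm <= 1e-5


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0, 1, (64, 64))
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:40, 25:45] = 2
        mask[15:20, 20:50] = 1
        return img, mask

    def test_disabled_is_identity(self):
        img, mask = self._pair()
        out_img, out_mask = augment(img, mask, AugmentConfig(enabled=False), np.random.default_rng(0))
        assert out_img is img and out_mask is mask

    def test_degenerate_ranges_are_identity(self):
        img, mask = self._pair()
        cfg = AugmentConfig(rot_deg=(0.0, 0.0), trans_px=0, scale=(1.0, 1.0))
        out_img, out_mask = augment(img, mask, cfg, np.random.default_rng(0))
        assert np.allclose(out_img, img, atol=1e-9)
        assert np.array_equal(out_mask, mask)

    def test_labels_preserved(self):
        img, mask = self._pair()
        rng = np.random.default_rng(3)
        for _ in range(10):
            _, out_mask = augment(img, mask, AugmentConfig(), rng)
            assert set(np.unique(out_mask)) <= {0, 1, 2}

    def test_pure_translation_shifts_mask(self):
        img, mask = self._pair()
        cfg = AugmentConfig(rot_deg=(0.0, 0.0), trans_px=5, scale=(1.0, 1.0))
        rng = np.random.default_rng(1)
        _, out_mask = augment(img, mask, cfg, rng)
        assert out_mask.sum() > 0  # content stays on the grid for small shifts


class TestTrainPredict:
    def _tiny_dataset(self, n=3):
        rng = np.random.default_rng(0)
        plane = _plane(32, 0.39)
        data = []
        for _ in range(n):
            mask = np.zeros((32, 32), dtype=np.uint8)
            c = rng.integers(12, 20, 2)
            yy, xx = np.mgrid[:32, :32]
            d = np.hypot(xx - c[0], yy - c[1])
            mask[d < 8] = 1
            mask[d < 5] = 2
            img = np.where(mask == 2, -1.5, np.where(mask == 1, 1.2, 0.0))
            img = img + rng.normal(0, 0.1, img.shape)
            img = (img - img.mean()) / img.std()
            data.append(
                (CrossSection(img, _plane(32, 0.39), normalized=True), LabelMask(mask, 0.39))
            )
        return data

    def test_loss_decreases(self):
        data = self._tiny_dataset()
        net = build_unet(NetConfig(depth=3, base_filters=4, n_px=32), seed=0)
        cfg = TrainConfig(epochs=20, batch_size=4, seed=0, augmentation=AugmentConfig(enabled=False))
        history = train(net, data, cfg)
        assert history[-1] <= history[0]
        assert len(history) == 20

    def test_predict_deterministic_and_valid(self):
        data = self._tiny_dataset(1)
        net = build_unet(NetConfig(depth=3, base_filters=4, n_px=32), seed=0)
        cs = data[0][0]
        a = predict(net, cs)
        b = predict(net, cs)
        assert np.array_equal(a.labels, b.labels)
        assert set(np.unique(a.labels)) <= {0, 1, 2}

    def test_training_reproducible_under_seed(self):
        data = self._tiny_dataset()
        cfg = TrainConfig(epochs=3, batch_size=2, seed=5)
        h1 = train(build_unet(NetConfig(depth=3, base_filters=4, n_px=32), seed=1), data, cfg)
        h2 = train(build_unet(NetConfig(depth=3, base_filters=4, n_px=32), seed=1), data, cfg)
        assert h1 == h2

    def test_unnormalized_input_warns(self):
        data = self._tiny_dataset(1)
        cs, mask = data[0]
        bad = CrossSection(cs.image * 10 + 5, cs.plane, normalized=True)
        net = build_unet(NetConfig(depth=3, base_filters=4, n_px=32), seed=0)
        with pytest.warns(UserWarning, match="normalized"):
            train(net, [(bad, mask)], TrainConfig(epochs=1, batch_size=1, seed=0))

    def test_save_load_roundtrip(self, tmp_path):
        data = self._tiny_dataset(1)
        net = build_unet(NetConfig(depth=3, base_filters=4, n_px=32), seed=0)
        train(net, data, TrainConfig(epochs=2, batch_size=1, seed=0))
        net.save(tmp_path / "model")
        clone = ResUNet.load(tmp_path / "model")
        a = predict(net, data[0][0])
        b = predict(clone, data[0][0])
        assert np.array_equal(a.labels, b.labels)


class TestOneHot:
    def test_encoding_matches_labels(self):
        labels = np.array([[[0, 1], [2, 1]]], dtype=np.uint8)
        oh = one_hot(labels)
        assert oh.shape == (1, 3, 2, 2)
        assert oh[0, 0, 0, 0] == 1 and oh[0, 1, 0, 1] == 1 and oh[0, 2, 1, 0] == 1
        assert np.all(oh.sum(axis=1) == 1)
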