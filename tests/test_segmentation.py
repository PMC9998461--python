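"""BCE-Dice loss closed forms, input channels and segmentation training."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervicad.labels import OrdinalLabel
from cervicad.phantom import generate_phantom_slide
from cervicad.segmentation import (SegConfig, SegModel, bce_dice_loss, predict_mask,
                                   to_input_channels, train_segmenter)
from cervicad import nn


class TestBceDiceLoss:
    def test_perfect_all_ones(self):
        x = np.ones((8, 8))
        terms = bce_dice_loss(x, x)
        assert terms.dice_loss == pytest.approx(0.0)
        assert terms.bce == pytest.approx(0.0, abs=1e-5)
        assert terms.total == pytest.approx(0.0, abs=1e-5)

    def test_perfect_all_zeros_rescued_by_smoothing(self):
        z = np.zeros((8, 8))
        terms = bce_dice_loss(z, z)
        assert terms.dice_loss == pytest.approx(0.0)
        assert terms.total == pytest.approx(0.0, abs=1e-5)

    def test_hand_computed_mixed_case(self):
        """target=[1,0], pred=[.5,.5]: dice = 1/3, bce = ln 2."""
        terms = bce_dice_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert terms.dice_loss == pytest.approx(1 / 3)
        assert terms.bce == pytest.approx(np.log(2))
        assert terms.total == pytest.approx(1 / 3 + np.log(2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_non_negative_and_zero_only_at_exact_match(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((6, 6))
        target = (rng.random((6, 6)) > 0.5).astype(float)
        terms = bce_dice_loss(pred, target)
        assert terms.total >= 0
        if not np.array_equal(pred, target):
            assert terms.total > 0

    def test_dice_term_symmetric_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        a = (rng.random(50) > 0.5).astype(float)
        b = (rng.random(50) > 0.5).astype(float)
        assert bce_dice_loss(a, b).dice_loss == pytest.approx(bce_dice_loss(b, a).dice_loss)
        perm = rng.permutation(50)
        assert bce_dice_loss(a[perm], b[perm]).dice_loss == pytest.approx(
            bce_dice_loss(a, b).dice_loss)


class TestInputChannels:
    def test_gray_pixel_has_zero_saturation(self):
        img = np.full((4, 4, 3), 120, np.uint8)
        assert to_input_channels(img, "saturation").max() == 0.0

    def test_pure_red_has_full_saturation(self):
        img = np.zeros((2, 2, 3), np.uint8)
        img[..., 0] = 255
        np.testing.assert_allclose(to_input_channels(img, "saturation"), 1.0)

    def test_gray_matches_per_pixel_luma_formula(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 255, size=(8, 8, 3), dtype=np.uint8)
        out = to_input_channels(img, "gray")[0]
        f = img.astype(float) / 255.0
        expected = 0.2125 * f[..., 0] + 0.7154 * f[..., 1] + 0.0721 * f[..., 2]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_channel_counts(self):
        img = np.zeros((4, 4, 3), np.uint8)
        assert to_input_channels(img, "rgb").shape == (3, 4, 4)
        assert to_input_channels(img, "gray").shape == (1, 4, 4)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            to_input_channels(np.zeros((4, 4, 3), np.uint8), "hue")
        with pytest.raises(ValueError):
            SegConfig(input_mode="hue")


def _tiny_pairs(small_cfg, seeds, crop_size=64):
    from cervicad.datasets import build_segmentation_pairs, records_from_phantoms

    phantoms = [generate_phantom_slide(small_cfg, OrdinalLabel.LSIL, seed=s) for s in seeds]
    return build_segmentation_pairs(records_from_phantoms(phantoms), crop_size=crop_size)


class TestTraining:
    def test_overfit_one_sample_dice_decreases(self, small_cfg):
        """Training dice on a single image drops over every 10-epoch window
        once past the first epochs where the BCE term dominates; small
        plateaus are tolerated."""
        pairs = _tiny_pairs(small_cfg, [42], crop_size=128)[:1]
        cfg = SegConfig(depth=2, base_filters=4, learning_rate=3e-3, batch_size=1,
                        epochs=40, seed=0)
        model = train_segmenter(pairs, pairs, cfg)
        dice = [h["train_dice_loss"] for h in model.history]
        for i in range(5, len(dice) - 10):
            assert dice[i + 10] <= dice[i] + 0.01
        assert dice[-1] < dice[0] - 0.2

    def test_returned_checkpoint_is_argmin_of_val_loss(self, small_cfg):
        pairs = _tiny_pairs(small_cfg, [42, 43, 44])
        cfg = SegConfig(depth=2, base_filters=4, learning_rate=3e-3, batch_size=2,
                        epochs=6, seed=0)
        model = train_segmenter(pairs[:2], pairs[2:3], cfg)
        assert model.best_val_loss <= model.history[-1]["val_loss"] + 1e-12
        assert model.best_val_loss == pytest.approx(
            min(h["val_loss"] for h in model.history))

    def test_same_seed_gives_identical_checkpoints(self, small_cfg, tmp_path):
        pairs = _tiny_pairs(small_cfg, [42, 43, 44])
        cfg = SegConfig(depth=2, base_filters=4, learning_rate=3e-3, batch_size=2,
                        epochs=3, seed=11)
        m1 = train_segmenter(pairs[:2], pairs[2:3], cfg)
        m2 = train_segmenter(pairs[:2], pairs[2:3], cfg)
        assert m1.digest() == m2.digest()
        m1.save(tmp_path / "ck")
        loaded = SegModel.load(tmp_path / "ck")
        assert loaded.digest() == m1.digest()

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], [], SegConfig())


class TestPredictMask:
    def _zero_logit_model(self):
        cfg = SegConfig(depth=1, base_filters=2, seed=0)
        net = nn.UNet(in_channels=3, depth=1, base_filters=2, rng=np.random.default_rng(0))
        for p in net.params():
            p.value[...] = 0.0
        return SegModel(net, cfg)

    def test_zero_logits_give_empty_mask_at_default_threshold(self):
        from cervicad.slide_io import Box, FragmentCrop

        crop = FragmentCrop(np.zeros((32, 32, 3), np.uint8), Box(0, 0, 32, 32), 1.0, 1.0)
        model = self._zero_logit_model()
        assert predict_mask(model, crop).sum() == 0

    def test_threshold_zero_gives_all_foreground(self):
        from cervicad.slide_io import Box, FragmentCrop

        crop = FragmentCrop(np.zeros((32, 32, 3), np.uint8), Box(0, 0, 32, 32), 1.0, 1.0)
        model = self._zero_logit_model()
        assert predict_mask(model, crop, threshold=0.0).all()
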