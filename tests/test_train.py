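"""Training-recipe contracts: region-target construction, soft-Dice loss
closed forms and loss/metric consistency, augmentation geometry, and the
overfit-sanity behavior of the training loop."""

import numpy as np
import pytest

from rectseg import metrics
from rectseg.train import (
    TrainConfig,
    augment_pair,
    dice_loss,
    make_region_target,
    one_hot_targets,
    region_mask,
    train_model,
)
from rectseg.unet import SOFTMAX, UNetConfig, build_unet

from conftest import random_blob_mask


class TestRegionTargets:
    def _slice(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[5:7, 5:10] = 1   # 10 lumen px
        labels[8:12, 5:10] = 2  # 20 wall px
        labels[14:16, 2:6] = 3  # fat
        labels[0:2, 16:20] = 4  # muscle
        return labels

    def test_wall_target_is_filled_union(self):
        t = make_region_target(self._slice(), "wall")
        assert int(t.mask.sum()) == 30
        assert set(np.unique(t.mask)) <= {0, 1}

    def test_lumen_nested_in_wall(self):
        labels = self._slice()
        lumen = make_region_target(labels, "lumen").mask
        wall = make_region_target(labels, "wall").mask
        assert not (lumen & ~wall).any()

    def test_empty_fat_slice_is_valid(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        t = make_region_target(labels, "fat")
        assert not t.mask.any()

    def test_muscle_and_background_never_in_targets(self):
        labels = self._slice()
        for region in ("wall", "lumen", "fat", "wall_annulus"):
            mask = make_region_target(labels, region).mask
            assert not (mask & (labels == 4)).any()
            assert not (mask & (labels == 0)).any()

    def test_wall_annulus_alternative_target(self):
        labels = self._slice()
        assert int(make_region_target(labels, "wall_annulus").mask.sum()) == 20

    def test_unknown_region_and_bad_labels(self):
        with pytest.raises(ValueError):
            make_region_target(self._slice(), "bladder")
        with pytest.raises(ValueError):
            make_region_target(np.full((4, 4), 9, dtype=np.uint8), "wall")

    def test_one_hot_partition_maps_muscle_to_background(self):
        hot = one_hot_targets(self._slice())
        assert hot.shape == (20, 20, 4)
        np.testing.assert_allclose(hot.sum(-1), 1.0)
        assert hot[0, 16, 0] == 1.0  # muscle voxel -> background channel


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self, rng):
        m = random_blob_mask(rng).astype(float)
        assert dice_loss(m, m) <= 1e-5

    def test_no_overlap_near_one(self, rng):
        t = random_blob_mask(rng).astype(float)
        assert dice_loss(np.zeros_like(t), t) == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_prediction_closed_form(self):
        # p = 0.5 everywhere, target covers half the pixels:
        # 1 - 2*(0.25 N) / (0.5 N + 0.5 N) = 0.5
        target = np.zeros((16, 16))
        target[:8] = 1.0
        pred = np.full((16, 16), 0.5)
        assert dice_loss(pred, target) == pytest.approx(0.5, abs=1e-5)

    def test_symmetry_on_hard_masks(self, rng):
        a = random_blob_mask(rng).astype(float)
        b = random_blob_mask(rng).astype(float)
        assert dice_loss(a, b) == pytest.approx(dice_loss(b, a), abs=1e-12)

    def test_consistency_with_dice_metric(self, rng):
        """1 - dice_loss on hard binary masks equals metrics.dice."""
        for _ in range(50):
            a = random_blob_mask(rng)
            b = random_blob_mask(rng)
            if not (a.any() or b.any()):
                continue
            assert 1.0 - dice_loss(a.astype(float), b.astype(float)) == pytest.approx(
                metrics.dice(a, b), abs=1e-5
            )

    def test_multiclass_perfect_and_average(self, rng):
        labels = (random_blob_mask(rng).astype(np.uint8)
                  + random_blob_mask(rng).astype(np.uint8))
        hot = one_hot_targets(labels, 4)
        assert dice_loss(hot, labels) <= 1e-5
        assert dice_loss(hot, hot, multiclass=True) <= 1e-5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAugment:
    def _cfg(self, flip=0.5, rot=(-30.0, 30.0)):
        return TrainConfig(aug_flip_prob=flip, aug_rot_range_deg=rot)

    def test_identity_configuration(self, rng):
        img = rng.random((32, 32))
        mask = random_blob_mask(rng, (32, 32)).astype(np.uint8)
        out_i, out_m = augment_pair(img, mask, self._cfg(flip=0.0, rot=(0.0, 0.0)), 0)
        np.testing.assert_array_equal(out_i, img)
        np.testing.assert_array_equal(out_m, mask)

    def test_certain_flip_is_involution(self, rng):
        img = rng.random((32, 32))
        mask = random_blob_mask(rng, (32, 32)).astype(np.uint8)
        cfg = self._cfg(flip=1.0, rot=(0.0, 0.0))
        i1, m1 = augment_pair(img, mask, cfg, 1)
        i2, m2 = augment_pair(i1, m1, cfg, 2)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(m2, mask)

    def test_rotation_conserves_centered_disk_area(self, rng):
        yy, xx = np.mgrid[:64, :64]
        disk = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 < 15**2).astype(np.uint8)
        img = disk.astype(float)
        for seed in range(5):
            _, m = augment_pair(img, disk, self._cfg(flip=0.0), seed)
            assert set(np.unique(m)) <= {0, 1}
            assert abs(int(m.sum()) - int(disk.sum())) <= 0.05 * disk.sum()

    def test_same_transform_applied_to_both(self, rng):
        mask = random_blob_mask(rng, (32, 32)).astype(np.uint8)
        img = mask.astype(float)  # image IS the mask -> must stay aligned
        out_i, out_m = augment_pair(img, mask, self._cfg(flip=1.0), 3)
        assert metrics.dice(out_i > 0.5, out_m > 0) > 0.95


class TestTrainModel:
    def _overfit_fixture(self, rng, n=10, size=64):
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[size // 4 : size // 2, size // 4 : size // 2] = 1
        img = mask * 2.0 + 0.1 * rng.random((size, size))
        imgs = np.repeat(img[None], n, axis=0).astype(np.float32)
        tgts = np.repeat(mask[None], n, axis=0)
        return imgs, tgts

    def test_overfit_sanity_reaches_low_loss(self, rng):
        imgs, tgts = self._overfit_fixture(rng)
        model = build_unet(UNetConfig(input_size=64, depth=2, base_filters=8), seed=0)
        # small batch + raised lr so the 30-epoch budget supplies enough
        # optimizer steps to drive the trivial task to convergence
        cfg = TrainConfig(epochs=30, batch_size=2, learning_rate=0.01, seed=0,
                          region="wall", aug_flip_prob=0.0, aug_rot_range_deg=(0.0, 0.0))
        _, hist = train_model(model, (imgs, tgts), None, cfg)
        assert hist.train_loss.iloc[-1] < 0.1

    def test_history_length_matches_epochs(self, rng):
        imgs, tgts = self._overfit_fixture(rng, n=4, size=32)
        model = build_unet(UNetConfig(input_size=32, depth=2, base_filters=4), seed=0)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0)
        _, hist = train_model(model, (imgs, tgts), (imgs, tgts), cfg)
        assert len(hist) == 1
        assert {"epoch", "train_loss", "val_loss"} <= set(hist.columns)

    def test_seeding_makes_runs_identical(self, rng):
        imgs, tgts = self._overfit_fixture(rng, n=6, size=32)
        hists = []
        for _ in range(2):
            model = build_unet(UNetConfig(input_size=32, depth=2, base_filters=4), seed=2)
            cfg = TrainConfig(epochs=3, batch_size=4, seed=9)
            _, hist = train_model(model, (imgs, tgts), None, cfg)
            hists.append(hist)
        np.testing.assert_array_equal(
            hists[0].train_loss.to_numpy(), hists[1].train_loss.to_numpy()
        )

    def test_loss_trend_non_increasing_late_in_training(self, rng):
        """Mean loss over the last epochs does not exceed the preceding
        window in at least 8 of 10 seeded runs."""
        imgs, tgts = self._overfit_fixture(rng, n=8, size=32)
        ok = 0
        for seed in range(10):
            model = build_unet(UNetConfig(input_size=32, depth=2, base_filters=4), seed=seed)
            cfg = TrainConfig(epochs=20, batch_size=8, seed=seed)
            _, hist = train_model(model, (imgs, tgts), None, cfg)
            tail = hist.train_loss.to_numpy()
            if tail[-5:].mean() <= tail[-10:-5].mean() + 1e-3:
                ok += 1
        assert ok >= 8, f"loss decreased late in only {ok}/10 runs"

    def test_empty_dataset_rejected(self):
        model = build_unet(UNetConfig(input_size=32, depth=2, base_filters=4), seed=0)
        with pytest.raises(ValueError):
            train_model(model, (np.zeros((0, 32, 32)), np.zeros((0, 32, 32))), None,
                        TrainConfig(epochs=1))

    def test_multiclass_training_step_runs(self, rng):
        labels = np.zeros((6, 32, 32), dtype=np.uint8)
        labels[:, 8:16, 8:16] = 2
        labels[:, 10:14, 10:14] = 1
        labels[:, 20:26, 20:26] = 3
        imgs = labels.astype(np.float32) + 0.05 * rng.random((6, 32, 32)).astype(np.float32)
        cfg = UNetConfig(input_size=32, depth=2, base_filters=4, head=SOFTMAX, n_classes=4)
        model = build_unet(cfg, seed=0)
        _, hist = train_model(
            model, (imgs, labels), None,
            TrainConfig(epochs=2, batch_size=4, seed=0, region="multiclass"),
        )
        assert np.isfinite(hist.train_loss).all()


def test_region_mask_matches_make_region_target(rng):
    labels = rng.integers(0, 5, (10, 10)).astype(np.uint8)
    for region in ("wall", "lumen", "fat"):
        np.testing.assert_array_equal(
            region_mask(labels, region), make_region_target(labels, region).mask.astype(bool)
        )
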