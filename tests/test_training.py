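"""Training protocol: poly decay, epoch sample accounting, early
stopping, overfit convergence and cross-validation plumbing."""

import numpy as np
import pytest

from marblingnet.data_io import DatasetIndex, DatasetRecord, save_image, save_mask
from marblingnet.losses import LossConfig
from marblingnet.network import MarblingNet, ModelConfig
from marblingnet.synthetic import SyntheticParams, generate_image
from marblingnet.training import (TrainConfig, _epoch_samples, cross_validate,
                                  poly_lr, train_fold)


def _tiny_pair(seed, side=48):
    params = SyntheticParams.for_size(side, side)
    s = generate_image(params, np.random.default_rng(seed))
    return s.image, s.mask


def _tiny_model(seed=0):
    return MarblingNet(ModelConfig.scaled(base_width=2, upsample_factor=1, seed=seed))


class TestPolyLr:
    def test_epoch_zero_is_base_rate(self):
        assert poly_lr(1e-4, 0, 400) == pytest.approx(1e-4)

    def test_final_epoch_is_zero(self):
        assert poly_lr(1e-4, 400, 400) == 0.0

    def test_hand_arithmetic(self):
        assert poly_lr(1e-4, 100, 400, power=1) == pytest.approx(7.5e-5)

    def test_nonincreasing_and_terminal_zero(self):
        rates = [poly_lr(1e-3, e, 50) for e in range(51)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            poly_lr(1e-4, 401, 400)
        with pytest.raises(ValueError):
            poly_lr(1e-4, 10, 400, power=0)


class TestEpochAccounting:
    def test_patch_based_multiplies_sample_count(self):
        img, mask = _tiny_pair(0, side=100)  # 100x100, patch 50 -> 4 patches
        cfg = TrainConfig(patch_size=50, patch_based=True, augmentation=None, seed=0)
        assert len(_epoch_samples([(img, mask)] * 3, cfg, np.random.default_rng(0))) == 12

    def test_patch_free_keeps_one_sample_per_image(self):
        img, mask = _tiny_pair(0)
        cfg = TrainConfig(patch_based=False, augmentation=None, seed=0)
        assert len(_epoch_samples([(img, mask)] * 5, cfg, np.random.default_rng(0))) == 5

    def test_canonical_image_yields_eight_200px_patches(self):
        img = np.zeros((400, 800, 3), np.uint8)
        mask = np.zeros((400, 800), np.uint8)
        cfg = TrainConfig(patch_size=200, augmentation=None)
        assert len(_epoch_samples([(img, mask)], cfg, np.random.default_rng(0))) == 8


class TestTrainFold:
    def test_overfits_single_image_to_low_loss(self):
        """Convergence smoke test: one image, <= 200 gradient steps."""
        img, mask = _tiny_pair(1)
        model = MarblingNet(ModelConfig.scaled(base_width=4, upsample_factor=1,
                                               seed=0))
        cfg = TrainConfig(batch_size=1, max_epochs=200, base_lr=5e-3,
                          early_stop_patience=200, patch_based=False,
                          augmentation=None, seed=0)
        res = train_fold(model, [(img, mask)], [], cfg, LossConfig("ce_ls"))
        assert min(res.train_loss) < 0.1

    def test_frozen_model_stops_after_exactly_two_epochs(self):
        """With lr ~ 0 and frozen normalization statistics nothing improves
        after the first epoch, so patience 1 ends training at epoch 2."""
        img, mask = _tiny_pair(2)
        model = _tiny_model()
        for m in model.modules():
            if hasattr(m, "momentum"):
                m.momentum = 0.0  # freeze running statistics too
        cfg = TrainConfig(batch_size=1, max_epochs=50, base_lr=1e-12,
                          early_stop_patience=1, patch_based=False,
                          augmentation=None, seed=0)
        res = train_fold(model, [(img, mask)], [(img, mask)], cfg)
        assert len(res.train_loss) == 2

    def test_identical_seed_identical_first_epoch_loss(self):
        img, mask = _tiny_pair(3)
        cfg = TrainConfig(batch_size=1, max_epochs=1, base_lr=1e-3,
                          patch_based=False, seed=5)
        losses = []
        for _ in range(2):
            res = train_fold(_tiny_model(seed=7), [(img, mask)], [], cfg)
            losses.append(res.train_loss[0])
        assert losses[0] == losses[1]

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_fold(_tiny_model(), [], [], TrainConfig(max_epochs=1))

    def test_non_divisible_patch_size_rejected(self):
        img, mask = _tiny_pair(4)  # 48x48
        cfg = TrainConfig(patch_size=50, patch_based=True, max_epochs=1)
        with pytest.raises(ValueError, match="not divisible"):
            train_fold(_tiny_model(), [(img, mask)], [], cfg)

    def test_non_finite_loss_aborts_with_diagnostic(self):
        img, mask = _tiny_pair(5)
        model = _tiny_model()
        for _, p in model.named_parameters():
            p.data[:] = np.nan
        cfg = TrainConfig(batch_size=1, max_epochs=1, patch_based=False,
                          augmentation=None)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_fold(model, [(img, mask)], [], cfg)


class TestCrossValidate:
    def test_173_records_split_into_published_sizes(self):
        idx = DatasetIndex([DatasetRecord(f"{i}.png", f"{i}_m.png")
                            for i in range(173)])
        idx.assign_folds(5, seed=0)
        val_sizes = sorted(len(idx.split(f)[1]) for f in range(5))
        train_sizes = sorted(len(idx.split(f)[0]) for f in range(5))
        assert val_sizes == [34, 34, 35, 35, 35]
        assert train_sizes == [138, 138, 138, 139, 139]

    def test_two_folds_on_four_images(self, tmp_path):
        for i in range(4):
            img, mask = _tiny_pair(10 + i)
            save_image(tmp_path / f"{i}.png", img)
            save_mask(tmp_path / f"{i}_m.png", mask)
        idx = DatasetIndex([DatasetRecord(str(tmp_path / f"{i}.png"),
                                          str(tmp_path / f"{i}_m.png"))
                            for i in range(4)])
        cfg = TrainConfig(batch_size=2, max_epochs=1, base_lr=1e-3,
                          patch_based=False, augmentation=None, seed=0)
        out = cross_validate(idx, k=2, cfg=cfg,
                             model_cfg=ModelConfig.scaled(base_width=2,
                                                          upsample_factor=1))
        assert len(out["folds"]) == 2
        assert set(out["mean"]) == {"iou", "precision", "recall", "f1"}
        # validation sets are disjoint and cover all records
        vals = [set(r.mask for r in idx.split(f)[1]) for f in range(2)]
        assert not (vals[0] & vals[1]) and len(vals[0] | vals[1]) == 4

    def test_too_few_records_rejected(self):
        idx = DatasetIndex([DatasetRecord("a.png", "a_m.png")])
        with pytest.raises(ValueError):
            cross_validate(idx, k=5)
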