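"""Segmentation model, training protocol and metrics."""

import numpy as np
import pytest

from bbtquant.phantom import PhantomConfig, generate_phantom
from bbtquant.segmentation import (
    TrainConfig,
    boundary_f1,
    build_model,
    make_patch_dataset,
    seg_metrics,
    train,
)
from bbtquant.segmentation.unet import UNet
from oracles import seg_metrics_oracle


class TestBuildModel:
    @pytest.mark.parametrize("channels", [1, 3, 4])
    def test_input_channels(self, channels):
        model = build_model(channels)
        assert model.enc1.c_in == channels
        x = np.zeros((2, channels, 64, 64), dtype=np.float32)
        assert model.forward(x).shape == (2, 2, 64, 64)

    def test_unsupported_channels(self):
        with pytest.raises(ValueError):
            build_model(2)

    def test_seeded_init_identical(self):
        a, b = build_model(4, seed=11), build_model(4, seed=11)
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa, pb)
        c = build_model(4, seed=12)
        assert any(not np.array_equal(pa, pc) for pa, pc in zip(a.params, c.params))


class TestTrainProtocol:
    def test_lr_schedule_closed_form(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(0) == pytest.approx(1e-3)
        assert cfg.lr_at_epoch(9) == pytest.approx(1e-3)
        assert cfg.lr_at_epoch(10) == pytest.approx(3e-4)
        assert cfg.lr_at_epoch(25) == pytest.approx(9e-5)

    def test_early_stopping_after_patience_checks(self, monkeypatch, rng):
        monkeypatch.setattr(UNet, "evaluate", lambda self, x, y, b=8: (1.0, 0.5))
        x = rng.random((12, 1, 16, 16)).astype(np.float32)
        y = (rng.random((12, 16, 16)) > 0.5).astype(np.int64)
        cfg = TrainConfig(channels_mode="raw", epochs=50, patience=4, batch_size=4)
        history = train(build_model(1), x, y, cfg)
        # the first check sets the best; the next 4 non-improving checks stop
        assert len(history.val_loss) == 1 + cfg.patience
        assert history.stopped_epoch == cfg.patience

    def test_loss_decreases_on_phantoms(self):
        samples = [
            generate_phantom(PhantomConfig(seed=s, contour_wobble=0.1)) for s in range(24)
        ]
        x, y = make_patch_dataset(samples, "raw")
        cfg = TrainConfig(channels_mode="raw", epochs=3, seed=0)
        model = build_model(1)
        history = train(model, x, y, cfg)
        assert history.train_loss[-1] < history.train_loss[0]
        assert len(history.lr) == len(history.train_loss)

    def test_non_binary_masks_rejected(self, rng):
        x = rng.random((4, 1, 16, 16)).astype(np.float32)
        y = rng.integers(0, 3, (4, 16, 16))
        with pytest.raises(ValueError):
            train(build_model(1), x, y, TrainConfig(channels_mode="raw"))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(
                build_model(1),
                np.zeros((0, 1, 16, 16), np.float32),
                np.zeros((0, 16, 16), np.int64),
                TrainConfig(channels_mode="raw"),
            )


class TestPatchDataset:
    def test_channel_counts_per_mode(self):
        samples = [generate_phantom(PhantomConfig(seed=3))]
        for mode, c in (("raw", 1), ("fusion", 3), ("raw_plus_fusion", 4)):
            x, y = make_patch_dataset(samples, mode)
            assert x.shape == (1, c, 64, 64)
            assert y.shape == (1, 64, 64)
            assert x.dtype == np.float32 and 0.0 <= x.min() and x.max() <= 1.0
            assert set(np.unique(y)) <= {0, 1}


class TestSegMetrics:
    def test_perfect_prediction(self, rng):
        gt = rng.random((16, 16)) < 0.5
        m = seg_metrics(gt, gt)
        assert m.mean_acc == m.mean_iou == m.bf1 == 1.0

    def test_all_background_vs_half_lesion(self):
        gt = np.zeros((10, 10), dtype=bool)
        gt[:, :5] = True
        pred = np.zeros((10, 10), dtype=bool)
        m = seg_metrics(pred, gt)
        assert m.mean_iou == pytest.approx((0.5 + 0.0) / 2)
        assert m.mean_acc == pytest.approx((1.0 + 0.0) / 2)

    def test_one_pixel_shift_full_bf1_at_theta2(self):
        gt = np.zeros((20, 20), dtype=bool)
        gt[5:15, 5:15] = True
        pred = np.roll(gt, 1, axis=1)
        assert boundary_f1(pred, gt, theta=2) == 1.0

    def test_bf1_symmetric_and_monotone_in_theta(self, rng):
        a = rng.random((16, 16)) < 0.5
        b = rng.random((16, 16)) < 0.5
        vals = [boundary_f1(a, b, theta=t) for t in (1, 2, 4, 8)]
        assert vals == sorted(vals)
        for t in (1, 3):
            assert boundary_f1(a, b, theta=t) == boundary_f1(b, a, theta=t)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            pred = rng.random((12, 12)) < rng.uniform(0.2, 0.8)
            gt = rng.random((12, 12)) < rng.uniform(0.2, 0.8)
            theta = float(rng.integers(1, 4))
            m = seg_metrics(pred, gt, theta)
            acc_o, iou_o, bf1_o = seg_metrics_oracle(
                pred.astype(int), gt.astype(int), theta
            )
            assert m.mean_acc == pytest.approx(acc_o)
            assert m.mean_iou == pytest.approx(iou_o)
            assert m.bf1 == pytest.approx(bf1_o)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg_metrics(np.zeros((4, 4), bool), np.zeros((5, 5), bool))
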