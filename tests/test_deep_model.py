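import numpy as np
import pytest

from cycleseg import deep_model as dm


TINY = dm.NetworkConfig(base_channels=2, pool_kernels=((2, 2, 2),) * 3, dtype="float64")


class TestArchitecture:
    def test_block_counts_and_head(self):
        net = dm.UNet3D(TINY, seed=0)
        assert len(net.enc) == 4
        assert len(net.dec) == 3
        assert net.final.k == 1
        assert net.final.c_out == 1

    def test_forward_shape_and_range(self):
        net = dm.UNet3D(dm.NetworkConfig(base_channels=2), seed=0)
        x = np.random.default_rng(0).normal(size=(20, 32, 32))
        p = net.forward(x, train=False)
        assert p.shape == (20, 32, 32)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_default_z_pooling_handles_depth_20(self):
        # (2,2,2), (2,2,2), (1,2,2) takes z 20 -> 10 -> 5 -> 5 and back
        net = dm.UNet3D(dm.NetworkConfig(base_channels=2), seed=0)
        p = net.forward(np.zeros((20, 16, 16)), train=False)
        assert p.shape == (20, 16, 16)

    def test_indivisible_axis_raises_naming_axis(self):
        net = dm.UNet3D(TINY, seed=0)
        with pytest.raises(ValueError, match="axis z"):
            net.forward(np.zeros((10, 16, 16)))

    def test_channel_doubling(self):
        net = dm.UNet3D(dm.NetworkConfig(base_channels=4), seed=0)
        assert [blk[0].conv.c_out for blk in net.enc] == [4, 8, 16, 32]

    def test_repeated_inference_identical(self):
        net = dm.UNet3D(TINY, seed=0)
        x = np.random.default_rng(1).normal(size=(8, 8, 8))
        a = net.forward(x, train=False)
        b = net.forward(x, train=False)
        np.testing.assert_array_equal(a, b)


class TestGradients:
    @pytest.mark.parametrize("loss", ["gdl", "dice", "bce", "wce"])
    def test_backprop_matches_finite_differences(self, loss):
        net = dm.UNet3D(TINY, seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 8, 8))
        t = (rng.random((8, 8, 8)) < 0.1).astype(float)
        loss_fn, grad_fn = dm.LOSSES[loss]
        p = net.forward(x, train=True)
        net.zero_grad()
        net.backward(grad_fn(p, t))
        checked = 0
        for name, params, grads in net.parameters():
            for k in params:
                flat, gflat = params[k].ravel(), grads[k].ravel()
                for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                    eps, old = 1e-5, flat[i]
                    flat[i] = old + eps
                    lp = loss_fn(net.forward(x, train=True), t)
                    flat[i] = old - eps
                    lm = loss_fn(net.forward(x, train=True), t)
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = gflat[i]
                    assert abs(num - ana) <= 1e-6 + 1e-4 * (abs(num) + abs(ana)), (name, k, i)
                    checked += 1
        assert checked > 20


class TestLosses:
    def test_gdl_identities(self):
        t = (np.random.default_rng(0).random((4, 4, 4)) < 0.2).astype(float)
        assert dm.gdl_loss(t, t) == pytest.approx(0.0, abs=1e-12)
        assert dm.gdl_loss(1 - t, t) == pytest.approx(1.0, abs=1e-12)

    def test_gdl_two_voxel_hand_example(self):
        # t=[1,0], p=[0.5,0.5]: w_fg=w_bg=1, numerator 1, denominator 4
        assert dm.gdl_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(0.5)

    def test_gdl_empty_foreground_capped_not_nan(self):
        t = np.zeros((3, 3, 3))
        p = np.full((3, 3, 3), 0.2)
        val = dm.gdl_loss(p, t)
        assert np.isfinite(val) and 0.0 <= val <= 1.0

    def test_dice_identities(self):
        t = np.zeros((3, 3, 3))
        t[1, 1, 1] = 1
        assert dm.dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)
        disjoint = np.zeros_like(t)
        disjoint[0, 0, 0] = 1
        assert dm.dice_loss(disjoint, t) == pytest.approx(1.0, abs=1e-6)
        assert dm.dice_loss(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(1 / 3, abs=1e-6)

    def test_cross_entropy_values(self):
        assert dm.cross_entropy_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(np.log(2), abs=1e-9)
        t = np.array([1.0, 0.0])
        assert dm.cross_entropy_loss(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_weighted_equals_unweighted_when_balanced(self):
        t = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.array([0.8, 0.6, 0.3, 0.1])
        assert dm.cross_entropy_loss(p, t, weighted=True) == pytest.approx(
            dm.cross_entropy_loss(p, t, weighted=False)
        )

    def test_losses_bounded(self):
        rng = np.random.default_rng(5)
        p = rng.random((4, 4, 4))
        t = (rng.random((4, 4, 4)) < 0.3).astype(float)
        assert 0.0 <= dm.gdl_loss(p, t) <= 1.0
        assert 0.0 <= dm.dice_loss(p, t) <= 1.0


class TestNormalizeAugment:
    def test_zero_mean_unit_variance(self):
        v = np.random.default_rng(0).random((6, 6, 6)) * 50 + 7
        out = dm.normalize_volume(v)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6

    def test_two_value_volume(self):
        v = np.zeros((2, 2, 2))
        v[0] = 2.0
        out = dm.normalize_volume(v)
        assert set(np.round(out.ravel(), 6)) == {-1.0, 1.0}

    def test_constant_volume_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = dm.normalize_volume(np.full((3, 3, 3), 4.0))
        assert not out.any()

    def test_augment_involutions_preserve_multiset(self):
        rng = np.random.default_rng(0)
        patch = rng.random((4, 6, 6))
        target = (rng.random((4, 6, 6)) < 0.2).astype(float)
        for seed in range(8):
            p2, t2 = dm.augment_pair(patch, target, np.random.default_rng(seed))
            assert p2.shape == patch.shape
            np.testing.assert_allclose(np.sort(p2.ravel()), np.sort(patch.ravel()))
        # flips and rotations applied jointly: foreground count preserved
            assert t2.sum() == target.sum()

    def test_non_square_plane_skips_odd_rotation(self):
        patch = np.zeros((2, 4, 6))
        target = np.zeros((2, 4, 6))
        for seed in range(10):
            p2, t2 = dm.augment_pair(patch, target, np.random.default_rng(seed))
            assert p2.shape == (2, 4, 6)


class TestTraining:
    def test_single_patch_memorization_gdl(self):
        """A small net overfits one synthetic patch: training loss drops below 0.1."""
        rng = np.random.default_rng(3)
        t = np.zeros((8, 16, 16))
        t[3:6, 6:10, 6:10] = 1.0
        x = t * 5 + rng.normal(0, 0.3, size=t.shape)
        cfg = dm.TrainingConfig(
            patch_size=(8, 16, 16), epochs=300, loss="gdl", seed=0, augment=False, learning_rate=2e-3
        )
        net_cfg = dm.NetworkConfig(base_channels=4, pool_kernels=((2, 2, 2),) * 3)
        model, hist = dm.train_model([x], [t], net=net_cfg, cfg=cfg)
        assert min(hist["train_loss"]) < 0.1

    def test_histories_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        t = (rng.random((8, 16, 16)) < 0.05).astype(float)
        x = t * 3 + rng.normal(size=t.shape) * 0.1
        cfg = dm.TrainingConfig(patch_size=(8, 16, 16), epochs=3, loss="dice", seed=5)
        net_cfg = dm.NetworkConfig(base_channels=2, pool_kernels=((2, 2, 2),) * 3)
        _, h1 = dm.train_model([x], [t], net=net_cfg, cfg=cfg)
        _, h2 = dm.train_model([x], [t], net=net_cfg, cfg=cfg)
        assert h1["train_loss"] == h2["train_loss"]

    def test_best_epoch_is_argmin_of_validation(self):
        rng = np.random.default_rng(3)
        t = (rng.random((8, 16, 16)) < 0.05).astype(float)
        x = t * 3 + rng.normal(size=t.shape) * 0.1
        cfg = dm.TrainingConfig(patch_size=(8, 16, 16), epochs=4, loss="dice", seed=5)
        net_cfg = dm.NetworkConfig(base_channels=2, pool_kernels=((2, 2, 2),) * 3)
        _, hist = dm.train_model([x], [t], [x], [t], net=net_cfg, cfg=cfg)
        assert hist["best_epoch"] == int(np.argmin(hist["val_loss"]))

    def test_all_background_training_set_aborts(self):
        with pytest.raises(ValueError, match="foreground"):
            dm.train_model(
                [np.random.default_rng(0).random((8, 16, 16))],
                [np.zeros((8, 16, 16))],
                net=dm.NetworkConfig(base_channels=2, pool_kernels=((2, 2, 2),) * 3),
                cfg=dm.TrainingConfig(patch_size=(8, 16, 16), epochs=1),
            )


class TestPredictVolume:
    def test_output_shape_range_and_small_volume_padding(self):
        net = dm.UNet3D(dm.NetworkConfig(base_channels=2, pool_kernels=((2, 2, 2),) * 3), seed=0)
        cfg = dm.TrainingConfig(patch_size=(8, 16, 16))
        vol = np.random.default_rng(0).random((6, 20, 12))  # smaller than patch in z and x
        out = dm.predict_volume(net, vol, cfg)
        assert out.shape == vol.shape
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        net = dm.UNet3D(dm.NetworkConfig(base_channels=2, pool_kernels=((2, 2, 2),) * 3), seed=3)
        cfg = dm.TrainingConfig(patch_size=(8, 16, 16), loss="gdl")
        x = np.random.default_rng(0).normal(size=(8, 16, 16))
        before = net.forward(x, train=False)
        dm.save_model(net, cfg, tmp_path / "ck.npz")
        again, cfg2 = dm.load_model(tmp_path / "ck.npz")
        np.testing.assert_allclose(again.forward(x, train=False), before)
        assert cfg2.loss == "gdl"
        assert cfg2.patch_size == (8, 16, 16)
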