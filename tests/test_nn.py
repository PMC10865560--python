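import numpy as np
import pytest

import perisinus as ps
from perisinus.nn import (UNet3D, UNetConfig, _loss_and_dlogits, load_model,
                          save_model, softmax)


def _tiny_net(seed=0, in_ch=1, out=2):
    return UNet3D(UNetConfig(in_ch, out, levels=2, base_channels=2, seed=seed))


class TestUNetContracts:
    def test_output_shape_full_patch(self):
        net = UNet3D(UNetConfig(1, 4, levels=3, base_channels=4, seed=0))
        x = np.zeros((1, 64, 96, 64, 1), dtype=np.float32)
        out = net.forward(x)
        assert out.shape == (1, 64, 96, 64, 4)

    def test_same_seed_identical_init(self):
        a = ps.build_unet(UNetConfig(1, 2, 3, 8, seed=5))
        b = ps.build_unet(UNetConfig(1, 2, 3, 8, seed=5))
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_softmax_head_sums_to_one(self, rng):
        net = _tiny_net()
        x = rng.normal(size=(2, 8, 8, 8, 1)).astype(np.float32)
        p = net.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)

    def test_indivisible_shape_rejected(self):
        net = UNet3D(UNetConfig(1, 2, levels=3, base_channels=2, seed=0))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 10, 8, 8, 1), dtype=np.float32))

    def test_gradients_match_finite_differences(self, rng):
        """Hand-derived backprop against central differences (both losses)."""
        net = UNet3D(UNetConfig(2, 3, levels=2, base_channels=2, seed=0))
        x = rng.normal(size=(1, 4, 4, 4, 2)).astype(np.float32)
        t = rng.integers(0, 3, size=(1, 4, 4, 4))
        for kind in ("ce", "gdl"):
            logits = net.forward(x, train=True)
            _, dz = _loss_and_dlogits(logits, t, kind, 2)
            net.backward(dz)
            params = net.params()
            checked = 0
            for pi in range(0, len(params), 7):
                p, g = params[pi]
                flat, gflat = p.reshape(-1), g.reshape(-1)
                j = flat.size // 2
                eps = 1e-2
                old = flat[j]
                flat[j] = old + eps
                v1, _ = _loss_and_dlogits(net.forward(x, train=True), t, kind, 2)
                flat[j] = old - eps
                v2, _ = _loss_and_dlogits(net.forward(x, train=True), t, kind, 2)
                flat[j] = old
                num = (v1 - v2) / (2 * eps)
                denom = abs(num) + abs(gflat[j]) + 1e-4
                assert abs(num - gflat[j]) / denom < 0.05, (kind, pi)
                checked += 1
            assert checked >= 4

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = _tiny_net(seed=3)
        x = rng.normal(size=(1, 8, 8, 8, 1)).astype(np.float32)
        ref = net.predict_proba(x)
        save_model(net, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.predict_proba(x), ref)


class TestLosses:
    def test_ce_perfect_prediction_zero(self):
        t = np.array([0, 1, 2, 3])
        p = np.eye(4)[t]
        assert ps.loss_ce(p, t) == pytest.approx(0.0, abs=1e-6)

    def test_ce_uniform_is_log4(self):
        p = np.full((10, 4), 0.25)
        t = np.zeros(10, dtype=int)
        assert ps.loss_ce(p, t) == pytest.approx(np.log(4), abs=1e-9)

    def test_ce_two_voxel_hand_case(self):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        t = np.array([0, 1])
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert ps.loss_ce(p, t) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1643, abs=5e-5)

    def test_ce_monotone_in_true_class_mass(self):
        t = np.array([0])
        losses = [ps.loss_ce(np.array([[q, 1 - q]]), t)
                  for q in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(losses) < 0)

    def test_gdl_perfect_and_disjoint(self):
        t = np.array([0, 0, 1, 1, 2, 3])
        p = np.eye(4)[t]
        assert ps.loss_gdl(p, t) == pytest.approx(0.0, abs=1e-6)
        worst = np.eye(4)[(t + 1) % 4]
        assert ps.loss_gdl(worst, t) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("power", [1, 2])
    def test_gdl_matches_bruteforce_oracle(self, rng, power):
        """Vectorized GDL equals an explicit-loop evaluation of the formula."""
        for _ in range(10):
            k = 3
            t = rng.integers(0, k, size=20)
            p = rng.dirichlet(np.ones(k), size=20)
            r = np.eye(k)[t]
            num = den = 0.0
            for l in range(k):
                rsum = sum(r[n, l] for n in range(20))
                if rsum == 0:
                    continue
                w = 1.0 / rsum**power
                num += w * sum(r[n, l] * p[n, l] for n in range(20))
                den += w * sum(r[n, l] + p[n, l] for n in range(20))
            expected = 1 - 2 * (num + 1e-6) / (den + 1e-6)
            assert ps.loss_gdl(p, t, weight_power=power) == pytest.approx(
                max(expected, 0.0), abs=1e-9)

    def test_gdl_single_class_reduces_to_soft_dice(self, rng):
        """With one foreground class present, GDL = 1 - soft Dice."""
        t = np.array([1] * 8)
        p = rng.dirichlet(np.ones(2), size=8)
        inter = p[:, 1].sum()
        # soft Dice on the one present class, with the absent class dropped
        expected = 1 - 2 * (inter / 64 + 1e-6) / ((8 + p[:, 1].sum()) / 64 + 1e-6)
        assert ps.loss_gdl(p, t) == pytest.approx(max(expected, 0), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ps.loss_ce(np.ones((3, 2)) / 2, np.zeros(4, dtype=int))


class TestAugmentation:
    def test_flip_is_involution_and_conserves_counts(self, rng):
        img = rng.normal(size=(8, 8, 8))
        lab = rng.integers(0, 4, (8, 8, 8))
        flipped_img, flipped_lab = img, lab
        r = np.random.default_rng(0)
        flips = 0
        for _ in range(8):
            new_img, new_lab = ps.augment_flip(flipped_img, flipped_lab, r)
            if not np.array_equal(new_img, flipped_img):
                flips += 1
            for c in range(4):
                assert (new_lab == c).sum() == (lab == c).sum()
            flipped_img, flipped_lab = new_img, new_lab
        double_i, double_l = ps.augment_flip(img, lab, np.random.default_rng(99))
        redo_i, redo_l = ps.augment_flip(double_i, double_l,
                                         np.random.default_rng(99))
        # same generator state -> same decision -> involution
        np.testing.assert_array_equal(redo_i, img)

    def test_noise_zero_sd_identity_and_bounded_sd(self, rng):
        x = rng.normal(size=(20, 20, 25)).astype(np.float32)
        assert ps.augment_noise(x, 0.0, 1) is x
        sds = []
        for seed in range(30):
            out = ps.augment_noise(x, 0.5, seed)
            sds.append((out - x).std())
        assert max(sds) <= 0.5 * (1 + 4 / np.sqrt(x.size))
        out1 = ps.augment_noise(x, 0.3, 7)
        out2 = ps.augment_noise(x, 0.3, 7)
        np.testing.assert_array_equal(out1, out2)

    def test_clahe_constant_identity_and_range(self, rng):
        const = np.full((8, 16, 16), 2.0)
        np.testing.assert_array_equal(ps.augment_clahe(const), const)
        x = rng.normal(size=(8, 32, 32))
        out = ps.augment_clahe(x)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_clahe_preserves_intensity_ranking(self, rng):
        from scipy.stats import spearmanr
        x = rng.normal(size=(4, 32, 32)) + np.linspace(0, 3, 32)[None, :, None]
        out = ps.augment_clahe(x, clip_limit=0.02, tiles=4)
        # interior tile of one slice
        a = x[1, 8:16, 8:16].ravel()
        b = out[1, 8:16, 8:16].ravel()
        rho, _ = spearmanr(a, b)
        assert rho >= 0.9


class TestTraining:
    def _dataset(self, rng, n=1):
        img = rng.normal(size=(8, 8, 8)).astype(np.float32)
        lab = (img > 0).astype(np.int64)
        return [ps.TrainingSample(image=img, labels=lab) for _ in range(n)]

    def test_overfit_single_patch(self, rng):
        net = _tiny_net()
        cfg = ps.TrainConfig(learning_rate=1e-2, epochs=50, batch_size=1,
                             seed=0, augment_flip=False, augment_noise=False)
        _, hist = ps.train(net, self._dataset(rng), cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_zero_lr_constant_history(self, rng):
        net = _tiny_net()
        cfg = ps.TrainConfig(learning_rate=0.0, epochs=4, batch_size=1, seed=0,
                             augment_flip=False, augment_noise=False)
        _, hist = ps.train(net, self._dataset(rng), cfg)
        losses = [h["train_loss"] for h in hist]
        assert np.allclose(losses, losses[0])

    def test_reproducible_histories(self, rng):
        data = self._dataset(rng, n=3)
        cfg = ps.TrainConfig(learning_rate=1e-3, epochs=3, batch_size=2, seed=4)
        _, h1 = ps.train(_tiny_net(), data, cfg)
        _, h2 = ps.train(_tiny_net(), data, cfg)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ps.train(_tiny_net(), [], ps.TrainConfig())
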