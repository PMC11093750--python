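"""Steering network: initialization, training, prediction, MC dropout, FLOPs."""

import numpy as np
import pytest

from emflight.model import (
    SteeringNetConfig,
    TrainConfig,
    augment_sample,
    build_and_init,
    count_flops,
    mc_predict,
    predict,
    reference_config,
    test_scale_config as small_scale_config,
    train,
)

TINY = SteeringNetConfig(
    input_shape=(16, 16, 8),
    conv_channels=(6, 8),
    conv_strides=((2, 2, 2), (2, 2, 2)),
    fc_widths=(16, 12, 8),
    dropout_rate=0.5,
)

TINY_NODROP = SteeringNetConfig(
    input_shape=(16, 16, 8),
    conv_channels=(6, 8),
    conv_strides=((2, 2, 2), (2, 2, 2)),
    fc_widths=(16, 12, 8),
    dropout_rate=0.0,
)


class TestBuildAndInit:
    def test_same_seed_identical_parameters(self):
        a = build_and_init(TINY, seed=5)
        b = build_and_init(TINY, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.parameters(), b.parameters()))

    def test_different_seed_different_parameters(self):
        a = build_and_init(TINY, seed=5)
        b = build_and_init(TINY, seed=6)
        assert not np.array_equal(a.convs[0].W, b.convs[0].W)

    def test_he_variance_of_wide_hidden_layer(self):
        cfg = SteeringNetConfig(
            input_shape=(16, 16, 8), conv_channels=(6, 8),
            conv_strides=((2, 2, 2), (2, 2, 2)), fc_widths=(256, 64, 32),
        )
        net = build_and_init(cfg, seed=0)
        W = net.fcs[1].W  # 256 -> 64, fan_in 256
        assert W.var() == pytest.approx(2.0 / 256, rel=0.10)

    def test_forward_on_zero_input_finite(self):
        net = build_and_init(TINY, seed=0)
        out = net.forward(np.zeros((2, 16, 16, 8), dtype=np.float32))
        assert np.all(np.isfinite(out))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SteeringNetConfig(conv_channels=(8,), conv_strides=((1, 1, 1), (2, 2, 2)))
        with pytest.raises(ValueError):
            SteeringNetConfig(activation="tanh")


class TestTraining:
    def _toy_data(self, rng, n=160):
        # a bright Gaussian tube-like bump at in-plane offset (a, b); the
        # targets are the offsets plus a radius-like scalar — a miniature of
        # the real centering task, learnable and generalizable
        ii, jj = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        X = np.empty((n, 16, 16, 8), dtype=np.float32)
        Y = np.empty((n, 3), dtype=np.float32)
        for i in range(n):
            a, b = rng.uniform(-4, 4, size=2)
            w = rng.uniform(2.0, 3.5)
            img = np.exp(-((ii - 7.5 - a) ** 2 + (jj - 7.5 - b) ** 2) / (2 * w**2))
            X[i] = img[:, :, None] + rng.normal(0, 0.05, size=(16, 16, 8))
            Y[i] = (a / 2.0, b / 2.0, w)
        return X, Y

    def test_learns_toy_problem(self, rng):
        X, Y = self._toy_data(rng, n=400)
        net = build_and_init(TINY_NODROP, seed=0)
        cfg = TrainConfig(batch_size=32, max_updates=600, learning_rate=1e-3,
                          l2_coeff=0.0, seed=0, augment=False)
        net, hist = train(net, X[:320], Y[:320], cfg)
        scale = np.array([0.5, 0.5, 1.0])
        preds = []
        for x in X[320:]:
            p = predict(net, x)
            preds.append([p.k1 * 0.5, p.k2 * 0.5, p.membrane_distance])
        val_mse = float(((np.asarray(preds) - Y[320:] * scale) ** 2).mean())
        baseline = float(((Y[320:] * scale - (Y[:320] * scale).mean(0)) ** 2).mean())
        assert val_mse < 0.5 * baseline

    def test_overfit_single_batch_loss_decreases(self, rng):
        X, Y = self._toy_data(rng, n=32)
        net = build_and_init(TINY_NODROP, seed=1)
        cfg = TrainConfig(batch_size=32, max_updates=100, learning_rate=1e-3,
                          l2_coeff=0.0, seed=0, augment=False)
        net, hist = train(net, X, Y, cfg)
        losses = np.asarray(hist["loss"])
        increases = int((np.diff(losses) > 0).sum())
        assert losses[-1] < losses[0]
        assert increases <= 10  # optimizer noise allowed, trend down

    def test_nan_loss_aborts(self):
        net = build_and_init(TINY, seed=0)
        X = np.full((8, 16, 16, 8), np.nan, dtype=np.float32)
        Y = np.zeros((8, 3), dtype=np.float32)
        with pytest.raises(FloatingPointError):
            train(net, X, Y, TrainConfig(batch_size=8, max_updates=2, augment=False))

    def test_elu_and_relu_both_trainable(self, rng):
        # the activation comparison harness: both nonlinearities train to
        # finite, decreasing loss on the same data
        X, Y = self._toy_data(rng, n=64)
        finals = {}
        for act in ("elu", "relu"):
            cfg = SteeringNetConfig(
                input_shape=(16, 16, 8), conv_channels=(6, 8),
                conv_strides=((2, 2, 2), (2, 2, 2)), fc_widths=(16, 12, 8),
                dropout_rate=0.0, activation=act,
            )
            net = build_and_init(cfg, seed=0)
            net, hist = train(net, X, Y, TrainConfig(
                batch_size=16, max_updates=120, learning_rate=1e-3,
                l2_coeff=0.0, seed=0, augment=False))
            assert np.isfinite(hist["loss"]).all()
            finals[act] = np.mean(hist["loss"][-10:])
            assert finals[act] < np.mean(hist["loss"][:10])

    def test_rmsprop_momentum_optimizer_runs(self, rng):
        X, Y = self._toy_data(rng, n=64)
        net = build_and_init(TINY, seed=0)
        cfg = TrainConfig(batch_size=16, max_updates=50, optimizer="rmsprop_momentum",
                          learning_rate=1e-4, seed=0, augment=False)
        net, hist = train(net, X, Y, cfg)
        assert np.all(np.isfinite(hist["loss"]))

    def test_deterministic_under_seed(self, rng):
        X, Y = self._toy_data(rng, n=64)
        outs = []
        for _ in range(2):
            net = build_and_init(TINY, seed=3)
            cfg = TrainConfig(batch_size=16, max_updates=30, seed=9)
            net, _ = train(net, X, Y, cfg)
            outs.append(np.concatenate([p.ravel() for p in net.parameters()]))
        assert np.array_equal(outs[0], outs[1])


class TestAugmentation:
    def test_rotation_roundtrip(self, rng):
        patch = rng.normal(size=(16, 16, 8)).astype(np.float32)
        target = np.array([0.7, -0.3, 0.5])
        p, t = patch, target
        for _ in range(4):
            p, t = augment_sample(p, t, 1, False)
        assert np.array_equal(p, patch)
        assert np.allclose(t, target, atol=1e-12)

    def test_flip_involution(self, rng):
        patch = rng.normal(size=(16, 16, 8)).astype(np.float32)
        target = np.array([0.7, -0.3, 0.5])
        p, t = augment_sample(patch, target, 0, True)
        p, t = augment_sample(p, t, 0, True)
        assert np.array_equal(p, patch) and np.allclose(t, target)

    def test_augmentation_matches_frame_rotation(self, tube_scene):
        # quarter-turn patch augmentation equals extracting the patch in the
        # rotated frame with co-rotated curvature target
        from emflight.geometry import rotate_flip_frame
        from emflight.sampling import PatchGeometry, extract_aligned_patch

        neu = tube_scene.neurites[0]
        st = neu.framed.frame_at(2.0)
        geom = PatchGeometry(shape=(16, 16, 8), p=0.6, z_spacing=0.06)
        p0 = extract_aligned_patch(tube_scene.volume, st, geom)
        k = np.array([0.4, -0.2, 0.3])
        p_aug, k_aug = augment_sample(p0.intensities, k, 1, False)
        st90 = rotate_flip_frame(st, np.pi / 2)
        p90 = extract_aligned_patch(tube_scene.volume, st90, geom)
        assert np.allclose(p_aug, p90.intensities, atol=1e-5)
        # target transforms: new k1 = old k2, new k2 = -old k1
        assert k_aug[0] == pytest.approx(-0.2) and k_aug[1] == pytest.approx(-0.4)


class TestPrediction:
    def test_predict_deterministic(self, rng):
        net = build_and_init(TINY, seed=0)
        x = rng.normal(size=(16, 16, 8)).astype(np.float32)
        a = predict(net, x)
        b = predict(net, x)
        assert a.k1 == b.k1 and a.k2 == b.k2

    def test_membrane_distance_clamped_nonnegative(self, rng):
        net = build_and_init(TINY, seed=0)
        for _ in range(10):
            x = rng.normal(size=(16, 16, 8)).astype(np.float32)
            assert predict(net, x).membrane_distance >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        net = build_and_init(TINY, seed=0)
        with pytest.raises(ValueError):
            predict(net, rng.normal(size=(8, 8, 4)).astype(np.float32))


class TestMCDropout:
    def test_zero_rate_all_samples_equal_prediction(self, rng):
        cfg = SteeringNetConfig(
            input_shape=(16, 16, 8), conv_channels=(6, 8),
            conv_strides=((2, 2, 2), (2, 2, 2)), fc_widths=(16, 12, 8),
            dropout_rate=0.0,
        )
        net = build_and_init(cfg, seed=0)
        x = rng.normal(size=(16, 16, 8)).astype(np.float32)
        s = mc_predict(net, x, M=8, seed=0)
        p = predict(net, x)
        assert np.allclose(s.curvature_samples, [[p.k1, p.k2]] * 8, atol=1e-5)

    def test_seed_reproducibility(self, rng):
        net = build_and_init(TINY, seed=0)
        x = rng.normal(size=(16, 16, 8)).astype(np.float32)
        a = mc_predict(net, x, M=16, seed=11)
        b = mc_predict(net, x, M=16, seed=11)
        assert np.array_equal(a.curvature_samples, b.curvature_samples)

    def test_sample_mean_converges_at_root_m(self, rng):
        # Monte-Carlo means approach the true dropout expectation at 1/sqrt(M);
        # the reference expectation is estimated from one very large run
        # (note: weight scaling 'predict' is only an approximation of this
        # expectation because the head is nonlinear)
        net = build_and_init(TINY, seed=2)
        x = rng.normal(size=(16, 16, 8)).astype(np.float32)
        ref = mc_predict(net, x, M=32768, seed=999).curvature_samples.mean(axis=0)
        devs = {}
        for M in (64, 1024):
            reps = []
            for rep in range(10):
                s = mc_predict(net, x, M=M, seed=100 + rep)
                reps.append(np.linalg.norm(s.curvature_samples.mean(axis=0) - ref))
            devs[M] = np.mean(reps)
        ratio = devs[64] / devs[1024]
        assert 2.0 < ratio < 6.0  # expect ~4 = sqrt(1024/64)

    def test_m_below_two_rejected(self, rng):
        net = build_and_init(TINY, seed=0)
        with pytest.raises(ValueError):
            mc_predict(net, rng.normal(size=(16, 16, 8)).astype(np.float32), M=1)


class TestCountFlops:
    def test_single_sample_zero_overhead(self):
        _, _, ov = count_flops(reference_config(), M=1)
        assert ov == 0.0

    def test_overhead_linear_in_extra_samples(self):
        cfg = reference_config()
        _, _, ov128 = count_flops(cfg, M=128)
        _, _, ov256 = count_flops(cfg, M=256)
        expected = ov128 * (256 - 1) / (128 - 1)
        assert ov256 == pytest.approx(expected, rel=1e-9)

    def test_reference_architecture_overhead_below_two_percent(self):
        # the architectural constraint: a single post-conv dropout layer keeps
        # 128-sample MC inference within 2% extra FLOPs
        _, _, ov = count_flops(reference_config(), M=128)
        assert ov < 0.02

    def test_conv_flop_formula(self):
        cfg = SteeringNetConfig(
            input_shape=(8, 8, 4), conv_channels=(4,), conv_strides=((2, 2, 2),),
            fc_widths=(4, 4, 4),
        )
        single, _, _ = count_flops(cfg, M=1)
        conv = 4 * 4 * 2 * 4 * 1 * 27 * 2  # out_voxels x c_out x c_in x k^3 x 2
        head = (4 * 4 * 2 * 4) * 4 * 2 + 4 * 4 * 2 + 4 * 4 * 2 + 4 * 3 * 2
        assert single == conv + head
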