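"""Autoencoder: Dice objective, architecture geometry, training dynamics,
dual-output consistency, and latent filtering."""

import numpy as np
import pytest

from dualrad import (ModelConfig, TrainConfig, binarize, build_model,
                     dice_coefficient, filter_latent, latent_matrix,
                     load_model, model_summary, predict, save_model, train)
from dualrad.autoencoder import AutoencoderError, _batch_dice_loss_grad
from dualrad.phantom import PhantomConfig, generate_cohort


def brute_force_dice(p, g):
    """Independent elementwise-summation oracle for the squared-denominator
    Dice coefficient."""
    num = den = 0.0
    for pi, gi in zip(np.ravel(p), np.ravel(g)):
        num += 2.0 * pi * gi
        den += pi * pi + gi * gi
    return 1.0 if den == 0 else num / den


class TestDiceCoefficient:
    def test_matches_brute_force_on_randomized_masks(self, rng):
        for _ in range(25):
            shape = (rng.integers(2, 9), rng.integers(2, 9))
            p = rng.uniform(0, 1, shape)
            g = (rng.uniform(0, 1, shape) > 0.5).astype(float)
            assert dice_coefficient(p, g) == pytest.approx(
                brute_force_dice(p, g), abs=1e-12)

    def test_identity_and_disjoint_cases(self):
        m = np.array([[1, 0], [1, 1]], dtype=float)
        assert dice_coefficient(m, m) == 1.0
        assert dice_coefficient(1.0 - m, m) == 0.0

    def test_hand_computed_value(self):
        # 2*0.5 / (0.25 + 0.25 + 1)
        assert dice_coefficient([0.5, 0.5], [1, 0]) == pytest.approx(2 / 3, abs=1e-9)

    def test_empty_vs_empty_is_perfect_agreement(self):
        z = np.zeros((4, 4))
        assert dice_coefficient(z, z) == 1.0

    def test_symmetry_for_binary_inputs(self, rng):
        a = (rng.uniform(0, 1, 20) > 0.4).astype(float)
        b = (rng.uniform(0, 1, 20) > 0.6).astype(float)
        if not (a.any() or b.any()):
            a[0] = 1.0
        assert dice_coefficient(a, b) == pytest.approx(dice_coefficient(b, a))

    def test_range_and_errors(self, rng):
        p = rng.uniform(0, 1, (5, 5))
        g = (rng.uniform(0, 1, (5, 5)) > 0.5).astype(float)
        assert 0.0 <= dice_coefficient(p, g) <= 1.0
        with pytest.raises(AutoencoderError, match="shape"):
            dice_coefficient(np.zeros(3), np.zeros(4))
        with pytest.raises(AutoencoderError, match="binary"):
            dice_coefficient(np.zeros(3), np.array([0.0, 0.5, 1.0]))


class TestArchitecture:
    def test_desk_forward_shapes(self, desk_model):
        out = predict(desk_model, np.zeros((64, 64), dtype=np.float32))
        assert out.prob_map.shape == (64, 64)
        assert np.all((out.prob_map >= 0) & (out.prob_map <= 1))
        assert out.latent.shape == (16,)

    def test_latent_dim_passthrough(self):
        cfg = ModelConfig(input_size=32, n_blocks=3, base_filters=4,
                          dense_hidden=16, latent_dim=1)
        m = build_model(cfg, seed=0)
        assert predict(m, np.zeros((32, 32))).latent.shape == (1,)

    def test_paper_preset_flatten_is_262144(self):
        summary = model_summary(ModelConfig.paper())
        assert summary["flatten_features"] == 262_144
        assert summary["latent_dim"] == 16
        # soft check: same order of magnitude as a ~1.9e8-parameter network
        assert 5e7 < summary["n_params"] < 5e8

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(AutoencoderError, match="divisible"):
            ModelConfig(input_size=100, n_blocks=5)

    def test_shape_mismatch_rejected(self, desk_model):
        with pytest.raises(AutoencoderError, match="does not match"):
            predict(desk_model, np.zeros((32, 32)))

    def test_dual_output_latent_equals_encoder_alone(self, desk_model, rng):
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        out = predict(desk_model, img)
        enc = desk_model.encode(img[None, :, :, None])[0]
        assert np.array_equal(out.latent, enc.astype(np.float64))


class TestGradients:
    """Finite-difference checks of each layer's backward pass.

    Layers are checked in isolation against the scalar loss sum(y * R) with a
    fixed random R, at inputs away from the non-smooth points of max-pooling
    and ReLU.
    """

    @staticmethod
    def _check_layer(layer, x, eps=1e-5, tol=1e-4, check_params=True):
        rng = np.random.default_rng(99)
        y = layer.forward(x, train=True)
        R = rng.standard_normal(y.shape)
        dx = layer.backward(R.astype(np.float64))

        def loss(xv):
            return float((layer.forward(xv, train=True) * R).sum())

        flat = x.reshape(-1)
        for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss(x)
            flat[idx] = orig - eps
            down = loss(x)
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            scale = max(1.0, abs(numeric))
            assert abs(dx.reshape(-1)[idx] - numeric) / scale < tol
        if not check_params:
            return
        layer.forward(x, train=True)
        layer.backward(R.astype(np.float64))
        for p, grad in zip(layer.params, layer.grads):
            pf = p.reshape(-1)
            gf = np.array(grad, dtype=np.float64).reshape(-1)
            for idx in rng.choice(pf.size, size=min(4, pf.size), replace=False):
                orig = pf[idx]
                pf[idx] = orig + 1e-3
                up = loss(x)
                pf[idx] = orig - 1e-3
                down = loss(x)
                pf[idx] = orig
                numeric = (up - down) / 2e-3
                scale = max(1.0, abs(numeric))
                assert abs(gf[idx] - numeric) / scale < 1e-2

    def test_conv2d_backward(self, rng):
        from dualrad._nn import Conv2D

        layer = Conv2D(2, 3, 3, rng)
        self._check_layer(layer, rng.standard_normal((2, 6, 6, 2)))

    def test_dense_backward(self, rng):
        from dualrad._nn import Dense

        self._check_layer(Dense(7, 4, rng), rng.standard_normal((3, 7)))

    def test_batchnorm_backward(self, rng):
        from dualrad._nn import BatchNorm2D

        layer = BatchNorm2D(3)
        layer.params[0][...] = rng.uniform(0.5, 1.5, 3)  # nontrivial gamma
        self._check_layer(layer, rng.standard_normal((4, 5, 5, 3)), tol=1e-3)

    def test_maxpool_backward(self, rng):
        from dualrad._nn import MaxPool2

        # well-separated values so no argmax switch under perturbation
        x = rng.permuted(np.arange(2 * 8 * 8 * 2, dtype=np.float64)).reshape(2, 8, 8, 2)
        self._check_layer(MaxPool2(), x, check_params=False)

    def test_upsample_and_activations_backward(self, rng):
        from dualrad._nn import ReLU, Sigmoid, Upsample2

        self._check_layer(Upsample2(), rng.standard_normal((2, 4, 4, 3)),
                          check_params=False)
        x = rng.standard_normal((3, 10))
        x = np.sign(x) * (np.abs(x) + 0.2)  # away from the kink at zero
        self._check_layer(ReLU(), x, check_params=False)
        self._check_layer(Sigmoid(), rng.standard_normal((3, 10)),
                          check_params=False)

    def test_batch_dice_loss_grad_matches_finite_differences(self, rng):
        p = rng.uniform(0.05, 0.95, (2, 4, 4, 1))
        g = (rng.uniform(0, 1, (2, 4, 4, 1)) > 0.5).astype(np.float64)
        _, grad = _batch_dice_loss_grad(p, g)
        eps = 1e-6
        for idx in rng.choice(p.size, size=6, replace=False):
            pf = p.reshape(-1)
            orig = pf[idx]
            pf[idx] = orig + eps
            up = _batch_dice_loss_grad(p, g)[0]
            pf[idx] = orig - eps
            down = _batch_dice_loss_grad(p, g)[0]
            pf[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grad.reshape(-1)[idx] == pytest.approx(numeric, abs=1e-5)


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = PhantomConfig.easy_segmentation(4, 4, seed=21)
    return generate_cohort(cfg)[0]


class TestTraining:
    def test_single_sample_single_epoch(self, tiny_cohort):
        m = build_model(ModelConfig.desk(), seed=0)
        m, hist = train(m, tiny_cohort[:1], tcfg=TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1
        assert np.isfinite(hist["train_dice"].iloc[0])

    def test_seed_reproducibility_of_first_epoch(self, tiny_cohort):
        losses = []
        for _ in range(2):
            m = build_model(ModelConfig.desk(), seed=3)
            _, hist = train(m, tiny_cohort, tcfg=TrainConfig(epochs=1, seed=3))
            losses.append(hist["train_dice"].iloc[0])
        assert losses[0] == losses[1]

    def test_optimizer_steps_reduce_loss(self, tiny_cohort):
        """~50 optimizer steps on a fixed batch lower the Dice loss."""
        for attempt_seed in range(3):  # stochastic-tolerant
            m = build_model(ModelConfig.desk(), seed=attempt_seed)
            _, hist = train(m, tiny_cohort,
                            tcfg=TrainConfig(epochs=50, batch_size=8,
                                             lr_start=1e-3, lr_end=1e-4,
                                             seed=attempt_seed))
            if hist["train_dice"].iloc[-1] > hist["train_dice"].iloc[0]:
                return
        pytest.fail("loss failed to decrease under three seeds")

    def test_empty_training_set_rejected(self):
        m = build_model(ModelConfig.desk(), seed=0)
        with pytest.raises(AutoencoderError, match="training samples"):
            train(m, [], tcfg=TrainConfig(epochs=1))

    def test_normal_samples_excluded_by_default(self):
        cfg = PhantomConfig(image_size=64, n_benign=0, n_malignant=0,
                            n_normal=3, seed=0)
        normals = generate_cohort(cfg)[0]
        m = build_model(ModelConfig.desk(), seed=0)
        with pytest.raises(AutoencoderError, match="training samples"):
            train(m, normals, tcfg=TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, tiny_cohort, tmp_path):
        m = build_model(ModelConfig.desk(), seed=0)
        m, _ = train(m, tiny_cohort, tcfg=TrainConfig(epochs=1, seed=0))
        path = str(tmp_path / "model.npz")
        save_model(m, path)
        m2 = load_model(path)
        img = tiny_cohort[0].image
        a, b = predict(m, img), predict(m2, img)
        assert np.array_equal(a.prob_map, b.prob_map)
        assert np.array_equal(a.latent, b.latent)


class TestBinarize:
    def test_threshold_behavior(self):
        prob = np.full((4, 4), 0.4)
        assert binarize(prob, 0.5).sum() == 0
        assert binarize(prob, 0.4).sum() == 16


class TestFilterLatent:
    def test_zero_columns_dropped_varying_kept(self, rng):
        L = np.zeros((10, 16))
        varying = [2, 5, 9, 14]
        L[:, varying] = rng.standard_normal((10, 4))
        sel, reduced = filter_latent(L, k=4)
        assert list(sel) == varying
        assert reduced.shape == (10, 4)

    def test_output_width_is_k(self, desk_model, small_cohort):
        _, samples, _ = small_cohort
        L = latent_matrix(desk_model, samples[:10])
        assert L.shape == (10, 16)
        sel, reduced = filter_latent(L, k=4)
        assert reduced.shape[1] == 4

    def test_variance_ranking_matches_exhaustive_oracle(self, rng):
        L = rng.standard_normal((30, 16)) * rng.uniform(0.1, 3.0, 16)
        sel, _ = filter_latent(L, k=4)
        oracle = np.sort(np.argsort(-L.var(axis=0), kind="stable")[:4])
        assert np.array_equal(sel, oracle)

    def test_tie_broken_toward_lower_index(self):
        L = np.zeros((4, 6))
        L[:, 0] = [0, 1, 2, 3]      # high variance
        L[:, 1] = [0, 2, 4, 6]      # higher variance
        L[:, 3] = [0, 1, 0, 1]      # tied with column 4
        L[:, 4] = [1, 0, 1, 0]      # tied with column 3
        L[:, 5] = [0, 0.5, 1, 1.5]  # mid variance
        sel, _ = filter_latent(L, k=4)
        assert 3 in sel and 4 not in sel

    def test_too_few_nonzero_columns_warns_and_keeps_all(self):
        L = np.zeros((5, 16))
        L[:, 7] = np.arange(5)
        with pytest.warns(UserWarning, match="nonzero latent columns"):
            sel, reduced = filter_latent(L, k=4)
        assert list(sel) == [7]
        assert reduced.shape == (5, 1)
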