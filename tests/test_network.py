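"""Unit tests for the layered classifier: structure, training, truncation."""

import numpy as np
import pytest

from replaysim import network
from replaysim.network import (ArchitectureSpec, Dense, OptimizerConfig,
                               activations_at, build_model, count_parameters,
                               evaluate_arrays, train_epoch, truncate_at,
                               weight_fingerprint)


def _random_images(rng, n, side=16):
    return rng.random((n, side, side, 3)).astype(np.float32)


class TestArchitecture:
    def test_build_is_deterministic(self, tiny_spec):
        a = build_model(tiny_spec, init_seed=1)
        b = build_model(tiny_spec, init_seed=1)
        assert weight_fingerprint(a.layers) == weight_fingerprint(b.layers)
        c = build_model(tiny_spec, init_seed=2)
        assert weight_fingerprint(a.layers) != weight_fingerprint(c.layers)

    def test_forward_is_probability_vector(self, tiny_model, rng):
        p = tiny_model.forward(_random_images(rng, 5))
        assert p.shape == (5, 3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_mini_preset_has_five_cut_points(self):
        m = build_model(ArchitectureSpec.mini(), init_seed=0)
        assert sorted(m.cut_points) == [f"pool_{i}" for i in range(1, 6)]

    def test_pretrained_base_is_copied_and_head_fresh(self, tiny_spec):
        base = build_model(tiny_spec, init_seed=1)
        m = build_model(tiny_spec, init_seed=9, pretrained_base=base)
        for ls, ld in zip(base.conv_layers(), m.conv_layers()):
            for k in ls.params:
                assert np.array_equal(ls.params[k], ld.params[k])
        # head dense weights must differ from an init_seed=1 build
        same_seed = build_model(tiny_spec, init_seed=1)
        head_a = [l for l in m.head_layers() if l.params]
        head_b = [l for l in same_seed.head_layers() if l.params]
        assert any(not np.array_equal(a.params["W"], b.params["W"])
                   for a, b in zip(head_a, head_b))

    def test_pretrained_base_shape_mismatch_raises(self, tiny_spec):
        other = ArchitectureSpec(input_shape=(16, 16, 3), blocks=((1, 6), (1, 8)),
                                 head=(16,), n_outputs=3)
        base = build_model(other, init_seed=0)
        with pytest.raises(ValueError):
            build_model(tiny_spec, init_seed=0, pretrained_base=base)

    def test_invalid_specs_rejected(self):
        # five pooling stages cannot fit a 16-pixel side
        with pytest.raises(ValueError):
            ArchitectureSpec(input_shape=(16, 16, 3), blocks=((1, 4),) * 5,
                             head=(8,), n_outputs=3).validate()
        with pytest.raises(ValueError):
            ArchitectureSpec(n_outputs=0).validate()


class TestParameterCounting:
    def test_vgg16_preset_exact_count(self):
        # closed-form count from the architecture description alone
        assert count_parameters(ArchitectureSpec.vgg16(1000)) == 138_357_544

    def test_lone_dense_layer(self, rng):
        layer = Dense(10, 1, rng, relu=False)
        assert layer.n_params() == 11

    def test_mini_preset_matches_per_layer_arithmetic(self):
        spec = ArchitectureSpec.mini(n_outputs=10)
        model = build_model(spec, init_seed=0)
        # independent oracle: explicit per-layer sums
        expected = 0
        c_in = 3
        for n_conv, n_filt in spec.blocks:
            for _ in range(n_conv):
                expected += 3 * 3 * c_in * n_filt + n_filt
                c_in = n_filt
        n_in = (64 // 32) * (64 // 32) * c_in
        for width in (128, 128, 10):
            expected += n_in * width + width
            n_in = width
        assert count_parameters(model) == expected


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_model, rng):
        X = _random_images(rng, 10)
        y = rng.integers(0, 3, 10)
        before = weight_fingerprint(tiny_model.layers)
        train_epoch(tiny_model, X, y, OptimizerConfig(learning_rate=0.0), rng)
        assert weight_fingerprint(tiny_model.layers) == before

    def test_loss_decreases_on_separable_toy(self, tiny_spec, rng):
        model = build_model(tiny_spec, init_seed=4)
        # two trivially separable classes: dark vs bright images
        X = np.concatenate([np.full((12, 16, 16, 3), 0.1, dtype=np.float32),
                            np.full((12, 16, 16, 3), 0.9, dtype=np.float32)])
        X += rng.normal(0, 0.02, X.shape).astype(np.float32)
        y = np.array([0] * 12 + [1] * 12)
        opt = OptimizerConfig(learning_rate=1e-3, batch_size=8)
        losses = [train_epoch(model, X, y, opt, rng) for _ in range(5)]
        assert losses[-1] < losses[0]

    def test_batching_keeps_final_partial_batch(self, tiny_model, rng):
        X = _random_images(rng, 234)
        y = rng.integers(0, 3, 234)
        train_epoch(tiny_model, X, y, OptimizerConfig(batch_size=36), rng)
        assert len(tiny_model.last_batch_losses) == 7  # 6 x 36 + 1 x 18

    def test_empty_split_raises(self, tiny_model, rng):
        with pytest.raises(ValueError):
            train_epoch(tiny_model, np.empty((0, 16, 16, 3)), np.empty(0, int),
                        OptimizerConfig(), rng)

    def test_dropout_active_only_in_training(self, tiny_model, rng):
        X = _random_images(rng, 4)
        p1 = tiny_model.forward(X, train=True, rng=np.random.default_rng(0))
        p2 = tiny_model.forward(X, train=True, rng=np.random.default_rng(99))
        assert not np.allclose(p1, p2)
        assert np.array_equal(tiny_model.forward(X), tiny_model.forward(X))

    def test_gradients_match_numerical_differentiation(self, rng):
        spec = ArchitectureSpec(input_shape=(16, 16, 3), blocks=((1, 4), (1, 4)),
                                head=(8,), n_outputs=3, dropout_rate=0.0)
        model = build_model(spec, init_seed=0)
        X = _random_images(rng, 3)
        y = np.array([0, 1, 2])

        def loss():
            p = model.forward(X)
            return -np.mean(np.log(p[np.arange(3), y]))

        probs = model.forward(X, train=True, rng=rng)
        d = probs.copy()
        d[np.arange(3), y] -= 1
        model.backward((d / 3).astype(np.float32))
        eps = 1e-3
        for layer in [model.layers[0], model.layers[-1]]:
            W = layer.params["W"]
            flat_idx = rng.choice(W.size, size=3, replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, W.shape)
                orig = W[idx]
                W[idx] = orig + eps
                lp = loss()
                W[idx] = orig - eps
                lm = loss()
                W[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = layer.grads["W"][idx]
                assert abs(num - ana) < 2e-3 + 0.05 * abs(num)


class TestEvaluation:
    def test_report_matches_brute_force_recount(self, small_model, small_dataset):
        report = network.evaluate(small_model, small_dataset, split="test")
        correct = (report.predictions == report.labels)
        assert report.overall_accuracy == pytest.approx(correct.mean())
        for c in range(3):
            mask = report.labels == c
            assert report.per_class_total[c] == mask.sum()
            assert report.per_class_correct[c] == correct[mask].sum()
            assert report.per_class_accuracy[c] == pytest.approx(
                correct[mask].mean())

    def test_untrained_model_starts_at_chance(self):
        spec = ArchitectureSpec.mini(n_outputs=10, input_shape=(32, 32, 3))
        model = build_model(spec, init_seed=11)
        rng = np.random.default_rng(5)
        X = rng.random((200, 32, 32, 3)).astype(np.float32)
        y = np.repeat(np.arange(10), 20)
        report = evaluate_arrays(model, X, y)
        # 99% binomial band around chance (p = 0.1, n = 200)
        half = 2.576 * np.sqrt(0.1 * 0.9 / 200)
        assert abs(report.overall_accuracy - 0.1) < half + 1e-9


class TestCutPoints:
    def test_activations_are_nonnegative(self, small_model, small_dataset, rng):
        X, _ = small_dataset.arrays("test")
        for cp in small_model.spec.cut_point_names():
            acts = activations_at(small_model, cp, X[:4])
            assert (acts >= 0).all()

    def test_zero_input_gives_zero_activations(self, tiny_model):
        X = np.zeros((2, 16, 16, 3), dtype=np.float32)
        acts = activations_at(tiny_model, "pool_1", X)
        assert np.all(acts == 0)  # biases start at zero, ReLU(0) = 0

    def test_unknown_cut_point_raises(self, tiny_model, rng):
        with pytest.raises(ValueError):
            activations_at(tiny_model, "pool_9", _random_images(rng, 1))
        with pytest.raises(ValueError):
            truncate_at(tiny_model, "dense_1")

    def test_truncation_reproduces_full_forward_at_every_cut(self, small_model, rng):
        X = rng.random((5, 32, 32, 3)).astype(np.float32)
        full = small_model.forward(X)
        for cp in small_model.spec.cut_point_names():
            acts = activations_at(small_model, cp, X)
            head = truncate_at(small_model, cp)
            assert np.allclose(head.forward(acts), full, atol=1e-5)

    def test_head_training_freezes_upstream_and_updates_parent(self, small_model, rng):
        cp = "pool_3"
        cut = small_model.cut_index(cp)
        acts = rng.random((20, *small_model.cut_shape(cp))).astype(np.float32)
        y = rng.integers(0, 3, 20)
        before_up = weight_fingerprint(small_model.layers[:cut + 1])
        before_down = weight_fingerprint(small_model.layers[cut + 1:])
        head = truncate_at(small_model, cp)
        head.train_epoch(acts, y, OptimizerConfig(learning_rate=1e-3, batch_size=10), rng)
        assert weight_fingerprint(small_model.layers[:cut + 1]) == before_up
        assert weight_fingerprint(small_model.layers[cut + 1:]) != before_down

    def test_head_rejects_wrong_input_shape(self, small_model, rng):
        head = truncate_at(small_model, "pool_4")
        with pytest.raises(ValueError):
            head.forward(rng.random((2, 3, 3, 8)))
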