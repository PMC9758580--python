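"""Unit tests for activation resampling, Gaussian fitting, and night replay."""

import numpy as np
import pytest
from scipy import stats

from replaysim import network, replay
from replaysim.network import OptimizerConfig, weight_fingerprint
from replaysim.replay import (ActivationDistribution, ReplayBatch, ReplayConfig,
                              capture_veridical, downsample_activations,
                              fit_class_distribution, replay_night,
                              sample_distribution, upsample_activations)


def _brute_force_block_mean(act, factor):
    h, w, c = act.shape
    oh, ow = h // factor, w // factor
    out = np.zeros((oh, ow, c))
    for i in range(oh):
        for j in range(ow):
            for k in range(c):
                out[i, j, k] = act[i * factor:(i + 1) * factor,
                                   j * factor:(j + 1) * factor, k].mean()
    return out


class TestResampling:
    def test_constant_map_is_preserved(self):
        act = np.full((8, 8, 2), 3.25)
        for f in (1, 2, 4, 8):
            assert np.allclose(downsample_activations(act, f), 3.25)

    def test_known_4x4_block_average(self):
        act = np.arange(1.0, 17.0).reshape(4, 4, 1)
        out = downsample_activations(act, 2)
        assert np.array_equal(out[:, :, 0], [[3.5, 5.5], [11.5, 13.5]])

    @pytest.mark.parametrize("shape,factor", [((8, 8, 3), 2), ((12, 12, 2), 4),
                                              ((6, 6, 1), 3)])
    def test_matches_brute_force_oracle(self, rng, shape, factor):
        act = rng.random(shape)
        assert np.allclose(downsample_activations(act, factor),
                           _brute_force_block_mean(act, factor))

    def test_shape_contract_factor_8(self, rng):
        act = rng.random((32, 32, 8))
        assert downsample_activations(act, 8).shape == (4, 4, 8)

    def test_factor_larger_than_side_raises(self, rng):
        with pytest.raises(ValueError):
            downsample_activations(rng.random((4, 4, 1)), 5)

    def test_nondividing_factor_uses_edge_padding(self, rng):
        act = rng.random((14, 14, 2))
        out = downsample_activations(act, 7)
        assert out.shape == (2, 2, 2)
        act2 = rng.random((5, 5, 1))
        out2 = downsample_activations(act2, 2)  # padded to 6x6
        assert out2.shape == (3, 3, 1)

    def test_upsample_factor_1_is_identity(self, rng):
        act = rng.random((4, 4, 2))
        assert np.array_equal(upsample_activations(act, 1), act)

    def test_down_up_round_trip_is_identity(self, rng):
        act = rng.random((4, 4, 3))
        up = upsample_activations(act, 8)
        assert up.shape == (32, 32, 3)
        # block means of constant blocks recover the input (to rounding ulps)
        assert np.allclose(downsample_activations(up, 8), act, rtol=1e-14, atol=0)
        # constant 8x8 blocks by construction
        assert np.all(up[:8, :8, 0] == up[0, 0, 0])

    def test_upsample_crops_to_target_shape(self, rng):
        act = rng.random((2, 2, 1))
        out = upsample_activations(act, 7, target_shape=(13, 13))
        assert out.shape == (13, 13, 1)


class TestDistributionFit:
    def test_identical_arrays_give_zero_variance_plus_jitter(self):
        arr = np.arange(12.0).reshape(2, 2, 3) + 1.0
        acts = np.stack([arr] * 6)
        cfg = ReplayConfig(covariance_jitter=1e-6)
        dist = fit_class_distribution(acts, 0, "pool_5", cfg)
        assert np.allclose(dist.mean, arr.ravel())
        assert dist.n_fit == 6
        off_diag = dist.covariance - np.diag(np.diag(dist.covariance))
        assert np.allclose(off_diag, 0.0)
        assert np.all(np.diag(dist.covariance) > 0)

    def test_recovers_known_diagonal_gaussian(self):
        rng = np.random.default_rng(77)
        true_mean = np.array([1.0, -2.0, 0.5, 3.0])
        true_var = np.array([0.5, 1.0, 2.0, 0.25])
        draws = true_mean + rng.standard_normal((2000, 4)) * np.sqrt(true_var)
        acts = draws.reshape(2000, 2, 2, 1)
        dist = fit_class_distribution(acts, 0, "pool_5", ReplayConfig())
        assert np.all(np.abs(dist.mean - true_mean) < 0.1)
        assert np.all(np.abs(np.diag(dist.covariance) / true_var - 1) < 0.15)

    def test_single_distribution_per_class(self, small_model, small_dataset):
        dists = replay.fit_all_classes(small_model, "pool_4", small_dataset,
                                       ReplayConfig())
        assert sorted(dists) == [0, 1, 2]
        assert all(d.class_id == c for c, d in dists.items())
        n_per_class = (small_dataset.labels["train"] == 0).sum()
        assert all(d.n_fit == n_per_class for d in dists.values())

    def test_fewer_than_two_samples_raises(self, rng):
        with pytest.raises(ValueError):
            fit_class_distribution(rng.random((1, 2, 2, 1)), 0, "pool_5")

    def test_downsample_factor_recorded_from_config(self, rng):
        acts = rng.random((10, 8, 8, 2))
        dist = fit_class_distribution(acts, 3, "pool_2", ReplayConfig())
        assert dist.downsample_factor == 4
        assert dist.spatial_shape == (2, 2, 2)
        assert dist.dim == 8
        assert dist.orig_spatial_shape == (8, 8, 2)


class TestSampling:
    def test_degenerate_distribution_returns_mean(self):
        mean = np.arange(4.0)
        dist = ActivationDistribution(
            class_id=1, cut_point="pool_5", mean=mean,
            covariance=np.eye(4) * 1e-18, spatial_shape=(2, 2, 1),
            orig_spatial_shape=(2, 2, 1), downsample_factor=1, n_fit=10)
        batch = sample_distribution(dist, 5, np.random.default_rng(0))
        assert batch.provenance == "generative"
        assert np.allclose(batch.arrays.reshape(5, 4), mean, atol=1e-6)
        assert np.all(batch.labels == 1)

    def test_moments_match_parameters_within_monte_carlo_error(self, rng):
        acts = rng.random((200, 2, 2, 1))
        dist = fit_class_distribution(acts, 0, "pool_5", ReplayConfig())
        n = 10_000
        batch = sample_distribution(dist, n, np.random.default_rng(3))
        flat = batch.arrays.reshape(n, 4).astype(np.float64)
        se_mean = np.sqrt(np.diag(dist.covariance) / n)
        assert np.all(np.abs(flat.mean(axis=0) - dist.mean) < 3 * se_mean)
        emp_cov = np.cov(flat, rowvar=False)
        assert np.all(np.abs(np.diag(emp_cov) / np.diag(dist.covariance) - 1) < 0.2)

    def test_sampler_agrees_with_scipy_reference(self, rng):
        # independent cross-check: same fitted Gaussian, scipy's sampler
        acts = rng.random((150, 2, 2, 1))
        dist = fit_class_distribution(acts, 0, "pool_5", ReplayConfig())
        mine = sample_distribution(dist, 4000, np.random.default_rng(8))
        ref = stats.multivariate_normal(dist.mean, dist.covariance,
                                        allow_singular=True, seed=9).rvs(4000)
        mine_flat = mine.arrays.reshape(4000, 4).astype(np.float64)
        assert np.allclose(mine_flat.mean(axis=0), ref.mean(axis=0), atol=0.05)
        assert np.allclose(np.cov(mine_flat, rowvar=False), np.cov(ref, rowvar=False),
                           atol=0.05)

    def test_round_trip_fit_sample_refit(self, rng):
        """fit -> sample -> refit recovers moments (3 s.e. / 20% on variances)."""
        acts = rng.random((300, 2, 2, 2)) * np.arange(1, 9).reshape(2, 2, 2)
        dist = fit_class_distribution(acts, 0, "pool_5", ReplayConfig())
        n = 5000
        batch = sample_distribution(dist, n, np.random.default_rng(21))
        refit = fit_class_distribution(batch.arrays, 0, "pool_5", ReplayConfig())
        se_mean = np.sqrt(np.diag(dist.covariance) / n)
        assert np.all(np.abs(refit.mean - dist.mean) < 3 * se_mean)
        assert np.all(np.abs(np.diag(refit.covariance) /
                             np.diag(dist.covariance) - 1) < 0.2)

    def test_upsampled_sample_has_cut_layer_shape(self, rng):
        acts = rng.random((20, 8, 8, 3))
        dist = fit_class_distribution(acts, 2, "pool_2", ReplayConfig())
        batch = sample_distribution(dist, 7, rng)
        assert batch.arrays.shape == (7, 8, 8, 3)

    def test_nonnegative_clipping_flag(self, rng):
        acts = rng.standard_normal((50, 2, 2, 1))
        dist = fit_class_distribution(acts, 0, "pool_5", ReplayConfig())
        clipped = sample_distribution(dist, 200, np.random.default_rng(0),
                                      clip_nonnegative=True)
        assert clipped.arrays.min() >= 0.0


class TestVeridicalAndNight:
    def test_veridical_batch_equals_activations(self, small_model, small_dataset):
        batch = capture_veridical(small_model, "pool_4", small_dataset)
        X, y = small_dataset.arrays("train")
        acts = network.activations_at(small_model, "pool_4", X,
                                      channel_means=small_dataset.channel_means)
        assert batch.provenance == "veridical"
        assert len(batch.arrays) == len(X)
        assert np.array_equal(batch.arrays, acts)
        assert np.array_equal(batch.labels, y)

    def test_head_on_veridical_batch_reproduces_full_forward(self, small_model,
                                                             small_dataset):
        batch = capture_veridical(small_model, "pool_3", small_dataset)
        head = network.truncate_at(small_model, "pool_3")
        X, _ = small_dataset.arrays("train")
        xb = X - small_dataset.channel_means
        full = small_model.forward(xb)
        assert np.allclose(head.forward(batch.arrays), full, atol=1e-5)

    def test_zero_lr_night_changes_nothing(self, small_model, small_dataset, rng):
        batch = capture_veridical(small_model, "pool_4", small_dataset)
        before = weight_fingerprint(small_model.layers)
        replay_night(small_model, "pool_4", batch,
                     OptimizerConfig(learning_rate=0.0), rng)
        assert weight_fingerprint(small_model.layers) == before

    def test_night_never_touches_upstream_weights(self, small_model, small_dataset, rng):
        for cp in ("pool_1", "pool_4"):
            cut = small_model.cut_index(cp)
            batch = capture_veridical(small_model, cp, small_dataset)
            before_up = weight_fingerprint(small_model.layers[:cut + 1])
            replay_night(small_model, cp, batch,
                         OptimizerConfig(learning_rate=1e-3), rng)
            assert weight_fingerprint(small_model.layers[:cut + 1]) == before_up

    def test_night_reduces_loss_on_separable_batches(self, rng):
        spec = network.ArchitectureSpec(input_shape=(16, 16, 3),
                                        blocks=((1, 4), (1, 8)), head=(16,),
                                        n_outputs=2, dropout_rate=0.0)
        model = network.build_model(spec, init_seed=5)
        shape = model.cut_shape("pool_2")
        a0 = np.zeros((30, *shape), dtype=np.float32)
        a1 = np.full((30, *shape), 2.0, dtype=np.float32)
        batches = [ReplayBatch(a0, np.zeros(30, int), "generative"),
                   ReplayBatch(a1, np.ones(30, int), "generative")]
        opt = OptimizerConfig(learning_rate=1e-3, batch_size=12)
        first = replay_night(model, "pool_2", batches, opt, rng)
        last = first
        for _ in range(4):
            last = replay_night(model, "pool_2", batches, opt, rng)
        assert last < first

    def test_shape_mismatch_raises(self, small_model, rng):
        bad = ReplayBatch(rng.random((4, 3, 3, 7)).astype(np.float32),
                          np.zeros(4, int), "generative")
        with pytest.raises(ValueError):
            replay_night(small_model, "pool_4", bad, OptimizerConfig(), rng)


class TestSerialization:
    def test_distribution_store_round_trips_bit_exactly(self, rng, tmp_path):
        acts = {c: rng.random((12, 8, 8, 2)) for c in (0, 1, 2)}
        dists = {c: fit_class_distribution(a, c, "pool_2", ReplayConfig())
                 for c, a in acts.items()}
        path = tmp_path / "dists.npz"
        replay.save_distributions(dists, path)
        loaded = replay.load_distributions(path)
        assert sorted(loaded) == [0, 1, 2]
        for c in dists:
            assert np.array_equal(loaded[c].mean, dists[c].mean)
            assert np.array_equal(loaded[c].covariance, dists[c].covariance)
            assert loaded[c].cut_point == "pool_2"
            assert loaded[c].spatial_shape == dists[c].spatial_shape
            assert loaded[c].orig_spatial_shape == dists[c].orig_spatial_shape
            assert loaded[c].downsample_factor == dists[c].downsample_factor
            assert loaded[c].n_fit == dists[c].n_fit

    def test_model_checkpoint_round_trip(self, small_model, rng, tmp_path):
        path = tmp_path / "model.npz"
        network.save_model(small_model, path)
        loaded = network.load_model(path)
        X = rng.random((3, 32, 32, 3)).astype(np.float32)
        assert np.array_equal(loaded.forward(X), small_model.forward(X))
        assert weight_fingerprint(loaded.layers) == weight_fingerprint(small_model.layers)
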