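"""Generator contracts: label hierarchy, features, voxels, sequences."""

import numpy as np
import pytest

import cortexflow as cf
from cortexflow.synthetic import (
    N_COARSE,
    N_FINE,
    N_MID,
    _balanced_fine_labels,
    make_label_hierarchy,
    shuffle_labels,
    simulate_area_sequences,
    simulate_dataset,
    simulate_features,
    simulate_voxels_from_features,
    stack_sequences,
)


class TestLabelHierarchy:
    def test_nested_partition_has_no_orphans(self):
        h = make_label_hierarchy(seed=0)
        fine = np.arange(N_FINE)
        mid = h.mid_of(fine)
        coarse = h.coarse_of_fine(fine)
        assert set(mid) == set(range(N_MID))
        assert set(coarse) == set(range(N_COARSE))

    def test_group_sizes_balanced(self):
        """Mid groups hold 2-3 fine labels, coarse groups 4-5, at any seed."""
        for seed in range(5):
            h = make_label_hierarchy(seed)
            fine = np.arange(N_FINE)
            mid_sizes = np.bincount(h.mid_of(fine), minlength=N_MID)
            coarse_sizes = np.bincount(h.coarse_of_fine(fine), minlength=N_COARSE)
            assert set(mid_sizes) <= {2, 3}
            assert set(coarse_sizes) <= {4, 5}

    def test_deterministic_per_seed(self):
        assert make_label_hierarchy(3) == make_label_hierarchy(3)
        assert make_label_hierarchy(3) != make_label_hierarchy(4)

    def test_exactly_ten_distinct_mid_labels(self):
        h = make_label_hierarchy(seed=2)
        assert len(set(h.mid_of_fine)) == N_MID

    def test_consistent_through_levels(self):
        h = make_label_hierarchy(seed=1)
        fine = np.arange(N_FINE)
        # coarse through mid equals coarse_of_fine
        via_mid = np.asarray(h.coarse_of_mid)[h.mid_of(fine)]
        assert np.array_equal(via_mid, h.coarse_of_fine(fine))


class TestFeatures:
    def test_shapes_follow_config(self):
        cfg = cf.SimConfig(n_train=80, n_val=20, feature_dims=(64, 128), seed=0)
        feats = simulate_features(cfg)
        assert feats[0].shape == (100, 64)
        assert feats[1].shape == (100, 128)

    def test_columns_approximately_standard_normal(self):
        cfg = cf.SimConfig(n_train=900, n_val=100, feature_dims=(32,), seed=0)
        X = simulate_features(cfg)[0]
        n = X.shape[0]
        assert np.all(np.abs(X.mean(axis=0)) < 4 / np.sqrt(n))

    def test_bitwise_deterministic(self):
        cfg = cf.SimConfig(n_train=50, n_val=10, seed=9)
        a = simulate_features(cfg)
        b = simulate_features(cfg)
        for layer in a:
            assert np.array_equal(a[layer], b[layer])

    def test_zero_dims_rejected(self):
        with pytest.raises(ValueError):
            cf.SimConfig(feature_dims=(64, 0))


class TestVoxelsFromFeatures:
    def test_noiseless_limit_is_standardized_signal(self):
        cfg = cf.SimConfig(n_train=100, n_val=20, voxels_per_area=5,
                           feature_dims=(16,), sparsity_k=2, snr=np.inf, seed=0)
        feats = simulate_features(cfg)
        vox, truth = simulate_voxels_from_features(feats, cfg)
        vset = vox["V1"]
        for i, vid in enumerate(vset.voxel_ids):
            signal = feats[0] @ truth.true_weights[vid]
            mu = signal[:100].mean()
            sd = signal[:100].std()
            assert np.allclose(vset.data[:, i], (signal - mu) / sd)

    def test_training_split_standardized(self, small_config):
        feats = simulate_features(small_config)
        vox, _ = simulate_voxels_from_features(feats, small_config)
        for vset in vox.values():
            train = vset.data[: small_config.n_train]
            assert np.all(np.abs(train.mean(axis=0)) < 1e-9)
            assert np.all(np.abs(train.var(axis=0) - 1.0) < 1e-9)

    def test_snr_matches_empirical_variance_ratio(self):
        """R^2 of the true sparse model ~ snr/(snr+1), within 20% at n=1000."""
        cfg = cf.SimConfig(n_train=1000, n_val=20, voxels_per_area=30,
                           feature_dims=(16,), sparsity_k=2, snr=4.0, seed=3)
        feats = simulate_features(cfg)
        vox, truth = simulate_voxels_from_features(feats, cfg)
        r2s = []
        for i, vid in enumerate(vox["V1"].voxel_ids):
            y = vox["V1"].data[:1000, i]
            signal = feats[0][:1000] @ truth.true_weights[vid]
            s = (signal - signal.mean()) / signal.std()
            resid = y - np.polyval(np.polyfit(s, y, 1), s)
            r2s.append(1 - resid.var() / y.var())
        expected = cfg.snr / (cfg.snr + 1.0)  # 0.8 at snr=4
        assert abs(np.mean(r2s) - expected) < 0.2 * expected

    def test_sparsity_exceeding_dim_rejected(self):
        cfg = cf.SimConfig(n_train=50, n_val=10, feature_dims=(4,), sparsity_k=5)
        feats = simulate_features(cfg)
        with pytest.raises(ValueError):
            simulate_voxels_from_features(feats, cfg)

    def test_supports_have_exactly_k_indices(self, small_config):
        feats = simulate_features(small_config)
        _, truth = simulate_voxels_from_features(feats, small_config)
        for vid, support in truth.true_supports.items():
            assert support.size == small_config.sparsity_k
            assert len(set(support)) == small_config.sparsity_k


class TestAreaSequences:
    def test_shapes_and_labels(self, hierarchy):
        cfg = cf.SimConfig(n_train=46, n_val=23, voxels_per_area=7, seed=0)
        train, val, _ = simulate_area_sequences(cfg, hierarchy)
        assert len(train) == 46 and len(val) == 23
        for s in train:
            assert s.areas.shape == (5, 7)
            assert hierarchy.mid_of_fine[s.fine] == s.mid
            assert hierarchy.coarse_of_mid[s.mid] == s.coarse

    def test_label_balance_within_one(self, hierarchy):
        cfg = cf.SimConfig(n_train=230, n_val=23, voxels_per_area=4, seed=5)
        train, _, _ = simulate_area_sequences(cfg, hierarchy)
        counts = np.bincount([s.fine for s in train], minlength=23)
        assert counts.max() - counts.min() <= 1

    def test_no_signal_null_is_chance(self, hierarchy):
        """With both signal terms zero, a strong classifier stays at chance.

        Averaged over three generator seeds; the 99% binomial CI applies to
        the pooled validation count.
        """
        accs = []
        for seed in range(3):
            cfg = cf.SimConfig(n_train=400, n_val=200, voxels_per_area=8,
                               beta_marginal=(0,) * 5, beta_relational=0.0,
                               seed=seed)
            train, val, _ = simulate_area_sequences(cfg, hierarchy)
            accs.append(cf.train_classical(train, val, "svm_linear", seed=0)[1])
        half = 2.576 * np.sqrt(0.2 * 0.8 / (3 * 200))
        assert abs(np.mean(accs) - 0.2) <= half

    def test_marginal_signal_linearly_separable_at_high_snr(self, hierarchy):
        cfg = cf.SimConfig(n_train=600, n_val=200, voxels_per_area=12,
                           beta_marginal=(8.0,) * 5, beta_relational=0.0, seed=0)
        train, val, _ = simulate_area_sequences(cfg, hierarchy)
        _, acc = cf.train_classical(train, val, "svm_linear", seed=0)
        assert acc >= 0.98

    def test_deterministic_per_seed(self, hierarchy):
        cfg = cf.SimConfig(n_train=20, n_val=10, voxels_per_area=5, seed=11)
        a_train, a_val, _ = simulate_area_sequences(cfg, hierarchy)
        b_train, b_val, _ = simulate_area_sequences(cfg, hierarchy)
        for a, b in zip(a_train + a_val, b_train + b_val):
            assert np.array_equal(a.areas, b.areas)
            assert a.labels == b.labels


class TestShuffleLabels:
    def test_histogram_preserved_and_data_untouched(self, hierarchy):
        cfg = cf.SimConfig(n_train=60, n_val=10, voxels_per_area=4, seed=0)
        train, _, _ = simulate_area_sequences(cfg, hierarchy)
        shuffled = shuffle_labels(train, seed=1)
        assert sorted(s.fine for s in train) == sorted(s.fine for s in shuffled)
        for a, b in zip(train, shuffled):
            assert a.areas is b.areas
        assert any(a.fine != b.fine for a, b in zip(train, shuffled))

    def test_deterministic_per_seed(self, hierarchy):
        cfg = cf.SimConfig(n_train=40, n_val=10, voxels_per_area=4, seed=0)
        train, _, _ = simulate_area_sequences(cfg, hierarchy)
        a = shuffle_labels(train, seed=7)
        b = shuffle_labels(train, seed=7)
        assert [s.labels for s in a] == [s.labels for s in b]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shuffle_labels([], seed=0)


class TestCompositeDataset:
    def test_carries_both_structures(self, hierarchy):
        cfg = cf.SimConfig(n_train=100, n_val=40, voxels_per_area=6,
                           feature_dims=(8, 12), sparsity_k=2, seed=0)
        feats, vox, labels, truth = simulate_dataset(cfg, hierarchy)
        assert set(vox) == set(cfg.areas)
        assert len(labels["fine"]) == 140
        assert len(truth.true_supports) == 5 * 6
        assert truth.class_means.shape == (23, 5, 6)

    def test_balanced_labels_helper(self):
        rng = np.random.default_rng(0)
        labels = _balanced_fine_labels(47, rng)
        counts = np.bincount(labels, minlength=23)
        assert counts.max() - counts.min() <= 1


def test_stack_sequences_roundtrip(hierarchy):
    cfg = cf.SimConfig(n_train=10, n_val=5, voxels_per_area=3, seed=0)
    train, _, _ = simulate_area_sequences(cfg, hierarchy)
    X, labels = stack_sequences(train)
    assert X.shape == (10, 5, 3)
    assert np.array_equal(labels["fine"], [s.fine for s in train])
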