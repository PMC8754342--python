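"""Clustering, embedding, z-scores, homogeneity, morphometrics, markers."""

import numpy as np
import pandas as pd
import pytest

from upside import (cluster_composition, cluster_latents, embed_umap,
                    feature_correlation_groups, homogeneity_score,
                    morphometrics, quantify_markers, weight_sweep,
                    zscore_matrix)
from .oracles import brute_force_homogeneity


def _two_blobs(n=100, dim=8, sep=20.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n, dim))
    b = rng.normal(0.0, 1.0, (n, dim))
    b[:, 0] += sep
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestClustering:
    def test_two_extreme_blobs_two_clusters(self):
        X, truth = _two_blobs(sep=20.0)
        labels = cluster_latents(X, knn_k=10, resolution=0.1, seed=0)
        assert labels.max() + 1 == 2
        # silhouette oracle: the partition matches the planted one
        from sklearn.metrics import adjusted_rand_score, silhouette_score

        assert adjusted_rand_score(truth, labels) == 1.0
        assert silhouette_score(X, labels) > 0.5

    def test_identical_points_one_cluster(self):
        X = np.zeros((30, 4))
        labels = cluster_latents(X, knn_k=5, seed=0)
        assert labels.max() == 0

    def test_seeded_determinism(self):
        X, _ = _two_blobs(sep=3.0, seed=2)
        a = cluster_latents(X, knn_k=10, seed=7)
        b = cluster_latents(X, knn_k=10, seed=7)
        assert np.array_equal(a, b)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_latents(np.zeros((5, 2)), knn_k=10)

    def test_merge_map_never_increases_labels(self):
        X, _ = _two_blobs(sep=2.0, seed=3)
        raw = cluster_latents(X, knn_k=10, resolution=1.0, seed=0)
        merge = {i: i // 2 for i in range(raw.max() + 1)}
        merged = cluster_latents(X, knn_k=10, resolution=1.0, seed=0,
                                 merge_map=merge)
        assert merged.max() <= raw.max()


class TestUmap:
    def test_shape_separation_determinism(self):
        X, truth = _two_blobs(n=60, sep=20.0)
        c1 = embed_umap(X, n_neighbors=10, seed=0)
        assert c1.shape == (120, 2)
        assert np.isfinite(c1).all()
        centres = [c1[truth == k].mean(0) for k in (0, 1)]
        spread = np.mean([np.linalg.norm(c1[truth == k]
                                         - centres[k], axis=1).mean()
                          for k in (0, 1)])
        assert np.linalg.norm(centres[0] - centres[1]) > 3 * spread
        c2 = embed_umap(X, n_neighbors=10, seed=0)
        assert np.allclose(c1, c2)


class TestZScores:
    def test_hand_computed_value(self):
        # one feature: cluster mean 2.0, dataset mean 1.0, sd 0.5 -> Z = 2
        X = np.array([[2.0], [2.0], [0.5], [0.5], [0.5], [0.5]])
        X[2:] = [[0.5]]
        labels = np.array([0, 0, 1, 1, 1, 1])
        Z, ids, _, _ = zscore_matrix(X, labels)
        mu, sd = X.mean(), X.std()
        assert Z[0, 0] == pytest.approx((2.0 - mu) / sd)

    def test_single_cluster_all_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        Z, _, _, _ = zscore_matrix(X, np.zeros(50, dtype=int))
        assert np.allclose(Z, 0.0)

    def test_weighted_cluster_means_recover_dataset_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 4))
        labels = rng.integers(0, 3, 80)
        Z, ids, _, _ = zscore_matrix(X, labels)
        sd = X.std(axis=0)
        weights = np.array([(labels == c).sum() for c in ids]) / len(X)
        # sum_C n_C (mu_fC - mu_f) = 0  =>  weighted Z rows cancel
        assert np.allclose((weights[:, None] * Z).sum(axis=0), 0.0,
                           atol=1e-12)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        labels = rng.integers(0, 3, 60)
        Z1, ids1, _, _ = zscore_matrix(X, labels)
        Z2, ids2, _, _ = zscore_matrix(X, 2 - labels)
        assert np.allclose(Z1, Z2[::-1])

    def test_zero_variance_feature_warns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.warns(UserWarning):
            Z, _, _, _ = zscore_matrix(X, np.repeat([0, 1], 10))
        assert np.all(Z[:, 0] == 0)


class TestFeatureGroups:
    def test_duplicated_feature_same_group(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(500, 1))
        X = np.column_stack([base, base, rng.normal(size=(500, 2))])
        corr, kept, groups = feature_correlation_groups(X, 3)
        assert corr[0, 1] == pytest.approx(1.0)
        g_of = {f: gi for gi, g in enumerate(groups) for f in g}
        assert g_of[0] == g_of[1]

    def test_independent_features_weak_offdiagonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10000, 6))
        corr, _, _ = feature_correlation_groups(X, 3)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        corr, _, _ = feature_correlation_groups(rng.normal(size=(100, 5)), 2)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)


class TestHomogeneity:
    def test_separated_blobs_score_one(self):
        X, types = _two_blobs(n=50, sep=1000.0)
        per_type, mean_h = homogeneity_score(X, types, n_neighbors=10)
        assert per_type[0] == 1.0 and per_type[1] == 1.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(6, 31))
            X = rng.normal(size=(n, 3))
            types = rng.integers(0, 3, n)
            if len(np.unique(types)) < 2:
                continue
            N = int(rng.integers(1, n - 1))
            fast = homogeneity_score(X, types, N)
            slow = brute_force_homogeneity(X, types, N)
            assert fast[1] == pytest.approx(slow[1], abs=1e-12)
            for t in fast[0]:
                assert fast[0][t] == pytest.approx(slow[0][t], abs=1e-12)

    def test_random_labels_baseline(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2000, 5))
        types = rng.integers(0, 4, 2000)
        _, mean_h = homogeneity_score(X, types, n_neighbors=20)
        assert mean_h == pytest.approx(0.25, abs=0.03)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 3))
        types = rng.integers(0, 2, 100)
        base = homogeneity_score(X, types, 10)
        # random rotation + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = X @ Q + rng.normal(size=3)
        assert homogeneity_score(moved, types, 10)[1] == \
            pytest.approx(base[1], abs=1e-9)

    def test_neighbor_count_bounds(self):
        with pytest.raises(ValueError):
            homogeneity_score(np.zeros((5, 2)), np.zeros(5), 5)


class TestWeightSweep:
    def test_single_value_grid(self):
        rng = np.random.default_rng(0)
        zs = rng.normal(size=(40, 3))
        zt = rng.normal(size=(40, 3))
        types = rng.integers(0, 2, 40)
        _, best = weight_sweep(zs, zt, types, w_grid=[0.3], n_neighbors=5)
        assert best == 0.3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            weight_sweep(np.zeros((10, 2)), np.zeros((10, 2)),
                         np.zeros(10), w_grid=[])

    def test_shape_informative_latents_push_w_up(self):
        rng = np.random.default_rng(1)
        types = np.repeat([0, 1], 100)
        # moderate separation so down-weighting shape genuinely degrades H;
        # the noise branch matches the signal branch's overall scale
        z_shape = rng.normal(size=(200, 6))
        z_shape[types == 1, 0] += 3.0
        z_texture = rng.normal(0, z_shape.std(), size=(200, 6))
        _, best = weight_sweep(z_shape, z_texture, types, n_neighbors=15)
        assert best >= 0.8


class TestMorphometrics:
    def test_disc(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 15**2
        m = morphometrics(disc)
        assert m["eccentricity"] < 0.05
        assert m["area"] == disc.sum()

    def test_two_to_one_ellipse(self):
        yy, xx = np.mgrid[0:128, 0:128]
        ell = (((xx - 63.5) / 40) ** 2 + ((yy - 63.5) / 20) ** 2) <= 1
        m = morphometrics(ell)
        assert m["eccentricity"] == pytest.approx(np.sqrt(3) / 2, abs=0.02)

    def test_constant_image_zero_edge_strength(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disc = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 8**2
        m = morphometrics(disc, np.full((32, 32), 0.7))
        assert m["edge_strength"] == 0.0

    def test_calibration(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disc = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 8**2
        m = morphometrics(disc, um_per_px=0.5)
        assert m["area"] == pytest.approx(disc.sum() * 0.25)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morphometrics(np.zeros((8, 8), bool))


class TestMarkers:
    def _mask(self):
        yy, xx = np.mgrid[0:40, 0:40]
        return (yy - 20) ** 2 + (xx - 20) ** 2 <= 6**2

    def test_uniform_frame_zero_background(self):
        mask = self._mask()
        frame = np.where(mask, 3.5, 0.0)
        out = quantify_markers(mask, {"CD34": frame[None]}, 0.0, [0.0])
        assert out["CD34"] == pytest.approx(3.5)

    def test_two_cells_known_intensities(self):
        mask = self._mask()
        for level in (100.0, 200.0):
            frame = np.where(mask, level, 0.0)
            out = quantify_markers(mask, {"m": frame[None]}, 0.0, [0.0])
            assert out["m"] == pytest.approx(level)

    def test_background_subtraction(self):
        mask = self._mask()
        frame = np.where(mask, 10.0, 4.0)
        out = quantify_markers(mask, {"m": frame[None]}, 0.0, [0.0])
        assert out["m"] == pytest.approx(6.0)

    def test_no_frame_within_tolerance(self):
        mask = self._mask()
        out = quantify_markers(mask, {"m": np.zeros((1, 40, 40))},
                               frame_time_min=100.0, marker_times_min=[0.0],
                               max_dt_min=30.0)
        assert np.isnan(out["m"])

    def test_gating_recovers_planted_fractions(self):
        """A CD34/CD38 quadrant gate on bimodal intensities recovers the
        planted subpopulation fractions."""
        rng = np.random.default_rng(6)
        n = 2000
        stem = rng.random(n) < 0.3    # planted CD34+CD38- fraction
        cd34 = np.where(stem, rng.normal(100, 10, n), rng.normal(10, 5, n))
        cd38 = np.where(stem, rng.normal(8, 4, n), rng.normal(120, 12, n))
        gate34, gate38 = 50.0, 50.0
        frac_stem = np.mean((cd34 > gate34) & (cd38 < gate38))
        assert frac_stem == pytest.approx(0.3, abs=0.05)


class TestComposition:
    def test_single_type(self):
        frac = cluster_composition(np.array([0, 0, 1, 1]),
                                   np.array(["a"] * 4))
        assert np.allclose(frac.to_numpy(), 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 4, 300)
        types = rng.choice(["x", "y", "z"], 300)
        frac = cluster_composition(labels, types)
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_balanced_sampling_recovers_planted_mixture(self):
        rng = np.random.default_rng(8)
        # cluster 0 drawn 80/20 from types a/b; cluster 1 20/80
        types = np.array(["a"] * 500 + ["b"] * 500)
        labels = np.concatenate([
            rng.choice([0, 1], 500, p=[0.8, 0.2]),
            rng.choice([0, 1], 500, p=[0.2, 0.8])])
        frac = cluster_composition(labels, types, balanced_sample=400,
                                   seed=0)
        assert frac.loc[0, "a"] == pytest.approx(0.8, abs=0.06)
        assert frac.loc[1, "b"] == pytest.approx(0.8, abs=0.06)

    def test_balanced_needs_enough_cells(self):
        with pytest.raises(ValueError):
            cluster_composition(np.zeros(10), np.array(["a"] * 8 + ["b"] * 2),
                                balanced_sample=5)
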