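"""Z-score transform, UMAP embedding, seeded k-means, and cluster merging."""

import numpy as np
import pandas as pd
import pytest

from tecmap import (
    Embedding,
    ExpressionMatrix,
    PipelineConfig,
    Stage,
    embed_umap,
    kmeans_partition,
    merge_adjacent_clusters,
    seed_centers,
    zscore_transform,
)
from tecmap.cluster import SeedCenters, _hull_area
from .conftest import make_spec_calls


def frame(x):
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(
        x, index=[f"g{i}" for i in range(x.shape[0])], columns=[f"s{i}" for i in range(x.shape[1])]
    )


class TestZscore:
    def test_constant_row_becomes_zeros(self):
        z = zscore_transform(frame([[7.0, 7.0, 7.0]]))
        np.testing.assert_allclose(z.values, 0.0)

    def test_two_point_hand_formula(self):
        z = zscore_transform(frame([[1.0, 3.0]]))
        np.testing.assert_allclose(z.values[0], [-0.7071, 0.7071], atol=1e-4)

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        z = zscore_transform(frame(rng.lognormal(0, 1, (50, 9))))
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        sd = z.values.std(axis=1, ddof=1)
        assert np.all((np.abs(sd - 1) < 1e-9) | (sd == 0))


def fast_cfg(**kw):
    return PipelineConfig(umap_n_epochs=200, **kw)


def two_module_matrix(n_per=100, n_samples=24, seed=0):
    """Two orthogonal expression programs plus mild noise."""
    rng = np.random.default_rng(seed)
    a = np.zeros(n_samples)
    a[: n_samples // 2] = 5.0
    b = 5.0 - a
    rows = [a + rng.normal(0, 0.2, n_samples) + 1 for _ in range(n_per)]
    rows += [b + rng.normal(0, 0.2, n_samples) + 1 for _ in range(n_per)]
    return frame(np.abs(rows))


class TestUmap:
    def test_one_point_per_gene(self):
        z = zscore_transform(two_module_matrix())
        emb = embed_umap(z, fast_cfg(), seed=0)
        assert emb.coords.shape == (200, 2)
        assert list(emb.coords.index) == list(z.index)

    def test_same_seed_same_coordinates(self):
        z = zscore_transform(two_module_matrix())
        e1 = embed_umap(z, fast_cfg(), seed=5)
        e2 = embed_umap(z, fast_cfg(), seed=5)
        np.testing.assert_array_equal(e1.coords.values, e2.coords.values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_orthogonal_modules_separate(self, seed):
        z = zscore_transform(two_module_matrix(seed=seed))
        emb = embed_umap(z, fast_cfg(), seed=seed)
        xy = emb.coords.to_numpy()
        c1, c2 = xy[:100].mean(axis=0), xy[100:].mean(axis=0)
        spread = np.concatenate(
            [
                np.linalg.norm(xy[:100] - c1, axis=1),
                np.linalg.norm(xy[100:] - c2, axis=1),
            ]
        ).mean()
        assert np.linalg.norm(c1 - c2) > 3 * spread

    def test_too_few_genes_rejected(self):
        z = zscore_transform(frame(np.random.default_rng(0).random((10, 6))))
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_umap(z, fast_cfg(), seed=0)


def blob_embedding(centers, n=50, scale=0.01, seed=0):
    rng = np.random.default_rng(seed)
    pts, ids = [], []
    for bi, c in enumerate(centers):
        pts.append(rng.normal(0, scale, (n, 2)) + np.asarray(c))
        ids += [f"b{bi}_{i}" for i in range(n)]
    coords = pd.DataFrame(np.vstack(pts), index=ids, columns=["x", "y"])
    return Embedding(coords, 15, 1000, seed)


class TestSeedCenters:
    def test_two_blobs_two_centroids(self, cfg):
        emb = blob_embedding([(0, 0), (1, 0)], scale=0.012)
        sc = seed_centers(emb, cfg, seed=0)
        density = sc.centers[: sc.provenance.count("density_centroid")]
        assert len(density) == 2
        for blob_c in [(0, 0), (1, 0)]:
            assert min(np.linalg.norm(density - blob_c, axis=1)) < 0.05

    def test_identical_points_single_center_no_extras(self, cfg):
        coords = pd.DataFrame(
            np.tile([0.3, 0.4], (20, 1)), index=[f"g{i}" for i in range(20)], columns=["x", "y"]
        )
        sc = seed_centers(Embedding(coords, 15, 1000, 0), cfg, seed=0)
        assert len(sc.centers) == 1
        np.testing.assert_allclose(sc.centers[0], [0.3, 0.4])
        assert sc.provenance == ["density_centroid"]

    def test_deterministic_for_fixed_seed(self, cfg):
        emb = blob_embedding([(0, 0), (2, 0), (0, 2)], n=120, scale=0.05)
        s1 = seed_centers(emb, cfg, seed=3)
        s2 = seed_centers(emb, cfg, seed=3)
        np.testing.assert_array_equal(s1.centers, s2.centers)
        assert s1.provenance == s2.provenance

    def test_no_density_cluster_falls_back_to_centroid(self, cfg):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(
            rng.uniform(0, 100, (30, 2)), index=[f"g{i}" for i in range(30)], columns=["x", "y"]
        )
        with pytest.warns(UserWarning, match="centroid"):
            sc = seed_centers(Embedding(coords, 15, 1000, 0), cfg, seed=0)
        assert len(sc.centers) == 1

    def test_degenerate_hull_area_is_zero(self):
        assert _hull_area(np.array([[0.0, 0.0], [1.0, 1.0]])) == 0.0
        assert _hull_area(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])) == 0.0


class TestKmeans:
    def test_two_blobs_recovered(self, cfg):
        emb = blob_embedding([(0, 0), (3, 0)], n=40, scale=0.05)
        labels = kmeans_partition(emb, SeedCenters(np.array([[0.2, 0.1], [2.5, 0.0]])), cfg)
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_single_center_single_cluster(self, cfg):
        emb = blob_embedding([(0, 0)], n=30)
        labels = kmeans_partition(emb, SeedCenters(np.array([[5.0, 5.0]])), cfg)
        assert set(labels) == {1}

    def test_sse_non_increasing(self, cfg):
        from scipy.spatial.distance import cdist

        emb = blob_embedding([(0, 0), (1, 1), (2, 0)], n=60, scale=0.3, seed=4)
        xy = emb.coords.to_numpy()
        rng = np.random.default_rng(0)
        mu = xy[rng.choice(len(xy), 5, replace=False)]
        sses = []
        for n_iter in range(1, 8):
            labels = kmeans_partition(emb, SeedCenters(mu.copy()), PipelineConfig(kmeans_iterations=n_iter))
            centers = np.vstack([xy[labels == c].mean(axis=0) for c in sorted(set(labels))])
            d = cdist(xy, centers).min(axis=1)
            sses.append((d**2).sum())
        assert all(b <= a + 1e-9 for a, b in zip(sses, sses[1:]))

    def test_empty_center_dropped_with_contiguous_labels(self, cfg):
        emb = blob_embedding([(0, 0)], n=25, scale=0.01)
        centers = SeedCenters(np.array([[0.0, 0.0], [50.0, 50.0]]))
        with pytest.warns(UserWarning, match="empty"):
            labels = kmeans_partition(emb, centers, cfg)
        assert set(labels) == {1}


def grid_embedding(spots, per=30, scale=0.005, seed=0):
    return blob_embedding(spots, n=per, scale=scale, seed=seed)


class TestMerge:
    def _run(self, spots, tissue_sets, cfg=None, n_per=30):
        """Each spot is one k-means cluster; tissue_sets[i] marks its genes elevated.

        A distant background blob of 3x n_per low-specificity genes is
        always appended so elevated genes are a minority of the universe
        (otherwise the hypergeometric test has no power).
        """
        cfg = cfg or PipelineConfig()
        spots = list(spots) + [(50.0, 50.0)]
        sizes = [n_per] * (len(spots) - 1) + [3 * n_per]
        rng = np.random.default_rng(0)
        pts, ids = [], []
        for bi, (c, n) in enumerate(zip(spots, sizes)):
            pts.append(rng.normal(0, 0.005, (n, 2)) + np.asarray(c))
            ids += [f"b{bi}_{i}" for i in range(n)]
        emb = Embedding(
            pd.DataFrame(np.vstack(pts), index=ids, columns=["x", "y"]), 15, 1000, 0
        )
        labels = np.concatenate(
            [np.full(n, bi + 1) for bi, n in enumerate(sizes)]
        )
        rows = []
        for ci, n in enumerate(sizes):
            tissues = tissue_sets[ci] if ci < len(tissue_sets) else []
            for gi in range(n):
                gid = f"b{ci}_{gi}"
                if tissues:
                    cat = "tissue_enriched" if len(tissues) == 1 else "group_enriched"
                    rows.append((gid, cat, list(tissues)))
                else:
                    rows.append((gid, "low_specificity", []))
        calls = make_spec_calls(rows)
        return merge_adjacent_clusters(labels, emb, calls, cfg)

    def test_adjacent_same_set_merged(self):
        asg = self._run([(0, 0), (0.05, 0)], [["testis"], ["testis"]])
        assert asg.n_clusters == 2  # merged pair + background

    def test_distant_same_set_not_merged(self):
        asg = self._run([(0, 0), (5, 0)], [["testis"], ["testis"]])
        assert asg.n_clusters == 3

    def test_subset_sets_not_merged(self):
        asg = self._run([(0, 0), (0.05, 0)], [["testis"], ["testis", "brain"]])
        assert asg.n_clusters == 3

    def test_empty_sets_never_merge(self):
        asg = self._run([(0, 0), (0.05, 0)], [[], []])
        assert asg.n_clusters == 3

    def test_chain_collapses_to_single_cluster(self):
        asg = self._run(
            [(0, 0), (0.05, 0), (0.1, 0)], [["testis"], ["testis"], ["testis"]]
        )
        assert asg.n_clusters == 2
        assert asg.merge_rounds >= 1

    def test_final_associations_at_strict_alpha(self):
        asg = self._run([(0, 0), (3, 0)], [["liver"], []])
        sig = asg.clusters.set_index("cluster_id")["significant_tissues"]
        liver_cluster = asg.labels[0]
        assert sig[liver_cluster] == ["liver"]

    def test_labels_partition_and_counts_sum(self):
        asg = self._run([(0, 0), (1, 0), (2, 0)], [["a"], ["b"], []])
        assert asg.clusters["n_genes"].sum() == len(asg.gene_ids)
        assert set(asg.labels) == set(range(1, asg.n_clusters + 1))
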