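import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ionvox import neighborhoods as nb


def _blobs(n_per=60, d=4, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per, d))
    b = rng.normal(sep, 1.0, (n_per, d))
    X = np.vstack([a, b])
    truth = np.repeat([0, 1], n_per)
    return X, truth


def _table(values: dict, fov="f"):
    n = len(next(iter(values.values())))
    base = {"fov_id": fov, "center_x": 0.0, "center_y": 0.0, "center_z": 0.0,
            "wx": 1, "wy": 1, "wz": 1, "sx": 1, "sy": 1, "sz": 1,
            "normalization": "raw"}
    return pd.DataFrame({**{k: [v] * n for k, v in base.items()},
                         **{k: np.asarray(v, float)
                            for k, v in values.items()}})


class TestHierarchicalCluster:
    def test_k_one_single_label(self):
        X, _ = _blobs(10)
        assert set(nb.hierarchical_cluster(X, 1)) == {1}

    def test_k_n_singletons(self):
        X, _ = _blobs(5)
        assert len(set(nb.hierarchical_cluster(X, len(X)))) == len(X)

    def test_separated_blobs_fully_recovered(self):
        X, truth = _blobs()
        labels = nb.hierarchical_cluster(X, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_out_of_range(self):
        X, _ = _blobs(5)
        with pytest.raises(ValueError, match="k="):
            nb.hierarchical_cluster(X, len(X) + 1)


class TestEmbedTsne:
    def test_deterministic_and_shaped(self):
        X, _ = _blobs(40, sep=8.0)
        a = nb.embed_tsne(X, perplexity=10, seed=3, n_iter=300)
        b = nb.embed_tsne(X, perplexity=10, seed=3, n_iter=300)
        assert a.shape == (len(X), 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_blobs_stay_separated(self):
        X, truth = _blobs(50, sep=12.0, seed=2)
        emb = nb.embed_tsne(X, perplexity=10, seed=1, n_iter=300)
        intra = np.linalg.norm(
            emb[truth == 0] - emb[truth == 0].mean(axis=0), axis=1).mean()
        inter = np.linalg.norm(
            emb[truth == 0].mean(axis=0) - emb[truth == 1].mean(axis=0))
        assert inter > intra

    def test_perplexity_too_large(self):
        X, _ = _blobs(10)
        with pytest.raises(ValueError, match="perplexity"):
            nb.embed_tsne(X, perplexity=10)


class TestClusterOnEmbedding:
    def test_two_blobs_in_plane(self):
        X, truth = _blobs(40, d=2, sep=15.0)
        labels = nb.cluster_on_embedding(X, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_requires_2d(self):
        with pytest.raises(ValueError, match="n, 2"):
            nb.cluster_on_embedding(np.zeros((10, 3)), 2)


class TestMergeClusters:
    def test_identity_map(self):
        labels = np.array([1, 2, 3, 3])
        out = nb.merge_clusters(labels, {1: 1, 2: 2, 3: 3})
        np.testing.assert_array_equal(out, labels)

    def test_all_to_one(self):
        out = nb.merge_clusters(np.array([1, 2, 3]), {1: 1, 2: 1, 3: 1})
        np.testing.assert_array_equal(out, 1)

    def test_worked_example(self):
        out = nb.merge_clusters(np.array([1, 2, 3, 3]), {1: 1, 2: 1, 3: 2})
        np.testing.assert_array_equal(out, [1, 1, 2, 2])

    def test_unmapped_label_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            nb.merge_clusters(np.array([1, 2]), {1: 1})

    def test_composition_property(self):
        labels = np.array([1, 2, 3, 4, 4, 2])
        m1 = {1: 1, 2: 1, 3: 2, 4: 3}
        m2 = {1: 1, 2: 2, 3: 2}
        composed = {k: m2[v] for k, v in m1.items()}
        np.testing.assert_array_equal(
            nb.merge_clusters(nb.merge_clusters(labels, m1), m2),
            nb.merge_clusters(labels, composed))


class TestProfiles:
    def test_single_cluster_equals_column_means(self):
        t = _table({"19F": [1, 2, 3], "31P": [4, 5, 9]})
        prof = nb.profile(t, np.ones(3, dtype=int))
        np.testing.assert_allclose(prof.loc[1], [2.0, 6.0])

    def test_constructed_two_cluster_values(self):
        t = _table({"19F": [1, 1, 5, 5], "31P": [2, 2, 0, 0]})
        prof = nb.profile(t, np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(prof.loc[1], [1.0, 2.0])
        np.testing.assert_allclose(prof.loc[2], [5.0, 0.0])

    def test_median_stat(self):
        t = _table({"19F": [1, 2, 100]})
        prof = nb.profile(t, np.ones(3, dtype=int), stat="median")
        assert prof.loc[1, "19F"] == 2.0

    def test_row_zscore_rows_centred(self):
        t = _table({"19F": [1, 5], "31P": [2, 1], "81Br": [3, 9]})
        prof = nb.profile(t, np.array([1, 2]), row_normalize="zscore")
        np.testing.assert_allclose(prof.mean(axis=1), 0.0, atol=1e-12)

    def test_sizeweighted_mean_of_zscored_profiles_is_zero(self):
        rng = np.random.default_rng(9)
        t = _table({"19F": rng.random(30), "31P": rng.random(30)})
        from ionvox.voxels import zscore

        tz = zscore(t)
        labels = rng.integers(1, 4, 30)
        prof = nb.profile(tz, labels)
        sizes = pd.Series(labels).value_counts().sort_index().to_numpy()
        weighted = (prof.to_numpy() * sizes[:, None]).sum(axis=0) / sizes.sum()
        np.testing.assert_allclose(weighted, 0.0, atol=1e-12)

    def test_empty_table_rejected(self):
        t = _table({"19F": []})
        with pytest.raises(ValueError, match="empty"):
            nb.profile(t, np.array([], dtype=int))


class TestAutoMerge:
    def test_obvious_profile_groups(self):
        profiles = pd.DataFrame(
            [[10, 0], [11, 0], [0, 10], [0, 12]],
            index=[1, 2, 3, 4], columns=["a", "b"], dtype=float)
        m = nb.auto_merge_map(profiles, 2)
        assert m[1] == m[2] and m[3] == m[4] and m[1] != m[3]

    def test_identity_when_k_equal(self):
        profiles = pd.DataFrame(np.eye(3), index=[1, 2, 3])
        assert nb.auto_merge_map(profiles, 3) == {1: 1, 2: 2, 3: 3}

    def test_too_many_final_clusters(self):
        with pytest.raises(ValueError, match="merge"):
            nb.auto_merge_map(pd.DataFrame(np.eye(2), index=[1, 2]), 3)


class TestGating:
    def test_bounding_rectangle_selects_all(self):
        pts = np.random.default_rng(1).random((20, 2))
        gate = [(-1, -1), (2, -1), (2, 2), (-1, 2)]
        assert nb.gate_embedding(pts, gate).all()

    def test_far_polygon_selects_none(self):
        pts = np.random.default_rng(1).random((20, 2))
        gate = [(100, 100), (101, 100), (100.5, 101)]
        assert not nb.gate_embedding(pts, gate).any()

    def test_unit_square_example(self):
        got = nb.gate_embedding(np.array([[0.5, 0.5], [2.0, 2.0]]),
                                [(0, 0), (1, 0), (1, 1), (0, 1)])
        assert list(got) == [True, False]

    def test_boundary_point_included(self):
        got = nb.gate_embedding(np.array([[0.0, 0.5]]),
                                [(0, 0), (1, 0), (1, 1), (0, 1)])
        assert got[0]

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            nb.gate_embedding(np.zeros((3, 2)), [(0, 0), (1, 1), (2, 2)])


class TestRendering:
    def _voxel_table(self, centers, w=(2, 2, 1)):
        wx, wy, wz = w
        return pd.DataFrame({
            "fov_id": "f",
            "center_x": [c[0] for c in centers],
            "center_y": [c[1] for c in centers],
            "center_z": [c[2] for c in centers],
            "wx": wx, "wy": wy, "wz": wz, "sx": wx, "sy": wy, "sz": wz,
            "normalization": "raw",
        })

    def test_single_voxel_footprint(self):
        t = self._voxel_table([(0.5, 0.5, 0.0)])
        vol = nb.render_neighborhood_map(t, np.array([4]), (2, 4, 4),
                                         mode="volume")
        assert vol[0, :2, :2].min() == 4
        assert vol.sum() == 4 * 4  # only the 2x2x1 footprint painted

    def test_disjoint_voxels_do_not_overwrite(self):
        t = self._voxel_table([(0.5, 0.5, 0.0), (2.5, 2.5, 1.0)])
        vol = nb.render_neighborhood_map(t, np.array([1, 2]), (2, 4, 4),
                                         mode="volume")
        assert (vol[0, :2, :2] == 1).all()
        assert (vol[1, 2:4, 2:4] == 2).all()

    def test_projection_majority(self):
        t = self._voxel_table([(0.5, 0.5, 0.0), (0.5, 0.5, 1.0),
                               (0.5, 0.5, 2.0)])
        proj = nb.render_neighborhood_map(t, np.array([1, 2, 2]), (3, 4, 4))
        assert (proj[:2, :2] == 2).all()

    def test_unit_windows_reproduce_label_volume(self, small_phantom):
        _, _, truth = small_phantom
        sub = truth.label_volume[:1, :6, :6] + 1  # nonzero labels
        zz, yy, xx = np.meshgrid(range(1), range(6), range(6), indexing="ij")
        t = self._voxel_table(
            list(zip(xx.ravel() * 1.0, yy.ravel() * 1.0, zz.ravel() * 1.0)),
            w=(1, 1, 1))
        vol = nb.render_neighborhood_map(t, sub.ravel(), (1, 6, 6),
                                         mode="volume")
        np.testing.assert_array_equal(vol, sub)

    def test_out_of_frame_rejected(self):
        t = self._voxel_table([(10.0, 0.5, 0.0)])
        with pytest.raises(ValueError, match="outside frame"):
            nb.render_neighborhood_map(t, np.array([1]), (2, 4, 4))


def test_model_summary_mentions_counts(small_phantom):
    labels = np.array([1, 1, 2])
    profiles = pd.DataFrame([[1.0], [2.0]], index=[1, 2], columns=["19F"])
    model = nb.NeighborhoodModel(labels=labels, k_initial=2, k_final=2,
                                 merge_map={1: 1, 2: 2}, profiles=profiles,
                                 channels_used=["19F"])
    text = model.summary()
    assert "2 final" in text and "3 voxels" in text
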