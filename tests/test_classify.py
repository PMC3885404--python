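"""PCA reduction, ISO clustering, library handling, classification, kappa."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, cohen_kappa_score

from rockveg.classify import (
    StructuralClassLibrary,
    ClassSummary,
    UNCLASSIFIED,
    apply_class_mapping,
    cohen_kappa,
    iso_cluster,
    merge_libraries,
    min_distance_classify,
    pca_reduce,
    standardize_features,
    summarize_classes,
)


class TestPcaReduce:
    def test_two_varying_dimensions_retained(self):
        rng = np.random.default_rng(0)
        X = np.zeros((100, 5))
        X[:, 1] = rng.normal(size=100)
        X[:, 3] = rng.normal(size=100)
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, *_ = standardize_features(X)
        scores, pca = pca_reduce(Z, 0.99)
        assert pca.n_components_ == 2

    def test_one_dimensional_scores_equal_input(self):
        x = np.linspace(-2, 2, 50).reshape(-1, 1)
        Z, *_ = standardize_features(x)
        scores, pca = pca_reduce(Z)
        assert pca.n_components_ == 1
        np.testing.assert_allclose(np.abs(scores[:, 0]), np.abs(Z[:, 0]), atol=1e-9)

    def test_retained_count_matches_eigenvalue_cumsum_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 5))
        X = rng.multivariate_normal(np.zeros(5), A @ A.T, size=400)
        Z, *_ = standardize_features(X)
        scores, pca = pca_reduce(Z, 0.99)
        eigvals = np.linalg.eigvalsh(np.cov(Z.T))[::-1]
        cum = np.cumsum(eigvals) / eigvals.sum()
        expected = int(np.searchsorted(cum, 0.99 - 1e-12) + 1)
        assert pca.n_components_ == expected


class TestIsoCluster:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, (200, 2))
        b = rng.normal(10, 0.1, (200, 2))
        X = np.vstack([a, b])
        truth = np.r_[np.zeros(200), np.ones(200)]
        labels, centroids = iso_cluster(X, k_init=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(centroids) == 2

    def test_small_cluster_dissolved(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.5, (1000, 2)), rng.normal(50, 0.1, (3, 2))])
        labels, centroids = iso_cluster(X, k_init=2, min_area=0.01, seed=0)
        assert len(centroids) == 1
        assert len(labels) == 1003  # membership conserved

    def test_identical_points_single_class(self):
        X = np.ones((50, 3))
        with pytest.warns(UserWarning, match="identical"):
            labels, centroids = iso_cluster(X, k_init=4, seed=0)
        assert len(centroids) == 1
        np.testing.assert_allclose(centroids[0], 1.0)

    def test_no_surviving_class_below_min_area(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 3))
        labels, centroids = iso_cluster(X, k_init=12, min_area=0.05, seed=1)
        counts = np.bincount(labels)
        assert (counts >= 0.05 * len(X)).all()
        assert counts.sum() == len(X)


def _library(centroids, mean_ch=None, mean_gc=None, n_members=None):
    k = len(centroids)
    lib = StructuralClassLibrary(
        feature_names=["f0", "f1"], mean=np.zeros(2), std=np.ones(2)
    )
    for cid in range(k):
        lib.classes.append(
            ClassSummary(
                class_id=cid,
                centroid=np.asarray(centroids[cid], dtype=float),
                mean_ch=(mean_ch or [0] * k)[cid],
                mean_gc=(mean_gc or [0] * k)[cid],
                area_fraction=1 / k,
                n_members=(n_members or [10] * k)[cid],
                layer_stats={
                    "canopy_height": {"min": 0.0, "max": 1.0, "median": 0.5}
                },
            )
        )
    return lib


class TestSummarizeClasses:
    def test_constant_class(self):
        feats = pd.DataFrame(
            {"canopy_height": [10.0] * 4, "cover": [30.0] * 4, "crown_thickness": [2.0] * 4}
        )
        lib = summarize_classes(
            np.zeros(4, dtype=int), feats, np.zeros((1, 2)), ["f0", "f1"], np.zeros(2), np.ones(2)
        )
        st = lib.classes[0].layer_stats["canopy_height"]
        assert st["min"] == st["max"] == st["median"] == 10.0
        assert lib.classes[0].mean_ch == 10.0

    def test_order_statistics(self):
        feats = pd.DataFrame(
            {"canopy_height": [2.0, 4.0, 9.0], "cover": [1, 2, 3], "crown_thickness": [1, 1, 1]}
        )
        lib = summarize_classes(
            np.zeros(3, dtype=int), feats, np.zeros((1, 2)), ["f0", "f1"], np.zeros(2), np.ones(2)
        )
        st = lib.classes[0].layer_stats["canopy_height"]
        assert (st["min"], st["median"], st["max"]) == (2.0, 4.0, 9.0)

    def test_two_classes_distinct_ids(self):
        feats = pd.DataFrame(
            {"canopy_height": [1.0, 2.0], "cover": [1, 2], "crown_thickness": [1, 1]}
        )
        lib = summarize_classes(
            np.array([0, 1]), feats, np.zeros((2, 2)), ["f0", "f1"], np.zeros(2), np.ones(2)
        )
        assert sorted(c.class_id for c in lib.classes) == [0, 1]

    def test_json_round_trip(self, tmp_path):
        lib = _library([[0, 0], [3, 4]], mean_ch=[1.0, 5.0], mean_gc=[10.0, 60.0])
        lib.to_json(tmp_path / "lib.json")
        back = StructuralClassLibrary.from_json(tmp_path / "lib.json")
        assert back.feature_names == lib.feature_names
        np.testing.assert_allclose(back.centroids(), lib.centroids())
        assert back.get(1).mean_ch == 5.0


class TestMergeLibraries:
    def test_identical_centroids_merge(self):
        a = _library([[0.0, 0.0]])
        b = _library([[0.0, 0.0]])
        merged = merge_libraries([a, b], merge_tol=0.5)
        assert len(merged.classes) == 1

    def test_distant_centroids_kept(self):
        a = _library([[0.0, 0.0]])
        b = _library([[5.0, 0.0]])
        merged = merge_libraries([a, b], merge_tol=0.5)
        assert len(merged.classes) == 2

    def test_single_link_chain(self):
        # a~b and b~c within tol, a-c beyond: all three merge transitively
        a = _library([[0.0, 0.0], [0.4, 0.0], [0.8, 0.0]])
        merged = merge_libraries([a], merge_tol=0.5)
        assert len(merged.classes) == 1

    def test_idempotent_and_never_grows(self):
        a = _library([[0.0, 0.0], [0.4, 0.0], [3.0, 3.0]])
        m1 = merge_libraries([a], merge_tol=0.5)
        m2 = merge_libraries([m1], merge_tol=0.5)
        assert len(m1.classes) <= len(a.classes)
        assert len(m2.classes) == len(m1.classes)

    def test_incompatible_feature_spaces_fatal(self):
        a = _library([[0.0, 0.0]])
        b = _library([[0.0, 0.0]])
        b.feature_names = ["other", "names"]
        with pytest.raises(ValueError):
            merge_libraries([a, b])


class TestMinDistanceClassify:
    def test_centroid_maps_to_own_class(self):
        cents = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert min_distance_classify([[5.0, 5.0]], cents)[0] == 1

    def test_tie_goes_to_smaller_id(self):
        cents = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert min_distance_classify([[1.0, 0.0]], cents)[0] == 0

    def test_nonfinite_gets_sentinel(self):
        cents = np.array([[0.0, 0.0]])
        assert min_distance_classify([[np.nan, 0.0]], cents)[0] == UNCLASSIFIED

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        cents = rng.normal(size=(12, 4))
        X = rng.normal(size=(1000, 4))
        labels = min_distance_classify(X, cents)
        oracle = np.argmin(cdist(X, cents), axis=1)
        np.testing.assert_array_equal(labels, oracle)


def test_apply_class_mapping():
    mapping = pd.DataFrame({"profile_class": [0, 1, 2], "structural_class": [0, 0, 1]})
    out = apply_class_mapping(np.array([0, 1, 2, 7]), mapping)
    np.testing.assert_array_equal(out, [0, 0, 1, UNCLASSIFIED])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 7, 9])) == 1.0

    def test_hand_computed_example(self):
        assert cohen_kappa([[25, 5], [10, 60]]) == pytest.approx(0.6591, abs=1e-4)

    def test_independent_margins_zero(self):
        row = np.array([0.3, 0.7])
        col = np.array([0.6, 0.4])
        M = np.outer(row, col) * 1000
        assert cohen_kappa(M) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, 500)
        b = np.where(rng.uniform(size=500) < 0.7, a, rng.integers(0, 4, 500))
        M = np.zeros((4, 4), dtype=int)
        for x, y in zip(a, b):
            M[x, y] += 1
        assert cohen_kappa(M) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_degenerate_margins_signalled(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohen_kappa([[5, 0], [0, 0]])

    def test_range_bounds(self):
        assert -1.0 <= cohen_kappa([[0, 10], [10, 0]]) <= 1.0
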