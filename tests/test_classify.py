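import numpy as np
import pytest
from sklearn.metrics.pairwise import rbf_kernel

from mfdfa2d import (
    FeatureTable,
    KernelSpec,
    accuracy_clustering,
    combination_comparison,
    htrbf_gram,
    htrbf_kernel,
    kfold_cv,
    multiclass_experiment,
    pairwise_accuracy_matrix,
    subsample_experiment,
)
from mfdfa2d.classify import _child_seed, median_bandwidth
from mfdfa2d.synthetic import make_feature_dataset


def blob_table(centers, n_per, noise=1.0, seed=0, features=("h_m3", "alpha_min", "delta_alpha")):
    """Gaussian blobs at the given centers in the named feature dims."""
    from mfdfa2d.io_surfaces import FEATURE_NAMES

    centers = np.asarray(centers, dtype=float)
    full = np.zeros((len(centers), 12))
    for d, name in enumerate(features[: centers.shape[1]]):
        full[:, FEATURE_NAMES.index(name)] = centers[:, d]
    return make_feature_dataset(
        len(centers), n_per, noise_sd=noise, seed=seed, species_centers=full
    )


class TestKernel:
    def test_self_similarity_is_one(self, rng):
        spec = KernelSpec(bandwidth=2.0, power_a=0.7, power_b=1.3)
        for _ in range(5):
            x = rng.normal(size=6) * 10
            assert htrbf_kernel(x, x, spec) == pytest.approx(1.0)

    def test_gaussian_special_case(self, rng):
        X = rng.normal(size=(12, 4))
        spec = KernelSpec(bandwidth=3.0, power_a=1.0, power_b=2.0)
        G = htrbf_gram(X, X, spec)
        assert np.allclose(G, rbf_kernel(X, gamma=1 / 3.0), atol=1e-12)
        assert np.allclose(G, G.T, atol=0)

    def test_laplacian_point_value(self):
        spec = KernelSpec(bandwidth=1.0, power_a=1.0, power_b=1.0)
        assert htrbf_kernel([0.0], [1.0], spec) == pytest.approx(np.exp(-1))

    def test_signed_power_handles_negatives(self):
        spec = KernelSpec(bandwidth=1.0, power_a=0.5, power_b=1.0)
        v = htrbf_kernel([-4.0], [1.0], spec)  # |sign(-4)*2 - 1| = 3
        assert v == pytest.approx(np.exp(-3.0))

    def test_invalid_specs_and_inputs(self):
        with pytest.raises(ValueError):
            KernelSpec(bandwidth=-1.0)
        with pytest.raises(ValueError):
            KernelSpec(power_a=0.0)
        with pytest.raises(ValueError):
            htrbf_kernel([np.nan], [0.0], KernelSpec(bandwidth=1.0))

    def test_median_bandwidth_positive(self, rng):
        X = rng.normal(size=(20, 3))
        assert median_bandwidth(X, KernelSpec()) > 0
        assert median_bandwidth(np.zeros((5, 3)), KernelSpec()) == 1.0


class TestKFoldCV:
    def test_separable_limit(self):
        t = blob_table([[0, 0], [10, 10], [-10, 10]], n_per=20, noise=1.0, seed=1)
        res = kfold_cv(t, ["h_m3", "alpha_min"], K=5, repeats=2, seed=0)
        assert res.mean_accuracy >= 0.99

    def test_determinism(self):
        t = blob_table([[0, 0], [2, 1]], n_per=15, seed=3)
        a = kfold_cv(t, ["h_m3", "alpha_min"], K=5, repeats=3, seed=42)
        b = kfold_cv(t, ["h_m3", "alpha_min"], K=5, repeats=3, seed=42)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.mean_accuracy == b.mean_accuracy

    def test_confusion_bookkeeping(self):
        t = blob_table([[0, 0], [3, 3]], n_per=20, seed=5)
        res = kfold_cv(t, ["h_m3", "alpha_min"], K=4, repeats=1, seed=0)
        assert res.confusion.sum(axis=1).tolist() == [20, 20]
        assert res.mean_accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum()
        )

    def test_chance_level_on_permuted_labels(self):
        t = make_feature_dataset(5, 20, feature_shift=0.0, seed=9)
        res = kfold_cv(t, ["h_m3", "alpha_min", "delta_alpha"], K=5, repeats=4, seed=2)
        assert res.mean_accuracy == pytest.approx(0.20, abs=0.08)

    def test_class_smaller_than_k_rejected(self):
        t = blob_table([[0, 0], [5, 5]], n_per=4, seed=0)
        with pytest.raises(ValueError, match="fewer than K"):
            kfold_cv(t, ["h_m3"], K=5)


class TestPairwise:
    def test_geometry_and_symmetry(self):
        # one far species, two overlapping ones
        t = blob_table([[0, 0], [1.0, 0], [40, 40]], n_per=20, noise=1.0, seed=4)
        A, classes = pairwise_accuracy_matrix(
            t, ["h_m3", "alpha_min"], K=5, seed=0, repeats=2
        )
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 1.0)
        assert A[0, 2] >= 0.99 and A[1, 2] >= 0.99
        assert A[0, 1] < 0.95  # overlapping pair imperfect

    def test_identical_distributions_near_chance(self):
        t = make_feature_dataset(2, 25, feature_shift=0.0, seed=11)
        A, _ = pairwise_accuracy_matrix(t, ["h_m3", "h_p2"], K=5, seed=1, repeats=4)
        assert A[0, 1] == pytest.approx(0.5, abs=0.15)


class TestClustering:
    def test_smallest_distance_merges_first(self):
        A = np.array([[1.0, 0.5, 0.99], [0.5, 1.0, 0.99], [0.99, 0.99, 1.0]])
        dend = accuracy_clustering(A, ["A", "B", "C"])
        first = dend.Z[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.5)
        text = dend.to_text()
        assert "(A,B):0.5000" in text and text.endswith(";")

    def test_all_equal_distances_deterministic(self):
        A = np.full((4, 4), 0.8)
        np.fill_diagonal(A, 1.0)
        d1 = accuracy_clustering(A)
        d2 = accuracy_clustering(A)
        assert np.array_equal(d1.Z, d2.Z)
        assert {int(d1.Z[0, 0]), int(d1.Z[0, 1])} == {0, 1}  # lowest indices first

    def test_one_minus_transform_inverts_order(self):
        A = np.array([[1.0, 0.5, 0.99], [0.5, 1.0, 0.99], [0.99, 0.99, 1.0]])
        dend = accuracy_clustering(A, ["A", "B", "C"], transform="one-minus")
        # now the EASY pair (high accuracy) is the closest
        assert {int(dend.Z[0, 0]), int(dend.Z[0, 1])} != {0, 1}

    def test_flat_cut_recovers_planted_groups(self):
        A = np.ones((5, 5))
        for i, j in [(0, 1), (2, 3)]:
            A[i, j] = A[j, i] = 0.55
        dend = accuracy_clustering(A, list("abcde"))
        cut = dend.cut(3)
        assert cut["a"] == cut["b"] and cut["c"] == cut["d"]
        assert len({cut["a"], cut["c"], cut["e"]}) == 3

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            accuracy_clustering(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            accuracy_clustering(np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3]]))


class TestExperiments:
    def test_multiclass_identities(self):
        t = blob_table([[0, 0], [12, 0], [0, 12]], n_per=12, seed=6)
        res = multiclass_experiment(t, ["h_m3", "alpha_min"], K=4, repeats=1, seed=0)
        assert np.all(res.per_class_accuracy == 1.0)
        assert res.confusion.sum(axis=1).tolist() == [12, 12, 12]
        assert res.overall_accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum()
        )

    def test_subsample_full_size_matches_plain_cv(self):
        t = blob_table([[0, 0], [3, 2]], n_per=16, seed=8)
        out = subsample_experiment(
            t, ["h_m3", "alpha_min"], K=4, n_values=[16], repeats=3, seed=5
        )
        ref = kfold_cv(t, ["h_m3", "alpha_min"], K=4, repeats=3,
                       seed=_child_seed(5, 16))
        assert out[16][0] == pytest.approx(np.mean(ref.fold_accuracies))

    def test_subsample_stability_when_separable(self):
        t = blob_table([[0, 0], [15, 15]], n_per=24, seed=2)
        out = subsample_experiment(
            t, ["h_m3", "alpha_min"], K=4, n_values=[12, 24], repeats=3, seed=1
        )
        assert abs(out[12][0] - out[24][0]) < 0.02

    def test_subsample_bounds(self):
        t = blob_table([[0, 0], [3, 2]], n_per=10, seed=0)
        with pytest.raises(ValueError):
            subsample_experiment(t, ["h_m3"], K=2, n_values=[11], seed=0)

    def test_combination_comparison(self):
        t = make_feature_dataset(
            3, 20, shifted_features=("h_m3", "alpha_min", "delta_alpha"),
            feature_shift=3.0, seed=13,
        )
        combos = [("h_m3", "alpha_min", "delta_alpha"), ("h_p1", "h_p2", "delta_f")]
        res = combination_comparison(t, combos, K_values=[5], seed=0, repeats=2)
        assert res[combos[0]][5] > res[combos[1]][5]
        with pytest.raises(ValueError, match="unknown feature"):
            combination_comparison(t, [("bogus",)], K_values=[2], seed=0)

    def test_single_combo_reduces_to_kfold(self):
        t = blob_table([[0, 0], [4, 4]], n_per=12, seed=1)
        combo = ("h_m3", "alpha_min")
        res = combination_comparison(t, [combo], K_values=[3], seed=9, repeats=2)
        ref = kfold_cv(t, list(combo), K=3, repeats=2, seed=_child_seed(9, 0, 3))
        assert res[combo][3] == ref.mean_accuracy
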