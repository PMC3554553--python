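"""Unit and property tests for the MoRF core: component functions, distance
statistics, neighbour kernels and the generic weight-update engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import morf
from morf import (
    ConfigError,
    DataError,
    GenotypeDataset,
    NeighborKernel,
    class_comparator,
    diff_allelic,
    diff_genetic_model,
    distance_stats,
    hamming_distance,
    kernel_relieff,
    kernel_surf,
    kernel_surf_star,
    kernel_swrf_star,
    morf_weights,
    pairwise_distances,
    taxicab_distance,
)

from _oracles import naive_morf_weights

KERNELS = ("relieff", "surf", "surf_star", "swrf_star")


class TestComponentFunctions:
    @pytest.mark.parametrize(
        "li, lj, expected", [(0, 0, -1), (0, 1, 1), (1, 0, 1), (1, 1, -1)]
    )
    def test_class_comparator_hit_miss_sign(self, li, lj, expected):
        assert class_comparator(li, lj) == expected

    def test_class_comparator_rejects_nonbinary_label(self):
        with pytest.raises(DataError):
            class_comparator(0, 2)

    @pytest.mark.parametrize(
        "vi, vj, expected", [(1, 1, 0), (0, 2, 1), (2, 2, 0), (0, 1, 1)]
    )
    def test_diff_allelic_match_mismatch(self, vi, vj, expected):
        assert diff_allelic(vi, vj) == expected

    def test_diff_allelic_rejects_bad_genotype(self):
        with pytest.raises(DataError):
            diff_allelic(3, 0)

    @pytest.mark.parametrize(
        "vi, vj, model, expected",
        [
            (1, 2, "dominant", 0),   # both carry at least one minor allele
            (0, 1, "dominant", 1),
            (1, 2, "recessive", 1),  # only the homozygote is a carrier
            (2, 2, "recessive", 0),
            (1, 1, "heterozygote", 0),
            (1, 0, "heterozygote", 1),
            (0, 2, "heterozygote", 0),  # neither is heterozygous
        ],
    )
    def test_diff_genetic_model_collapse(self, vi, vj, model, expected):
        assert diff_genetic_model(vi, vj, model) == expected

    def test_diff_genetic_model_unknown_model(self):
        with pytest.raises(ConfigError):
            diff_genetic_model(0, 1, "additive")

    @pytest.mark.parametrize(
        "x, y, expected",
        [([0, 1, 2], [0, 1, 2], 0), ([0, 1, 2], [1, 1, 0], 2), ([0, 0], [2, 1], 2)],
    )
    def test_hamming_distance(self, x, y, expected):
        assert hamming_distance(x, y) == expected

    @pytest.mark.parametrize(
        "x, y, expected",
        [([0, 1, 2], [0, 1, 2], 0), ([0, 1, 2], [1, 1, 0], 3), ([0, 0], [2, 2], 4)],
    )
    def test_taxicab_distance(self, x, y, expected):
        assert taxicab_distance(x, y) == expected

    def test_distance_length_mismatch(self):
        with pytest.raises(DataError):
            hamming_distance([0, 1], [0, 1, 2])
        with pytest.raises(DataError):
            taxicab_distance([0, 1], [0, 1, 2])


class TestDistances:
    @pytest.mark.parametrize("metric", ["hamming", "taxicab"])
    def test_pairwise_matches_scalar_recomputation(self, make_dataset, metric):
        ds = make_dataset(n=10, a=8, seed=3)
        D = pairwise_distances(ds, metric)
        scalar = hamming_distance if metric == "hamming" else taxicab_distance
        assert D.shape == (10, 10)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)
        for i in range(10):
            for j in range(10):
                assert D[i, j] == scalar(ds.genotypes[i], ds.genotypes[j])

    def test_two_sample_hamming(self):
        ds = GenotypeDataset([[0], [1]], [0, 1])
        assert pairwise_distances(ds, "hamming").tolist() == [[0, 1], [1, 0]]

    def test_distance_stats_three_pairs(self):
        # distances {d12=1, d13=3, d23=2}: mean 2, population sd sqrt(2/3)
        D = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        t, u = distance_stats(D)
        assert t == pytest.approx(2.0)
        assert u == pytest.approx(math.sqrt(2 / 3))

    def test_distance_stats_degenerate(self):
        t, u = distance_stats(np.array([[0, 5], [5, 0]]))
        assert (t, u) == (5.0, 0.0)
        D = np.full((4, 4), 7)
        np.fill_diagonal(D, 0)
        assert distance_stats(D) == (7.0, 0.0)
        with pytest.raises(DataError):
            distance_stats(np.zeros((1, 1)))


class TestKernels:
    def test_relieff_step_at_thresholds(self):
        assert kernel_relieff(3, True, t_hit=3, t_miss=5) == 1
        assert kernel_relieff(4, True, t_hit=3, t_miss=5) == 0
        assert kernel_relieff(0, False, t_hit=3, t_miss=2) == 1

    def test_surf_inclusive_boundary(self):
        assert kernel_surf(4.0, 4.0) == 1
        assert kernel_surf(5.0, 4.0) == 0
        assert kernel_surf(0.0, 4.0) == 1

    def test_surf_star_signed_step(self):
        assert kernel_surf_star(4.0, 4.0) == 1
        assert kernel_surf_star(5.0, 4.0) == -1
        assert kernel_surf_star(0.0, 4.0) == 1

    def test_swrf_star_center_and_one_sigma(self):
        t, u = 10.0, 2.5
        assert kernel_swrf_star(t, t, u) == pytest.approx(0.0)
        # one width below/above the center: 2/(1+e^-4) - 1
        assert kernel_swrf_star(t - u, t, u, 4) == pytest.approx(0.9640276, abs=1e-7)
        assert kernel_swrf_star(t + u, t, u, 4) == pytest.approx(-0.9640276, abs=1e-7)

    def test_swrf_star_invalid_parameters(self):
        with pytest.raises(ConfigError):
            kernel_swrf_star(1.0, 1.0, 0.0)
        with pytest.raises(ConfigError):
            kernel_swrf_star(1.0, 1.0, 1.0, scale=-2)
        with pytest.raises(DataError):
            kernel_swrf_star(-1.0, 1.0, 1.0)

    @given(
        offsets=st.lists(
            st.integers(-2000, 2000), min_size=2, max_size=20, unique=True
        ),
        t=st.floats(50, 100),
        u=st.floats(1, 10),
        scale=st.floats(0.5, 8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swrf_star_strictly_decreasing_and_bounded(self, offsets, t, u, scale):
        # distances within +-20 sigmoid widths of the center, where the
        # float image of the sigmoid is still strictly monotone
        dists = sorted(max(0.0, t - (k / 100) * (u / scale)) for k in offsets)
        values = [kernel_swrf_star(d, t, u, scale) for d in dists]
        assert all(-1 < v < 1 for v in values)
        assert all(
            a > b for a, b, da, db in zip(values, values[1:], dists, dists[1:])
            if da != db
        )


class TestMorfWeights:
    def test_two_sample_near_miss_gives_full_weight(self):
        ds = GenotypeDataset([[0], [1]], [0, 1])
        w = morf_weights(ds, NeighborKernel("surf_star", t=1.0))
        assert w.weights.tolist() == [1.0]

    def test_two_sample_near_hit_gives_negative_weight(self):
        with pytest.warns(UserWarning, match="single class"):
            ds = GenotypeDataset([[0], [1]], [0, 0])
            w = morf_weights(ds, NeighborKernel("surf_star", t=1.0))
        assert w.weights.tolist() == [-1.0]

    def test_constant_attribute_weight_zero(self, make_dataset):
        ds = make_dataset(n=14, a=5, seed=9)
        X = ds.genotypes.copy()
        X[:, 2] = 1
        ds = GenotypeDataset(X, ds.labels)
        for kind in KERNELS:
            w = morf_weights(ds, NeighborKernel(kind, k=3))
            assert w.weights[2] == 0.0

    def test_empty_sample_set_rejected(self, make_dataset):
        with pytest.raises(ConfigError):
            morf_weights(make_dataset(), NeighborKernel("surf"), sample_set=[])

    @pytest.mark.parametrize("kind", KERNELS)
    @pytest.mark.parametrize("diff_model", ["allelic", "dominant", "recessive"])
    def test_matches_naive_triple_loop(self, make_dataset, kind, diff_model):
        for seed in range(5):
            ds = make_dataset(n=11, a=7, seed=seed)
            got = morf_weights(ds, NeighborKernel(kind, k=3), diff_model=diff_model)
            want = naive_morf_weights(
                ds.genotypes.tolist(), ds.labels.tolist(), kind, k=3,
                diff_model=diff_model,
            )
            np.testing.assert_allclose(got.weights, want, atol=1e-12)

    @pytest.mark.parametrize("kind", KERNELS)
    def test_label_flip_invariance(self, make_dataset, kind):
        ds = make_dataset(n=12, a=6, seed=4)
        flipped = GenotypeDataset(ds.genotypes, 1 - ds.labels)
        w1 = morf_weights(ds, NeighborKernel(kind, k=3))
        w2 = morf_weights(flipped, NeighborKernel(kind, k=3))
        np.testing.assert_allclose(w1.weights, w2.weights, atol=1e-15)

    @pytest.mark.parametrize("kind", KERNELS)
    def test_attribute_permutation_equivariance(self, make_dataset, rng, kind):
        ds = make_dataset(n=12, a=6, seed=5)
        perm = rng.permutation(ds.n_attributes)
        permuted = GenotypeDataset(
            ds.genotypes[:, perm], ds.labels,
            attribute_names=[ds.attribute_names[i] for i in perm],
        )
        w1 = morf_weights(ds, NeighborKernel(kind, k=3))
        w2 = morf_weights(permuted, NeighborKernel(kind, k=3))
        np.testing.assert_allclose(w2.weights, w1.weights[perm], atol=1e-15)

    @pytest.mark.parametrize("kind", KERNELS)
    def test_sample_order_invariance(self, make_dataset, rng, kind):
        ds = make_dataset(n=13, a=5, seed=6)
        perm = rng.permutation(ds.n_samples)
        shuffled = GenotypeDataset(ds.genotypes[perm], ds.labels[perm])
        w1 = morf_weights(ds, NeighborKernel(kind, k=3))
        w2 = morf_weights(shuffled, NeighborKernel(kind, k=3))
        np.testing.assert_allclose(w1.weights, w2.weights, atol=1e-12)

    @given(seed=st.integers(0, 10_000), kind=st.sampled_from(KERNELS))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_weights_always_bounded(self, seed, kind):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        a = int(rng.integers(1, 10))
        X = rng.integers(0, 3, size=(n, a))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        ds = GenotypeDataset(X, y)
        w = morf_weights(ds, NeighborKernel(kind, k=int(rng.integers(1, 6))))
        assert np.all(w.weights >= -1) and np.all(w.weights <= 1)

    def test_swrf_star_limit_matches_surf_star(self, make_dataset):
        # with a huge scale the sigmoid hardens into the signed step,
        # provided no pairwise distance sits exactly at the threshold t
        for seed in range(5):
            ds = make_dataset(n=12, a=9, seed=seed)
            D = pairwise_distances(ds)
            t, u = distance_stats(D)
            if np.any(np.isclose(D[np.triu_indices(12, 1)], t)):
                continue
            w_sig = morf_weights(ds, NeighborKernel("swrf_star", scale=1e6))
            w_step = morf_weights(ds, NeighborKernel("surf_star"))
            np.testing.assert_allclose(w_sig.weights, w_step.weights, atol=1e-9)


class TestDatasetValidation:
    def test_rejects_out_of_domain_genotype(self):
        with pytest.raises(DataError, match="attribute 1"):
            GenotypeDataset([[0, 3], [1, 1]], [0, 1])

    def test_rejects_nonbinary_labels(self):
        with pytest.raises(DataError, match="label"):
            GenotypeDataset([[0], [1]], [0, 2])

    def test_rejects_duplicate_attribute_names(self):
        with pytest.raises(DataError, match="unique"):
            GenotypeDataset([[0, 1], [1, 0]], [0, 1], attribute_names=["A", "A"])

    def test_weight_vector_bounds(self):
        with pytest.raises(DataError):
            morf.WeightVector([1.5], ["A"])
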