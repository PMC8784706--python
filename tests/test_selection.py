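import itertools

import numpy as np
import pandas as pd
import pytest

from etioscope.archetypes import fit_archetypes
from etioscope.preprocess import PhenotypeMatrix
from etioscope.selection import (adjusted_rand_index, assign_labels,
                                 find_minimal_parameter_set, match_archetypes,
                                 scree, stability_by_subsampling)


def make_mixture(n, k, m, noise, seed, alpha=0.5, plant_vertices=False):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(k, m)) * 2.0
    W = rng.dirichlet([alpha] * k, size=n)
    if plant_vertices:
        W[:k] = np.eye(k)
    X = W @ Z + noise * rng.standard_normal((n, m))
    return X, Z, W


class TestScree:
    def test_exact_mixture_rss_collapses_at_true_k(self):
        # planted vertices: the true profiles are attainable as data rows,
        # so k = k_true fits exactly while k-1 cannot
        X, _, _ = make_mixture(250, 4, 8, noise=0.0, seed=0,
                               plant_vertices=True)
        res = scree(X, k_range=range(3, 5), n_restarts=4, seed=1, robust=False)
        rss = dict(zip(res.k_values, res.best_rss))
        xnorm2 = float(np.sum(X * X))
        assert rss[4] < 1e-6 * xnorm2
        assert rss[3] > 100 * rss[4]

    def test_k1_equals_total_centered_sum_of_squares(self):
        # plain objective: the single archetype is the sample mean
        X, _, _ = make_mixture(100, 3, 5, noise=0.2, seed=2)
        res = scree(X, k_range=[1], n_restarts=2, seed=3, robust=False)
        tss = float(np.sum((X - X.mean(axis=0)) ** 2))
        assert res.best_rss[0] == pytest.approx(tss, rel=1e-6)

    def test_monotone_in_k_and_reproducible(self):
        X, _, _ = make_mixture(150, 3, 6, noise=0.3, seed=4)
        res = scree(X, k_range=range(1, 6), n_restarts=3, seed=5)
        rss = np.asarray(res.best_rss)
        assert np.all(np.diff(rss) <= 1e-8 * np.maximum(rss[:-1], 1.0))
        res2 = scree(X, k_range=range(1, 6), n_restarts=3, seed=5)
        np.testing.assert_array_equal(res.best_rss, res2.best_rss)


class TestMatchArchetypes:
    def test_recovers_row_permutation(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(4, 7))
        perm_true = np.array([2, 0, 3, 1])
        perm, sims = match_archetypes(Z, Z[perm_true])
        np.testing.assert_array_equal(perm, perm_true)
        np.testing.assert_allclose(sims, 1.0, atol=1e-10)

    def test_cosine_scale_invariance(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(3, 5))
        _, sims = match_archetypes(Z, 3.7 * Z)
        np.testing.assert_allclose(sims, 1.0, atol=1e-10)

    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(4, 6))
        noisy = Z[[1, 3, 0, 2]] + 0.1 * rng.normal(size=Z.shape)
        perm, _ = match_archetypes(Z, noisy)

        def norm(M):
            return M / np.linalg.norm(M, axis=1, keepdims=True)

        S = norm(noisy) @ norm(Z).T
        best = max(itertools.permutations(range(4)),
                   key=lambda p: sum(S[i, p[i]] for i in range(4)))
        np.testing.assert_array_equal(perm, np.asarray(best))

    def test_differing_k_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            match_archetypes(rng.normal(size=(3, 4)), rng.normal(size=(4, 4)))

    def test_shared_columns_restriction(self):
        rng = np.random.default_rng(10)
        Z = rng.normal(size=(3, 5))
        names = list("abcde")
        sub = ["a", "c", "e"]
        idx = [0, 2, 4]
        perm, sims = match_archetypes(Z, Z[:, idx], shared_columns=sub,
                                      ref_names=names, new_names=sub)
        np.testing.assert_array_equal(perm, [0, 1, 2])
        np.testing.assert_allclose(sims, 1.0, atol=1e-10)


class TestAssignLabels:
    def test_dominant_above_cutoff_gets_archetype(self):
        labels = assign_labels(np.array([[0.7, 0.1, 0.1, 0.1]]), 0.6)
        assert labels[0] == "A"

    def test_below_cutoff_is_mixed(self):
        labels = assign_labels(np.array([[0.4, 0.3, 0.2, 0.1]]), 0.6)
        assert labels[0] == "mixed"

    def test_threshold_zero_labels_everyone(self):
        rng = np.random.default_rng(11)
        scores = rng.dirichlet([1] * 4, size=50)
        labels = assign_labels(scores, 0.0)
        assert "mixed" not in labels
        expected = np.asarray(list("ABCD"))[scores.argmax(axis=1)]
        np.testing.assert_array_equal(labels, expected)

    def test_non_simplex_rows_rejected(self):
        with pytest.raises(ValueError):
            assign_labels(np.array([[0.9, 0.9, 0.1, 0.1]]), 0.5)


def manual_ari(a, b):
    """Pair-counting ARI from the contingency table (reference formula)."""
    from scipy.special import comb
    a, b = np.asarray(a), np.asarray(b)
    cats_a, cats_b = np.unique(a), np.unique(b)
    nij = np.array([[(np.logical_and(a == ca, b == cb)).sum()
                     for cb in cats_b] for ca in cats_a])
    sum_ij = comb(nij, 2).sum()
    sum_a = comb(nij.sum(axis=1), 2).sum()
    sum_b = comb(nij.sum(axis=0), 2).sum()
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if np.all(nij == np.diag(np.diag(nij))) else 0.0
    return (sum_ij - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        assert adjusted_rand_index([1, 1, 2, 2, 3], [1, 1, 2, 2, 3]) == 1.0

    def test_label_permutation_invariance(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_hand_computed_pair_counting_case(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_matches_pair_counting_formula_on_random_labelings(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 3, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(manual_ari(a, b),
                                                              abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 3, size=40)
        assert adjusted_rand_index(a, b) == adjusted_rand_index(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestStability:
    @pytest.fixture(scope="class")
    def structured(self):
        return make_mixture(220, 4, 10, noise=0.4, seed=14)

    def test_structured_data_is_stable(self, structured):
        X, _, _ = structured
        res = stability_by_subsampling(X, 4, replicates=8, seed=1,
                                       reference_restarts=5,
                                       replicate_restarts=3)
        assert res.median_at(0.0) > 0.7
        assert all(-1.0 <= v <= 1.0
                   for vals in res.ari_distribution.values() for v in vals)

    def test_noise_less_stable_than_structure(self, structured):
        X, _, _ = structured
        rng = np.random.default_rng(15)
        noise = rng.standard_normal(X.shape)
        stable = stability_by_subsampling(X, 4, replicates=6, seed=2,
                                          reference_restarts=4,
                                          replicate_restarts=2,
                                          thresholds=[0.0])
        unstable = stability_by_subsampling(noise, 4, replicates=6, seed=2,
                                            reference_restarts=4,
                                            replicate_restarts=2,
                                            thresholds=[0.0])
        assert unstable.median_at(0.0) < stable.median_at(0.0)

    def test_exactly_reproducible(self, structured):
        X, _, _ = structured
        kwargs = dict(replicates=4, seed=3, reference_restarts=3,
                      replicate_restarts=2, thresholds=[0.0, 0.5])
        a = stability_by_subsampling(X, 4, **kwargs)
        b = stability_by_subsampling(X, 4, **kwargs)
        assert a.ari_distribution == b.ari_distribution

    def test_full_fraction_same_seed_is_self_comparison(self, structured):
        # replicate covering (almost) all subjects refit with ample restarts
        # reproduces the reference partition
        X, _, _ = structured
        res = stability_by_subsampling(X, 4, fraction=0.999, replicates=1,
                                       seed=4, reference_restarts=5,
                                       replicate_restarts=5,
                                       thresholds=[0.0])
        assert res.ari_distribution[0.0][0] > 0.95

    def test_subsample_smaller_than_k_rejected(self, structured):
        X, _, _ = structured
        with pytest.raises(ValueError):
            stability_by_subsampling(X[:5], 4, fraction=0.5, replicates=1)


class TestMinimalParameterSet:
    def test_uncorrelated_columns_keep_full_set(self):
        X, _, _ = make_mixture(200, 3, 5, noise=0.3, seed=16)
        m = PhenotypeMatrix(values=X, column_names=[f"p{j}" for j in range(5)])
        res = find_minimal_parameter_set(m, cutoffs=[0.95], k=3, seed=0,
                                         n_restarts=3)
        assert res.satisfied
        assert res.retained_columns == m.column_names
        assert np.all(res.similarities > 0.95)

    def test_duplicated_columns_pruned_archetypes_preserved(self):
        # informative columns pairwise |r| < 0.75; duplicates |r| > 0.99
        X, _, _ = make_mixture(250, 4, 6, noise=0.8, seed=1)
        rng = np.random.default_rng(18)
        dup = X + 0.02 * rng.standard_normal(X.shape)
        Xd = np.hstack([X, dup])
        names = [f"p{j}" for j in range(6)] + [f"p{j}_dup" for j in range(6)]
        m = PhenotypeMatrix(values=Xd, column_names=names)
        res = find_minimal_parameter_set(m, cutoffs=[0.9], k=4, seed=1,
                                         n_restarts=3)
        assert res.satisfied
        assert len(res.retained_columns) == 6
        # exactly one member of each duplicate pair survives
        for j in range(6):
            assert (f"p{j}" in res.retained_columns) ^ \
                   (f"p{j}_dup" in res.retained_columns)
        assert np.all(res.similarities > 0.99)

    def test_cutoff_sweep_mirrors_decreasing_protocol(self):
        X, _, _ = make_mixture(200, 3, 8, noise=0.3, seed=19)
        m = PhenotypeMatrix(values=X, column_names=[f"p{j}" for j in range(8)])
        cutoffs = (0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)
        res = find_minimal_parameter_set(m, cutoffs=cutoffs, k=3, seed=2,
                                         n_restarts=2)
        assert set(res.per_cutoff) == set(cutoffs)
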