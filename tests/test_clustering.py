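import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from gaitpattern import (
    distance_matrix,
    kmeans_cluster,
    loading_rates,
    merge_tree,
    select_k,
    silhouette_values,
)
from gaitpattern.errors import ParameterError


def _blobs(rng, centers, n_per, spread=0.1):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, spread, size=(n_per, len(c))))
        labels += [i] * n_per
    return np.vstack(pts), np.asarray(labels)


class TestKMeans:
    def test_two_separated_blobs_recovered(self, rng):
        X, truth = _blobs(rng, [(0, 0), (10, 10)], 8)
        res = kmeans_cluster(X, 2, seed=0, restarts=5)
        # agreement up to relabeling
        table = pd.crosstab(truth, res.assignments)
        assert (table.max(axis=1) == 8).all()

    def test_k_equals_rows_gives_zero_inertia(self, rng):
        X = rng.normal(size=(6, 3))
        res = kmeans_cluster(X, 6, seed=0, restarts=3)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert np.unique(res.assignments).size == 6

    def test_inertia_matches_exhaustive_minimum_1d(self, rng):
        X = rng.normal(size=(10, 1)) * 3
        res = kmeans_cluster(X, 2, seed=0, restarts=25)
        assert res.inertia == pytest.approx(
            oracles.exhaustive_kmeans_inertia(X, 2), rel=1e-9
        )

    def test_all_cluster_ids_used_and_one_based(self, rng):
        X = rng.normal(size=(20, 2))
        res = kmeans_cluster(X, 4, seed=1, restarts=5)
        assert set(np.unique(res.assignments)) == {1, 2, 3, 4}

    def test_k_out_of_range(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ParameterError):
            kmeans_cluster(X, 1)
        with pytest.raises(ParameterError):
            kmeans_cluster(X, 6)

    def test_restarts_never_worsen_inertia(self, rng):
        X = rng.normal(size=(30, 2))
        inertias = [
            kmeans_cluster(X, 5, seed=3, restarts=r).inertia for r in (1, 5, 15)
        ]
        assert inertias[0] >= inertias[1] >= inertias[2]


class TestSilhouette:
    def test_tight_distant_blobs_score_high(self, rng):
        X, labels = _blobs(rng, [(0, 0), (50, 50)], 6)
        _, mean_sil = silhouette_values(X, labels)
        assert mean_sil > 0.9

    def test_misassigned_points_get_negative_values(self, rng):
        X, labels = _blobs(rng, [(0, 0), (50, 50)], 6)
        swapped = labels.copy()
        swapped[0], swapped[6] = labels[6], labels[0]
        sil, _ = silhouette_values(X, swapped)
        assert sil[0] < 0 and sil[6] < 0

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array([0, 0, 1, 1, 1, 0])
        sil, mean_sil = silhouette_values(X, labels)
        expected = oracles.silhouette_direct(X, labels)
        assert np.allclose(sil, expected)
        assert mean_sil == pytest.approx(expected.mean())

    def test_singleton_only_clustering_is_zero_with_warning(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.warns(UserWarning, match="silhouette undefined"):
            sil, mean_sil = silhouette_values(X, np.arange(4))
        assert np.allclose(sil, 0.0) and mean_sil == 0.0


class TestSelectK:
    def test_three_blobs_majority_over_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, _ = _blobs(rng, [(0, 0), (10, 0), (0, 10)], 7, spread=0.5)
            best_k, _ = select_k(X, range(2, 7), seed=seed, restarts=10)
            hits += best_k == 3
        assert hits >= 8

    def test_single_blob_warns_of_weak_structure(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            best_k, scores = select_k(X, range(2, 6), seed=0, restarts=5)
        assert max(scores.values()) < 0.6

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ParameterError):
            select_k(rng.normal(size=(10, 2)), [])

    def test_recovers_subject_count_on_synthetic_cohorts(self):
        # strong subject signature, no condition effect: the silhouette scan
        # over 2..n_subjects+5 should land within +-2 of the subject count
        from gaitpattern import SynthConfig, build_feature_matrix, generate_cohort, standardize

        hits = 0
        for seed in range(5):
            cfg = SynthConfig(
                n_subjects=6, n_trials=3, n_time=101, delta_cond=0.0, seed=seed
            )
            trials, _ = generate_cohort(cfg)
            fm_std, _ = standardize(build_feature_matrix(trials, n_time=cfg.n_time))
            best_k, _ = select_k(fm_std, range(2, 12), seed=seed, restarts=10)
            hits += abs(best_k - 6) <= 2
        assert hits >= 4


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        D = distance_matrix(rng.normal(size=(7, 3)))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_unit_difference_in_one_column(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert distance_matrix(X)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(5, 4))
        D = distance_matrix(X)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(np.linalg.norm(X[i] - X[j]))


class TestMergeTree:
    def test_collinear_points_merge_closest_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        tree = merge_tree(X)
        first = set(tree.linkage_matrix[0, :2].astype(int))
        assert first == {0, 1}

    def test_heights_nondecreasing(self, rng):
        tree = merge_tree(rng.normal(size=(12, 3)))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    @pytest.mark.parametrize("rule", ["ward", "single"])
    def test_matches_naive_agglomeration(self, rng, rule):
        X = rng.normal(size=(6, 2))
        tree = merge_tree(X, linkage_rule=rule)
        expected = oracles.naive_linkage(X, rule)
        assert np.allclose(tree.linkage_matrix[:, 2], expected[:, 2])
        for row, exp in zip(tree.linkage_matrix, expected):
            assert set(row[:2].astype(int)) == set(exp[:2].astype(int))

    def test_newick_export_has_all_leaves(self, rng):
        tree = merge_tree(rng.normal(size=(5, 2)))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        assert all(f"row{i}" in nwk for i in range(5))


class TestLoadingRates:
    @staticmethod
    def _labels(subjects, conditions, sides):
        return pd.DataFrame(
            {"subject": subjects, "condition": conditions, "side": sides,
             "trial": range(len(subjects))}
        )

    def test_fully_loaded_subject_has_rate_one(self):
        labels = self._labels(["s1"] * 40, ["N"] * 40, ["L"] * 40)
        table = loading_rates(np.ones(40, dtype=int), labels, "subject")
        assert table.max_rate["s1"] == 1.0
        assert table.n_groups_at_one == 1

    def test_three_one_split(self):
        labels = self._labels(["s1"] * 4, ["N"] * 4, ["L"] * 4)
        table = loading_rates(np.array([1, 1, 1, 2]), labels, "subject")
        assert sorted(table.rates.loc["s1"]) == [0.25, 0.75]
        assert table.max_rate["s1"] == 0.75

    def test_rates_sum_to_one_per_group(self, rng):
        n = 60
        labels = self._labels(
            rng.choice(["a", "b", "c"], n),
            rng.choice(["N", "C"], n),
            rng.choice(["L", "R"], n),
        )
        assignments = rng.integers(1, 5, n)
        for grouping in ("subject", "condition", "subject_condition_side"):
            table = loading_rates(assignments, labels, grouping)
            assert np.allclose(table.rates.sum(axis=1), 1.0)

    def test_unknown_grouping_rejected(self):
        labels = self._labels(["s1"], ["N"], ["L"])
        with pytest.raises(ParameterError):
            loading_rates(np.array([1]), labels, "side")
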