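import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from peakmine import (
    PeakTable,
    cluster_members_detail,
    cluster_trajectories,
    farthest_first_cluster,
    kmeans_cluster,
    kmedoids_cluster,
    profile_matrix,
    som_cluster,
)
from peakmine.clustering import ordered_samples
from conftest import make_separated_profiles


def purity(labels_pred, labels_true):
    total = 0
    for c in set(labels_pred):
        members = labels_true[labels_pred == c]
        total += np.bincount(members).max()
    return total / len(labels_true)


class TestProfileMatrix:
    def test_rows_zscored(self, toy_table):
        prof = profile_matrix(toy_table, standardize=True)
        assert np.allclose(prof.values.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(prof.values.std(axis=1), 1, atol=1e-12)

    def test_constant_row_flagged_and_zeroed(self):
        t = PeakTable(["a", "b"], ["s1", "s2", "s3"],
                      np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
        prof = profile_matrix(t, standardize=True)
        assert prof.constant_rows.tolist() == [False, True]
        assert np.all(prof.values[1] == 0.0)

    def test_standardize_off_is_identity(self, toy_table):
        prof = profile_matrix(toy_table, standardize=False)
        assert np.array_equal(prof.values, toy_table.values)


class TestKMeans:
    def test_planted_recovery_ari_one(self):
        x, labels = make_separated_profiles(3, 15, 12, seed=0)
        model = kmeans_cluster(x, 3, seed=1)
        assert adjusted_rand_score(labels, model.labels([str(i) for i in range(len(x))])) == 1.0

    def test_k_one_centroid_is_column_mean(self):
        x, _ = make_separated_profiles(2, 5, 6, seed=1)
        model = kmeans_cluster(x, 1, seed=0)
        assert model.k == 1
        assert np.allclose(model.centers[0], x.mean(axis=0))

    def test_k_equals_m(self):
        x, _ = make_separated_profiles(2, 3, 5, seed=2)
        model = kmeans_cluster(x, len(x), seed=0)
        assert sorted(model.assignment.values()) == list(range(1, len(x) + 1))

    def test_inertia_non_increasing(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((60, 8))
        model = kmeans_cluster(x, 4, seed=3)
        inertia = model.info["inertia"]
        assert all(b <= a + 1e-9 for a, b in zip(inertia, inertia[1:]))

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 6))
        assert kmeans_cluster(x, 3, seed=8).assignment == kmeans_cluster(x, 3, seed=8).assignment

    def test_k_out_of_range(self):
        x = np.zeros((4, 3))
        with pytest.raises(ValueError):
            kmeans_cluster(x, 5)


class TestKMedoids:
    def test_planted_recovery_ari_one(self):
        x, labels = make_separated_profiles(3, 12, 10, seed=6)
        model = kmedoids_cluster(x, 3)
        assert adjusted_rand_score(labels, model.labels([str(i) for i in range(len(x))])) == 1.0

    def test_k1_medoid_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for m in (5, 9, 12):
            x = rng.standard_normal((m, 4))
            model = kmedoids_cluster(x, 1)
            dist = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            best = int(np.argmin(dist.sum(axis=1)))
            assert model.medoid_ids == [str(best)]

    def test_medoids_are_input_rows(self):
        x, _ = make_separated_profiles(2, 6, 5, seed=8)
        model = kmedoids_cluster(x, 2)
        for center in model.centers:
            assert any(np.array_equal(center, row) for row in x)

    def test_k_equals_m_identity(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((6, 3))
        model = kmedoids_cluster(x, 6)
        assert sorted(model.assignment.values()) == list(range(1, 7))


class TestFarthestFirst:
    def test_one_dimensional_hand_case(self):
        x = np.array([[0.0], [1.0], [10.0]])
        model = farthest_first_cluster(x, 2, first_center=0)
        assert model.info["center_indices"] == [0, 2]

    def test_k1_single_cluster(self):
        x = np.random.default_rng(0).standard_normal((7, 3))
        model = farthest_first_cluster(x, 1, seed=1)
        assert set(model.assignment.values()) == {1}

    def test_planted_groups_one_center_each(self):
        x, labels = make_separated_profiles(3, 10, 8, seed=10, separation=20.0)
        for seed in range(5):
            model = farthest_first_cluster(x, 3, seed=seed)
            centers = model.info["center_indices"]
            assert sorted(labels[centers]) == [0, 1, 2]
            preds = model.labels([str(i) for i in range(len(x))])
            assert adjusted_rand_score(labels, preds) == 1.0

    def test_k2_matches_bruteforce_when_seeded_at_optimum(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((9, 2))
        dist = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        # exact 2-center: minimize max distance to nearest center
        best_cost, best_pair = min(
            (dist[:, list(pair)].min(axis=1).max(), pair)
            for pair in itertools.combinations(range(9), 2)
        )
        model = farthest_first_cluster(x, 2, first_center=best_pair[0])
        got = model.info["center_indices"]
        got_cost = dist[:, got].min(axis=1).max()
        # greedy from the optimal first center is within the 2x bound, and on
        # small instances typically reproduces the optimum
        assert got_cost <= 2 * best_cost + 1e-12


class TestSOM:
    def test_planted_purity(self):
        x, labels = make_separated_profiles(3, 20, 10, seed=12)
        model = som_cluster(x, 3, 3, seed=0)
        preds = model.labels([str(i) for i in range(len(x))])
        assert purity(preds, labels) >= 0.9

    def test_1x1_grid_single_cluster(self):
        x, _ = make_separated_profiles(2, 5, 6, seed=13)
        model = som_cluster(x, 1, 1, seed=0)
        assert model.k == 1

    def test_identical_rows_map_to_one_unit(self):
        x = np.tile([1.0, 2.0, 3.0], (8, 1))
        model = som_cluster(x, 3, 3, seed=1)
        assert model.k == 1

    def test_deterministic_per_seed(self):
        x, _ = make_separated_profiles(3, 8, 6, seed=14)
        a = som_cluster(x, 3, 3, seed=4)
        b = som_cluster(x, 3, 3, seed=4)
        assert a.assignment == b.assignment
        assert np.array_equal(a.centers, b.centers)

    def test_cluster_count_is_data_driven(self):
        x, _ = make_separated_profiles(2, 15, 8, seed=15)
        model = som_cluster(x, 3, 3, seed=2)
        assert model.k <= 9


class TestPartitionInvariant:
    @pytest.mark.parametrize("algo", ["kmeans", "kmedoids", "farthest_first", "som"])
    def test_total_partition(self, algo, cohort_fixture):
        table, _, _ = cohort_fixture
        prof = profile_matrix(table)
        if algo == "kmeans":
            model = kmeans_cluster(prof, 4, seed=0)
        elif algo == "kmedoids":
            model = kmedoids_cluster(prof, 4, seed=0)
        elif algo == "farthest_first":
            model = farthest_first_cluster(prof, 4, seed=0)
        else:
            model = som_cluster(prof, 2, 2, seed=0)
        assert sorted(model.assignment) == sorted(table.molecule_ids)
        used = sorted(set(model.assignment.values()))
        assert used == list(range(1, model.k + 1))  # contiguous from 1, none empty


class TestTrajectories:
    def make_model_and_table(self, toy_metadata):
        table = PeakTable(
            ["m1", "m2", "m3"],
            ["C01", "C02", "T01", "T02"],
            np.array([[1.0, 3.0, 1.0, 3.0], [3.0, 5.0, 3.0, 5.0], [9.0, 9.0, 9.0, 9.0]]),
        )
        from peakmine.clustering import ClusterModel

        model = ClusterModel(
            "kmeans", {"m1": 1, "m2": 1, "m3": 2}, 2,
            np.zeros((2, 4)), None, False, 0,
        )
        return model, table, toy_metadata

    def test_average_aggregate(self, toy_metadata):
        model, table, meta = self.make_model_and_table(toy_metadata)
        traj = cluster_trajectories(model, table, meta, "average")
        # order: time 0 -> C01, T01; time 2 -> C02, T02
        assert traj.sample_order == ["C01", "T01", "C02", "T02"]
        assert traj.trajectories[1].tolist() == [2.0, 2.0, 4.0, 4.0]

    def test_max_and_min_aggregates(self, toy_metadata):
        model, table, meta = self.make_model_and_table(toy_metadata)
        assert cluster_trajectories(model, table, meta, "max").trajectories[1].tolist() == [3.0, 3.0, 5.0, 5.0]
        assert cluster_trajectories(model, table, meta, "min").trajectories[1].tolist() == [1.0, 1.0, 3.0, 3.0]

    def test_singleton_cluster_equals_profile(self, toy_metadata):
        model, table, meta = self.make_model_and_table(toy_metadata)
        traj = cluster_trajectories(model, table, meta)
        assert traj.trajectories[2].tolist() == [9.0] * 4

    def test_unknown_aggregate(self, toy_metadata):
        model, table, meta = self.make_model_and_table(toy_metadata)
        with pytest.raises(ValueError):
            cluster_trajectories(model, table, meta, "median")

    def test_sample_order_time_then_alpha(self, cohort_fixture):
        table, meta, _ = cohort_fixture
        order = ordered_samples(meta)
        times = [meta.time_of(s) for s in order]
        assert times == sorted(times)
        for t in set(times):
            block = [s for s in order if meta.time_of(s) == t]
            assert block == sorted(block)

    def test_members_detail(self, toy_metadata):
        model, table, meta = self.make_model_and_table(toy_metadata)
        detail = cluster_members_detail(model, 1, table, meta)
        assert sorted(detail.index) == ["m1", "m2"]
        assert list(detail.columns) == ["C01", "T01", "C02", "T02"]
        with pytest.raises(IndexError):
            cluster_members_detail(model, 3, table)

    def test_member_counts_sum_to_m(self, cohort_fixture):
        table, meta, _ = cohort_fixture
        model = kmeans_cluster(profile_matrix(table), 5, seed=2)
        traj = cluster_trajectories(model, table, meta)
        assert sum(len(v) for v in traj.members.values()) == table.n_molecules
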