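"""Patient partitioning: dominance rule, DP clustering, recursion, routing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from ecgscar.partition import (
    MergedGroup,
    PartitionConfig,
    PartitionModel,
    fit_dpgmm,
    is_dominated,
    recursive_partition,
)


class TestDominance:
    def test_printed_rule_examples(self):
        assert is_dominated(10, 4, 2.0) is True    # 10 >= 2*4
        assert is_dominated(5, 4, 2.0) is False
        assert is_dominated(5, 4, 1.0) is True
        assert is_dominated(0, 0, 2.0) is True     # vacuous boundary convention

    def test_symmetry(self):
        assert is_dominated(4, 10, 2.0) is True

    @given(
        scar=st.integers(0, 1000),
        noscar=st.integers(0, 1000),
        ratio=st.floats(1.0, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ratio_one_always_dominates_and_monotone(self, scar, noscar, ratio):
        assert is_dominated(scar, noscar, 1.0)
        # dominance can only be lost, never gained, as the ratio grows
        if not is_dominated(scar, noscar, ratio):
            assert not is_dominated(scar, noscar, ratio + 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            is_dominated(-1, 2, 2.0)


def blobs(rng, n_per, d, separation, k=2):
    centers = np.zeros((k, d))
    for i in range(1, k):
        v = rng.normal(size=d)
        centers[i] = separation * v / np.linalg.norm(v)
    X = np.concatenate([rng.normal(size=(n_per, d)) + c for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestDpgmm:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X, truth = blobs(rng, 100, 20, 6.0)
        labels = fit_dpgmm(X, PartitionConfig(seed=1))
        assert len(np.unique(labels)) == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_iid_noise_yields_few_clusters(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 10))
        labels = fit_dpgmm(X, PartitionConfig(max_components=10, seed=2))
        assert len(np.unique(labels)) <= 3

    def test_degenerate_point_cloud_is_one_cluster(self):
        rng = np.random.default_rng(2)
        X = np.ones((40, 5)) + 1e-9 * rng.normal(size=(40, 5))
        labels = fit_dpgmm(X, PartitionConfig(seed=3))
        assert len(np.unique(labels)) == 1

    def test_non_finite_input_rejected(self):
        X = np.ones((20, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_dpgmm(X, PartitionConfig())

    def test_small_clusters_dissolved(self):
        rng = np.random.default_rng(3)
        X, _ = blobs(rng, 100, 10, 8.0)
        labels = fit_dpgmm(X, PartitionConfig(min_cluster_size=5, seed=4))
        _, counts = np.unique(labels, return_counts=True)
        assert (counts >= 5).all()


class TestRecursivePartition:
    def test_defaults_terminate_in_two_iterations_two_groups(self):
        """init ratio 2.0 halved once reaches 1.0, where every cluster is
        dominated, so the recursion runs at most twice and produces at most
        two merged groups."""
        rng = np.random.default_rng(4)
        for trial in range(3):
            X, cl = blobs(np.random.default_rng(trial), 80, 15, 6.0, k=3)
            y = (np.random.default_rng(100 + trial).random(X.shape[0]) < 0.45).astype(int)
            model = recursive_partition(X, y, PartitionConfig(seed=trial))
            assert model.n_iterations <= 2
            assert 1 <= model.n_groups <= 2
            # partition property: disjoint and exhaustive
            members = np.concatenate([g.members for g in model.groups])
            assert np.array_equal(np.sort(members), np.arange(X.shape[0]))

    def test_both_blobs_dominated_gives_single_group(self):
        rng = np.random.default_rng(5)
        X, cl = blobs(rng, 100, 15, 8.0)
        y = np.where(cl == 0, rng.random(200) < 0.9, rng.random(200) < 0.1).astype(int)
        model = recursive_partition(X, y, PartitionConfig(seed=6))
        assert model.n_groups == 1
        assert model.groups[0].iteration == 0
        assert model.groups[0].members.size == 200

    def test_all_one_class_gives_single_group_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 5))
        with pytest.warns(UserWarning, match="one class"):
            model = recursive_partition(X, np.zeros(50), PartitionConfig(seed=7))
        assert model.n_groups == 1

    def test_no_partitioning_ablation_yields_one_group_of_everyone(self):
        rng = np.random.default_rng(7)
        X, _ = blobs(rng, 80, 10, 6.0)
        y = (rng.random(160) < 0.5).astype(int)
        model = recursive_partition(X, y, PartitionConfig(no_partitioning=True))
        assert model.n_groups == 1
        assert model.groups[0].members.size == 160

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        X, _ = blobs(rng, 60, 10, 5.0)
        y = (rng.random(120) < 0.4).astype(int)
        m1 = recursive_partition(X, y, PartitionConfig(seed=9))
        m2 = recursive_partition(X, y, PartitionConfig(seed=9))
        assert m1.n_groups == m2.n_groups
        for g1, g2 in zip(m1.groups, m2.groups):
            assert np.array_equal(g1.members, g2.members)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PartitionConfig(init_dominance_ratio=0.5).validate()
        with pytest.raises(ValueError):
            PartitionConfig(decay=1.0).validate()


class TestAssignment:
    def _model(self, centroids):
        groups = tuple(
            MergedGroup(
                members=np.array([i]),
                centroid=np.asarray(c, float),
                iteration=0,
                dominance_ratio=2.0,
                cluster_centroids=np.asarray(c, float)[None, :],
            )
            for i, c in enumerate(centroids)
        )
        d = len(centroids[0])
        return PartitionModel(
            groups=groups,
            scale_mean=np.zeros(d),
            scale_sd=np.ones(d),
            config=PartitionConfig(),
            n_iterations=1,
        )

    def test_point_at_centroid_goes_to_that_group(self):
        model = self._model([[0.0, 0.0], [4.0, 0.0]])
        assert model.assign_group(np.array([4.0, 0.0])) == 1

    def test_equidistant_point_breaks_tie_to_lower_index(self):
        model = self._model([[0.0, 0.0], [4.0, 0.0]])
        assert model.assign_group(np.array([2.0, 0.0])) == 0

    def test_dimension_mismatch_raises(self):
        model = self._model([[0.0, 0.0]])
        with pytest.raises(ValueError, match="dimension"):
            model.assign_group(np.array([1.0, 2.0, 3.0]))

    def test_held_out_patients_route_to_planted_group(self):
        """Patients sampled from planted clusters route with >= 90% agreement
        to the merged group their cluster was pooled into."""
        rng = np.random.default_rng(9)
        d, sep = 15, 7.0
        centers = np.zeros((2, d))
        v = rng.normal(size=d)
        centers[1] = sep * v / np.linalg.norm(v)
        n_tr, n_ho = 150, 250
        X_all = np.concatenate(
            [rng.normal(size=(n_tr + n_ho, d)) + c for c in centers]
        )
        cl_all = np.repeat([0, 1], n_tr + n_ho)
        tr_mask = np.concatenate(
            [np.arange(n_tr), n_tr + n_ho + np.arange(n_tr)]
        )
        ho_mask = np.setdiff1d(np.arange(X_all.shape[0]), tr_mask)
        X, cl = X_all[tr_mask], cl_all[tr_mask]
        y = np.where(cl == 0, rng.random(2 * n_tr) < 0.8, rng.random(2 * n_tr) < 0.45).astype(int)
        model = recursive_partition(X, y, PartitionConfig(seed=10))
        assert model.n_groups == 2
        gid_of_cluster = {}
        for gid, g in enumerate(model.groups):
            for c in (0, 1):
                if np.isin(np.flatnonzero(cl == c), g.members).mean() > 0.5:
                    gid_of_cluster[c] = gid
        expected = np.array([gid_of_cluster[c] for c in cl_all[ho_mask]])
        got = model.assign_groups(X_all[ho_mask])
        assert (got == expected).mean() >= 0.90
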