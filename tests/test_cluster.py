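import math

import numpy as np
import pytest
from scipy import stats

from hepflow.cluster import (
    AdjacencyGraph,
    build_adjacency,
    cluster_permutation_test,
    cluster_summary,
    form_clusters,
    independent_t_map,
    paired_t_map,
)
from hepflow.montage import MontageLayout
from oracles import brute_force_clusters, brute_force_paired_p


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


class TestAdjacency:
    def test_three_channel_triangle(self):
        mont = MontageLayout(
            ("a", "b", "c"),
            np.array(
                [[0.0, 0.0, 1.0], [0.6, 0.0, 0.8], [0.0, 0.6, 0.8]]
            )
            / np.linalg.norm([[0, 0, 1.0], [0.6, 0, 0.8], [0, 0.6, 0.8]], axis=1)[
                :, None
            ],
        )
        adj = build_adjacency(mont, augment_radius=None)
        assert all(len(adj.neighbors(lb)) == 2 for lb in mont.labels)

    def test_zero_prune_cutoff_empties_delaunay_edges(self, montage):
        adj = build_adjacency(montage, prune_cutoff=0.0, augment_radius=None)
        assert adj.mean_degree == 0.0

    def test_default_mean_degree_near_five_point_six(self, adjacency):
        assert 4.5 <= adjacency.mean_degree <= 6.5
        assert adjacency.mean_degree == pytest.approx(5.6, abs=0.1)

    def test_symmetric_no_self_loops(self, adjacency):
        m = adjacency.matrix
        assert np.array_equal(m, m.T)
        assert not np.any(np.diag(m))

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((2, 2), dtype=bool)
        m[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencyGraph(("a", "b"), m)


# ---------------------------------------------------------------------------
# pointwise t
# ---------------------------------------------------------------------------


class TestPointwiseT:
    def test_paired_hand_computed(self):
        diffs = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        t, df = paired_t_map(diffs)
        assert df == 2
        assert t[0, 0] == pytest.approx(2.0 / (1.0 / math.sqrt(3)))
        assert t[0, 0] == pytest.approx(3.464, abs=1e-3)

    def test_identical_groups_give_zero(self, rng):
        a = rng.standard_normal((5, 2, 3))
        t, df = independent_t_map(a, a.copy())
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert df == 8

    def test_matches_scipy_on_random_data(self, rng):
        diffs = rng.standard_normal((8, 4, 6))
        t, _ = paired_t_map(diffs)
        expected = stats.ttest_1samp(diffs, 0.0, axis=0).statistic
        np.testing.assert_allclose(t, expected, atol=1e-10)

        a, b = rng.standard_normal((5, 4, 6)), rng.standard_normal((7, 4, 6))
        t2, _ = independent_t_map(a, b)
        expected2 = stats.ttest_ind(a, b, axis=0).statistic
        np.testing.assert_allclose(t2, expected2, atol=1e-10)

    def test_zero_variance_gives_infinite_sentinel(self):
        diffs = np.ones((4, 1, 1))
        t, _ = paired_t_map(diffs)
        assert np.isinf(t[0, 0])


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------


def _line_adjacency(n):
    m = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = True
    return AdjacencyGraph(tuple(f"ch{i}" for i in range(n)), m)


class TestFormClusters:
    def test_subthreshold_map_has_no_clusters(self):
        t_map = np.full((3, 5), 0.5)
        assert form_clusters(t_map, 10, _line_adjacency(3)) == []

    def test_consecutive_times_merge_and_sum_mass(self):
        t_map = np.zeros((3, 5))
        t_map[1, 2] = 3.0
        t_map[1, 3] = 4.0
        clusters = form_clusters(t_map, 30, _line_adjacency(3))
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(7.0)
        assert set(clusters[0].members) == {(1, 2), (1, 3)}

    def test_neighboring_channels_same_time_merge(self):
        t_map = np.zeros((3, 5))
        t_map[0, 2] = 3.0
        t_map[1, 2] = 3.0
        clusters = form_clusters(t_map, 30, _line_adjacency(3))
        assert len(clusters) == 1

    def test_non_neighbor_channels_stay_separate(self):
        t_map = np.zeros((3, 5))
        t_map[0, 2] = 3.0
        t_map[2, 2] = 3.0  # ch0 and ch2 not adjacent in a line graph
        clusters = form_clusters(t_map, 30, _line_adjacency(3))
        assert len(clusters) == 2

    def test_opposite_signs_split(self):
        t_map = np.zeros((3, 5))
        t_map[1, 2] = 3.0
        t_map[1, 3] = -3.0
        clusters = form_clusters(t_map, 30, _line_adjacency(3))
        assert len(clusters) == 2
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_agrees_with_bruteforce_on_random_maps(self, rng, adjacency):
        for _ in range(10):
            t_map = rng.standard_normal((23, 12)) * 2.0
            threshold = float(stats.t.ppf(0.975, 19))
            mine = form_clusters(t_map, 19, adjacency)
            ref = brute_force_clusters(t_map, threshold, adjacency.matrix)
            assert {frozenset(c.members) for c in mine} == {m for m, _ in ref}


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


class TestPermutationTest:
    def test_smallest_attainable_p_is_one_over_n_plus_one(self, rng, adjacency):
        data = rng.standard_normal((30, 23, 8))
        data[:, 0, :] += 2.0  # overwhelming effect
        res = cluster_permutation_test(data, adjacency, n_permutations=1000,
                                       seed=0)
        assert not res.exhaustive
        best = min(c.p_mc for c in res.clusters)
        assert best == pytest.approx(1.0 / 1001.0)

    def test_exhaustive_mode_for_five_subjects(self, rng, adjacency):
        data = rng.standard_normal((5, 23, 6))
        res = cluster_permutation_test(data, adjacency, n_permutations=1000,
                                       seed=0)
        assert res.exhaustive
        assert res.n_permutations == 32

    def test_exhaustive_p_equals_bruteforce_enumeration(self, rng, adjacency):
        data = rng.standard_normal((5, 23, 6))
        data[:, :5, 2:4] += 1.2
        res = cluster_permutation_test(data, adjacency, n_permutations=1000,
                                       seed=0)
        ref = brute_force_paired_p(data, res.threshold, adjacency.matrix)
        ref_by_members = {members: p for members, _, p in ref}
        assert len(res.clusters) == len(ref)
        for cl in res.clusters:
            assert cl.p_mc == ref_by_members[frozenset(cl.members)]

    def test_invariant_to_subject_ordering(self, rng, adjacency):
        data = rng.standard_normal((6, 23, 5))
        res_a = cluster_permutation_test(data, adjacency, seed=3)
        res_b = cluster_permutation_test(data[::-1], adjacency, seed=3)
        assert [c.p_mc for c in res_a.clusters] == [
            c.p_mc for c in res_b.clusters
        ]

    def test_seeded_runs_reproducible(self, rng, adjacency):
        data = rng.standard_normal((12, 23, 6))
        res_a = cluster_permutation_test(data, adjacency, seed=11)
        res_b = cluster_permutation_test(data, adjacency, seed=11)
        np.testing.assert_array_equal(res_a.null_max_pos, res_b.null_max_pos)
        assert [c.p_mc for c in res_a.clusters] == [
            c.p_mc for c in res_b.clusters
        ]

    def test_independent_design_exhaustive_small_groups(self, rng, adjacency):
        a = rng.standard_normal((3, 23, 4))
        b = rng.standard_normal((3, 23, 4)) + 0.5
        res = cluster_permutation_test(
            (a, b), adjacency, design="independent", n_permutations=1000,
            seed=0,
        )
        assert res.exhaustive
        assert res.n_permutations == math.comb(6, 3)

    def test_matches_mne_observed_clusters(self, rng, adjacency):
        """Observed t-map clustering agrees with the mne implementation."""
        mne = pytest.importorskip("mne")
        from scipy import sparse

        data = rng.standard_normal((15, 23, 10))
        data[:, :4, 3:6] += 0.8
        res = cluster_permutation_test(data, adjacency, n_permutations=200,
                                       seed=0)
        t_obs, clusters, _, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            np.transpose(data, (0, 2, 1)),
            threshold=res.threshold,
            n_permutations=100,
            adjacency=sparse.coo_matrix(adjacency.matrix.astype(int)),
            tail=0,
            out_type="mask",
            seed=0,
            verbose="error",
        )
        mne_masses = sorted(float(t_obs[m].sum()) for m in clusters)
        mine = sorted(c.mass for c in res.clusters)
        np.testing.assert_allclose(mine, mne_masses, atol=1e-8)


class TestClusterSummary:
    def test_paired_effect_size_convention(self, rng, adjacency):
        data = rng.standard_normal((10, 23, 6))
        data[:, 2, 2] += 3.0
        res = cluster_permutation_test(data, adjacency, n_permutations=200,
                                       seed=0)
        summaries = cluster_summary(res, data, "paired")
        top = summaries[0]
        assert top["d"] == pytest.approx(top["t"] / math.sqrt(10))

    def test_independent_effect_size_convention(self, rng, adjacency):
        a = rng.standard_normal((8, 23, 6))
        b = rng.standard_normal((8, 23, 6))
        a[:, 3, 2] += 3.0
        res = cluster_permutation_test(
            (a, b), adjacency, design="independent", n_permutations=200,
            seed=0,
        )
        summaries = cluster_summary(res, (a, b), "independent")
        top = summaries[0]
        assert top["d"] == pytest.approx(2 * top["t"] / math.sqrt(14))

    def test_degenerate_amplitudes_give_undefined_d(self, adjacency):
        # two connected members whose subject deviations cancel: each
        # member has finite t, but the cluster-averaged amplitude is
        # constant across subjects, so the follow-up d is undefined
        e = 0.01 * np.arange(1, 7)
        data = np.zeros((6, 23, 4))
        data[:, 5, 1] = 1.0 + e
        data[:, 5, 2] = 1.0 - e
        res = cluster_permutation_test(data, adjacency, n_permutations=200,
                                       seed=0)
        summaries = cluster_summary(res, data, "paired")
        top = summaries[0]
        assert set(res.clusters[0].members) == {(5, 1), (5, 2)}
        assert math.isnan(top["d"])

    def test_peak_and_labels_reported(self, rng, adjacency, montage):
        data = rng.standard_normal((10, 23, 6))
        data[:, montage.index("Fz"), 3] += 3.0
        res = cluster_permutation_test(data, adjacency, n_permutations=200,
                                       seed=0)
        times = np.arange(200.0, 230.0, 5.0)
        summaries = cluster_summary(res, data, "paired", times, montage.labels)
        assert "Fz" in summaries[0]["channels"]
        assert summaries[0]["peak_channel"] == "Fz"
        assert summaries[0]["peak_time_ms"] == 215.0
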