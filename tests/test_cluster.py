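import numpy as np
import pytest
from _oracles import brute_dbscan, brute_kdist, partition

from conftest import make_read
from pirnakit.cluster import (
    ClusterParams,
    EpsEstimationError,
    classify_strandedness,
    dbscan_1d,
    detect_clusters,
    estimate_eps,
    kdist_profile,
    score_cluster,
)
from pirnakit.simulate import simulate_clustered_reads


class TestKDistProfile:
    def test_equal_spacing(self):
        prof = kdist_profile([0, 10, 20], k=1)
        assert prof.distances.tolist() == [10, 10, 10]

    def test_matches_brute_force_small(self):
        # oracle: all-pairs distances, k-th smallest per point
        positions = [0, 1, 100]
        expected, _ = brute_kdist(positions, k=2)
        assert expected == [100, 99, 100]  # frozen from the oracle
        prof = kdist_profile(positions, k=2)
        assert prof.distances.tolist() == expected

    def test_single_point_omitted(self):
        with pytest.warns(UserWarning):
            prof = kdist_profile([5], k=1)
        assert len(prof) == 0
        assert prof.n_omitted == 1

    def test_random_agreement_with_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 60))
            k = int(rng.integers(1, 5))
            pos = np.sort(rng.integers(0, 5000, size=n))
            expected, omitted = brute_kdist(pos.tolist(), k)
            prof = kdist_profile(pos, k)
            assert sorted(prof.distances.tolist()) == sorted(expected)
            assert prof.n_omitted == omitted

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            kdist_profile([5, 1], k=1)


class TestEstimateEps:
    @staticmethod
    def _profile(distances):
        from pirnakit.cluster import KDistProfile

        return KDistProfile("c", 1, np.array(distances))

    def test_modal_bin_rule(self):
        prof = self._profile([10] * 40 + [50] * 3)
        # bin width 5 from 0: modal bin [10, 15) -> upper edge 15
        assert estimate_eps(prof, bin_width=5) == 15

    def test_all_equal(self):
        eps = estimate_eps(self._profile([7] * 20))
        assert 7 <= eps <= 8  # bin containing d

    def test_tie_breaks_toward_smaller(self):
        prof = self._profile([10] * 5 + [100] * 5)
        # equal counts: first (smaller-distance) modal bin wins
        assert estimate_eps(prof, bin_width=5) == 15

    def test_empty_profile_errors(self):
        with pytest.warns(UserWarning):
            prof = kdist_profile([5], k=1)
        with pytest.raises(EpsEstimationError, match="manually"):
            estimate_eps(prof)


class TestDbscan1d:
    def test_single_dense_run(self):
        pos = list(range(0, 1000, 100))
        labels = dbscan_1d(pos, eps=150, min_reads=3)
        assert set(labels) == {0}

    def test_below_min_reads_is_noise(self):
        labels = dbscan_1d([100, 110], eps=50, min_reads=3)
        assert labels.tolist() == [-1, -1]

    def test_two_separated_blocks(self):
        pos = [0, 10, 20, 30, 40] + [10000, 10010, 10020, 10030, 10040]
        labels = dbscan_1d(pos, eps=1000, min_reads=3)
        assert partition(pos, labels) == partition(
            pos, brute_dbscan(pos, 1000, 3)
        )
        assert len(set(labels)) == 2

    def test_accepts_position_strand_tuples(self):
        labels = dbscan_1d([(0, "+"), (5, "-"), (10, "+")], eps=10, min_reads=2)
        assert set(labels) == {0}

    def test_oracle_agreement_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 150))
            pos = rng.integers(0, 3000, size=n)
            eps = int(rng.integers(1, 120))
            m = int(rng.integers(2, 8))
            assert partition(pos, dbscan_1d(pos, eps, m)) == partition(
                pos, brute_dbscan(pos, eps, m)
            )

    def test_permutation_invariance(self, rng):
        pos = rng.integers(0, 500, size=80)
        base = partition(pos, dbscan_1d(pos, 30, 4))
        perm = rng.permutation(len(pos))
        shuffled = pos[perm]
        relabeled = partition(shuffled, dbscan_1d(shuffled, 30, 4))
        # map shuffled indices back to original
        remap_noise = frozenset(int(perm[i]) for i in relabeled[0])
        remap_clusters = frozenset(
            frozenset(int(perm[i]) for i in c) for c in relabeled[1]
        )
        assert (remap_noise, remap_clusters) == base

    def test_eps_monotonicity_merge_only(self, rng):
        pos = np.sort(rng.integers(0, 2000, size=100))
        small = dbscan_1d(pos, 20, 3)
        large = dbscan_1d(pos, 80, 3)
        # every small-eps cluster must be contained in one large-eps cluster
        _, small_clusters = partition(pos, small)
        _, large_clusters = partition(pos, large)
        for sc in small_clusters:
            assert any(sc <= lc for lc in large_clusters)

    def test_validation(self):
        with pytest.raises(ValueError):
            dbscan_1d([1, 2], eps=0, min_reads=2)
        with pytest.raises(ValueError):
            dbscan_1d([1, 2], eps=5, min_reads=1)


class TestScoreCluster:
    @pytest.mark.parametrize(
        "n,m,expected", [(50, 5, 10.0), (5, 5, 1.0), (7, 2, 3.5)]
    )
    def test_ratio(self, n, m, expected):
        assert score_cluster(n, m) == expected

    def test_zero_min_reads_errors(self):
        with pytest.raises(ValueError):
            score_cluster(10, 0)

    def test_k_scaled_variant(self):
        assert score_cluster(40, 5, k=4, scale_by_k=True) == 2.0


class TestClassifyStrandedness:
    def test_uni_plus(self):
        members = [make_read("c", i * 100, i * 100 + 30, "+") for i in range(5)]
        assert classify_strandedness(members) == ("uni_plus", 5, 0)

    def test_uni_minus(self):
        members = [make_read("c", i * 100, i * 100 + 30, "-") for i in range(3)]
        assert classify_strandedness(members) == ("uni_minus", 0, 3)

    def test_dual_with_single_antisense(self):
        members = [make_read("c", i * 100, i * 100 + 30, "+") for i in range(4)]
        members.append(make_read("c", 900, 930, "-"))
        assert classify_strandedness(members) == ("dual", 4, 1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_strandedness([])

    def test_unstranded_member_errors(self):
        with pytest.raises(ValueError):
            classify_strandedness([make_read("c", 0, 30, ".")])


class TestDetectClusters:
    def test_empty(self):
        result = detect_clusters([], ClusterParams(eps=100, min_reads=3))
        assert result.clusters == [] and result.noise == []

    def test_sparse_reads_all_noise(self):
        reads = [
            make_read("c", i * 10_000, i * 10_000 + 30, "+", f"r{i}")
            for i in range(10)
        ]
        result = detect_clusters(reads, ClusterParams(eps=100, min_reads=3))
        assert result.clusters == []
        assert len(result.noise) == 10

    def test_planted_blocks_recovered_fixed_eps(self):
        reads, truth = simulate_clustered_reads(
            n_clusters=3, noise_reads=0, seed=11
        )
        result = detect_clusters(reads, ClusterParams(eps=500, min_reads=5))
        assert len(result.clusters) == 3
        for cluster, planted in zip(result.clusters, truth.clusters):
            assert cluster.interval.start == planted["start"]
            assert cluster.interval.end == planted["end"]
            assert cluster.n_reads == planted["n_reads"]

    def test_members_within_interval_and_sorted(self):
        reads, _ = simulate_clustered_reads(seed=3)
        result = detect_clusters(reads)
        starts = [(c.interval.chrom, c.interval.start) for c in result.clusters]
        assert starts == sorted(starts)
        for c in result.clusters:
            for m in c.members:
                assert c.interval.start <= m.interval.start
                assert m.interval.end <= c.interval.end

    def test_noise_side_channel_conserves_reads(self):
        reads, _ = simulate_clustered_reads(seed=5)
        result = detect_clusters(reads)
        total = sum(c.n_reads for c in result.clusters) + len(result.noise)
        assert total == len(reads)

    def test_single_run_clusters_disjoint(self):
        reads, _ = simulate_clustered_reads(seed=9)
        result = detect_clusters(reads)
        ids = [id(m) for c in result.clusters for m in c.members]
        assert len(ids) == len(set(ids))

    def test_params_logged_per_chromosome(self):
        reads, _ = simulate_clustered_reads(seed=2)
        result = detect_clusters(reads)
        assert "chrS" in result.params_by_chrom
        assert result.params_by_chrom["chrS"].eps >= 1
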