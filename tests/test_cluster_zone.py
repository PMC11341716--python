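import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from depthzone.cluster_zone import (
    DepthZoneAssignment,
    crosssite_cluster,
    depth_breaks,
    hierarchical_cluster,
    pool_clusters_to_zones,
    simprof_clusters,
    simprof_statistic,
)
from depthzone.errors import ValidationError
from depthzone.obsdata import combine_matrices

from conftest import make_matrix


def dm_from(square, ids=None):
    square = np.asarray(square, dtype=float)
    return DistanceMatrix(square, ids=ids or [f"s{i}" for i in range(len(square))])


class TestHierarchicalCluster:
    def test_complete_linkage_hand_trace(self):
        d = [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]
        dendro = hierarchical_cluster(dm_from(d, ids=["A", "B", "C"]), "complete")
        z = dendro.linkage_matrix
        assert sorted(z[0, :2]) == [0, 1] and z[0, 2] == pytest.approx(0.1)
        assert z[1, 2] == pytest.approx(0.9)

    def test_identical_samples_merge_at_zero(self):
        d = np.zeros((4, 4))
        dendro = hierarchical_cluster(dm_from(d), "complete")
        assert np.allclose(dendro.linkage_matrix[:, 2], 0)

    @pytest.mark.parametrize("method", ["complete", "ward"])
    def test_agrees_with_scipy_oracle_on_random_matrices(self, method):
        rng = np.random.default_rng(5)
        for _ in range(8):
            n = int(rng.integers(4, 9))
            cond = rng.uniform(0.05, 1.0, n * (n - 1) // 2)
            dendro = hierarchical_cluster(dm_from(squareform(cond)), method)
            ref = scipy_linkage(cond, method=method)
            assert np.allclose(cophenet(dendro.linkage_matrix), cophenet(ref), atol=1e-10)

    def test_complete_heights_equal_max_within_pair_distance(self):
        rng = np.random.default_rng(9)
        cond = rng.uniform(0.1, 1.0, 15)
        sq = squareform(cond)
        dendro = hierarchical_cluster(dm_from(sq), "complete")
        coph = squareform(cophenet(dendro.linkage_matrix))
        # cophenetic height of each pair >= its direct distance; root = overall max
        assert np.all(coph >= sq - 1e-12)
        assert dendro.linkage_matrix[-1, 2] == pytest.approx(sq.max())

    def test_newick_export_contains_all_labels(self):
        rng = np.random.default_rng(2)
        dendro = hierarchical_cluster(
            dm_from(squareform(rng.uniform(0.1, 1, 10)), ids=list("abcde")), "complete"
        )
        nwk = dendro.to_newick()
        assert nwk.endswith(");") and all(lbl in nwk for lbl in "abcde")


class TestSimprofStatistic:
    def test_identical_rows_homogeneous_with_zero_pi(self):
        x = np.tile([3.0, 1.0, 2.0], (5, 1))
        res = simprof_statistic(x, n_perm_expected=99, n_perm_null=99, seed=0)
        assert res.pi_statistic == pytest.approx(0.0)
        assert res.decision == "homogeneous"

    def test_two_disjoint_blocks_reach_minimum_p(self):
        x = np.zeros((6, 8))
        x[:3, :4] = 50.0
        x[3:, 4:] = 50.0
        res = simprof_statistic(x, n_perm_expected=199, n_perm_null=199, seed=1,
                                alpha=0.05)
        assert res.p_value == pytest.approx(1.0 / 200.0)
        assert res.decision == "heterogeneous"

    def test_fewer_than_three_samples_auto_homogeneous(self):
        res = simprof_statistic(np.ones((2, 4)), seed=0)
        assert res.decision == "homogeneous" and res.p_value == 1.0

    def test_decisions_stable_under_species_column_permutation(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.poisson(20, (4, 10)), rng.poisson(20, (4, 10)) + 30])
        a = simprof_statistic(x.astype(float), 199, 199, seed=7, alpha=0.05)
        b = simprof_statistic(x[:, ::-1].astype(float), 199, 199, seed=7, alpha=0.05)
        assert a.decision == b.decision == "heterogeneous"


class TestSimprofClusters:
    def _blocks(self, rng, sizes, n_species=12, strength=40):
        rows = []
        for bi, size in enumerate(sizes):
            base = np.zeros(n_species)
            lo = bi * n_species // len(sizes)
            hi = (bi + 1) * n_species // len(sizes)
            base[lo:hi] = strength
            rows += [rng.poisson(base) + 0.0 for _ in range(size)]
        return make_matrix(np.array(rows))

    def test_homogeneous_matrix_single_cluster(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.poisson(10, size=(8, 6)).astype(float))
        _, clusters, _ = simprof_clusters(m, alpha=0.05, n_perm_expected=99,
                                          n_perm_null=199, seed=0)
        assert clusters.n_clusters == 1

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(1)
        m = self._blocks(rng, [4, 4, 4])
        _, clusters, results = simprof_clusters(m, alpha=0.05, n_perm_expected=199,
                                                n_perm_null=199, seed=2)
        assert clusters.n_clusters == 3
        sizes = sorted(len(c) for c in clusters.clusters)
        assert sizes == [4, 4, 4]

    def test_alpha_zero_limit_is_one_cluster(self):
        rng = np.random.default_rng(1)
        m = self._blocks(rng, [4, 4])
        _, clusters, _ = simprof_clusters(m, alpha=0.0, n_perm_expected=49,
                                          n_perm_null=49, seed=0)
        assert clusters.n_clusters == 1

    def test_alpha_one_limit_fragments_to_untestable_groups(self):
        rng = np.random.default_rng(1)
        m = self._blocks(rng, [4, 4])
        _, clusters, _ = simprof_clusters(m, alpha=1.0, n_perm_expected=49,
                                          n_perm_null=49, seed=0)
        assert all(len(c) <= 2 for c in clusters.clusters)

    def test_clusters_partition_samples(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.poisson(6, size=(9, 7)).astype(float))
        _, clusters, _ = simprof_clusters(m, alpha=0.3, n_perm_expected=99,
                                          n_perm_null=99, seed=1)
        flat = sorted(s for c in clusters.clusters for s in c)
        assert flat == sorted(m.data.index)


class TestZonePooling:
    def test_identity_grouping_when_zones_equal_clusters(self):
        rng = np.random.default_rng(1)
        x = np.vstack([np.full((2, 6), 0.0) + rng.poisson([30, 30, 30, 0, 0, 0], (2, 6)),
                       rng.poisson([0, 0, 0, 30, 30, 30], (2, 6)).astype(float)])
        m = make_matrix(x, bins=[40, 50, 60, 70])
        dendro, clusters, _ = simprof_clusters(m, alpha=0.05, n_perm_expected=99,
                                               n_perm_null=199, seed=0)
        asg = pool_clusters_to_zones(dendro, m, 2, zone_names=["shallow", "deep"])
        assert asg.mapping == {40: "shallow", 50: "shallow", 60: "deep", 70: "deep"}
        assert depth_breaks(asg) == [60]

    def test_single_zone_maps_everything(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.poisson(9, (5, 4)).astype(float))
        dendro, _, _ = simprof_clusters(m, alpha=0.05, n_perm_expected=49,
                                        n_perm_null=49, seed=0)
        asg = pool_clusters_to_zones(dendro, m, 1, zone_names=["only"])
        assert set(asg.mapping.values()) == {"only"}
        assert depth_breaks(asg) == []

    def test_pooled_span_bins_inherit_zone(self):
        import pandas as pd
        from depthzone.obsdata import AbundanceMatrix

        data = pd.DataFrame([[9.0, 0], [8, 1], [0, 7], [1, 9]],
                            index=["A:40", "A:50-60", "A:70", "A:80"],
                            columns=["u", "v"])
        meta = pd.DataFrame(
            {"site": "A", "depth_bin": [40, 50, 70, 80],
             "bins": [(40,), (50, 60), (70,), (80,)]},
            index=data.index,
        )
        m = AbundanceMatrix(data=data, sample_meta=meta)
        dendro, _, _ = simprof_clusters(m, alpha=0.05, n_perm_expected=99,
                                        n_perm_null=199, seed=0)
        asg = pool_clusters_to_zones(dendro, m, 2, zone_names=["up", "down"])
        assert asg.mapping[50] == asg.mapping[60] == "up"
        assert depth_breaks(asg) == [70]


class TestCrosssite:
    def test_duplicated_sites_merge_at_height_zero_first(self):
        rng = np.random.default_rng(6)
        x = rng.poisson(15, size=(4, 8)).astype(float)
        m1 = make_matrix(x, site="A")
        m2 = make_matrix(x, site="B")
        combined = combine_matrices([m1, m2])
        dendro, _, _ = crosssite_cluster(combined, alpha=0.05, n_perm_expected=49,
                                         n_perm_null=49, seed=0)
        z = dendro.linkage_matrix
        # first 4 merges join identical (site, bin) twins at height 0
        assert np.allclose(z[:4, 2], 0.0, atol=1e-12)

    def test_shared_zone_structure_splits_by_depth_not_site(self):
        rng = np.random.default_rng(7)
        shallow = np.array([40.0, 40, 40, 0, 0, 0])
        deep = np.array([0.0, 0, 0, 40, 40, 40])
        mats = []
        for site in ("A", "B"):
            rows = np.vstack([rng.poisson(shallow, (3, 6)),
                              rng.poisson(deep, (3, 6))]).astype(float)
            mats.append(make_matrix(rows, site=site))
        dendro, clusters, _ = crosssite_cluster(mats, alpha=0.05, n_perm_expected=99,
                                                n_perm_null=199, seed=1)
        # the two top-level groups each contain both sites (split is by depth)
        from scipy.cluster.hierarchy import cut_tree

        groups = cut_tree(dendro.linkage_matrix, n_clusters=2).ravel()
        labels = dendro.labels
        for g in (0, 1):
            sites = {labels[i].split(":")[0] for i in np.flatnonzero(groups == g)}
            assert sites == {"A", "B"}
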