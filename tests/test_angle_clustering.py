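import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from vdomgeom.angle_clustering import (
    BootstrapWardClusterer,
    DistanceMatrix,
    average_bu,
    average_by_structure,
    bootstrap_support,
    cut_significant_clusters,
    ead_matrix_from_angles,
    pairwise_ead_matrix,
    to_newick,
    ward_linkage,
)
from vdomgeom.cuboid_geometry import EulerTriple, GeometryRecord, euler_angle_distance


def rec(pdb_id, phi, psi, theta, bu=1, **kw):
    return GeometryRecord(pdb_id, bu, EulerTriple(phi, psi, theta), **kw)


class TestAverageBU:
    def test_single_bu_unchanged(self):
        r = rec("a", 10, 20, 30)
        avg = average_bu([r])
        assert avg.bu_index == "averaged"
        np.testing.assert_allclose(avg.euler.as_array(), [10, 20, 30])

    def test_componentwise_mean(self):
        avg = average_bu([rec("a", 10, 20, 30), rec("a", 20, 30, 40, bu=2)])
        np.testing.assert_allclose(avg.euler.as_array(), [15, 25, 35])

    def test_mean_across_wrap_seam(self):
        avg = average_bu([rec("a", 179, 0, 0), rec("a", -179, 0, 0, bu=2)])
        assert avg.euler.phi == pytest.approx(180.0)

    def test_matches_brute_force_on_random_bus(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-60, 60, (4, 3))
        records = [rec("a", *row, bu=i + 1) for i, row in enumerate(angles)]
        avg = average_bu(records)
        # independent oracle: plain arithmetic mean (no wrapping needed here)
        np.testing.assert_allclose(avg.euler.as_array(), angles.mean(axis=0), atol=1e-9)

    def test_mixed_pdb_ids_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            average_bu([rec("a", 0, 0, 0), rec("b", 1, 1, 1)])

    def test_average_by_structure_groups_and_orders(self):
        records = [rec("a", 0, 0, 0), rec("b", 5, 5, 5), rec("a", 10, 0, 0, bu=2)]
        out = average_by_structure(records)
        assert [r.pdb_id for r in out] == ["a", "b"]
        np.testing.assert_allclose(out[0].euler.as_array(), [5, 0, 0])


class TestEADMatrix:
    def test_identical_records_zero_matrix(self):
        m = pairwise_ead_matrix([rec("a", 1, 2, 3), rec("b", 1, 2, 3)])
        np.testing.assert_allclose(m.values, 0, atol=1e-12)

    def test_constructed_equidistant_triplet(self):
        # mutual distance exactly 1 degree
        records = [rec("a", 0, 0, 0), rec("b", 1, 0, 0),
                   rec("c", 0.5, np.sqrt(3) / 2, 0)]
        m = pairwise_ead_matrix(records)
        off = m.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)

    def test_entries_match_scalar_distance(self):
        rng = np.random.default_rng(1)
        records = [rec(f"r{i}", *rng.uniform(-170, 170, 3)) for i in range(6)]
        m = pairwise_ead_matrix(records)
        for i in range(6):
            for j in range(6):
                assert m.values[i, j] == pytest.approx(
                    euler_angle_distance(records[i].euler, records[j].euler), abs=1e-9
                )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_ead_matrix([rec("a", 0, 0, 0), rec("a", 1, 0, 0)])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(["a", "b"], np.array([[0, np.nan], [np.nan, 0]]))


class TestWardLinkage:
    def test_two_leaves_single_merge(self):
        m = pairwise_ead_matrix([rec("a", 0, 0, 0), rec("b", 3, 4, 0)])
        dendro = ward_linkage(m)
        assert dendro.merges.shape == (1, 4)
        assert dendro.merges[0, 2] == pytest.approx(5.0)

    def test_two_triads_split_at_top(self):
        angles = [(0, 0, 0), (0.5, 0, 0), (0, 0.5, 0),
                  (40, 0, 0), (40.5, 0, 0), (40, 0.5, 0)]
        records = [rec(f"r{i}", *a) for i, a in enumerate(angles)]
        dendro = ward_linkage(pairwise_ead_matrix(records))
        top_members = dendro.node_members()[-2]  # children of the root
        assert top_members in (
            frozenset({"r0:1", "r1:1", "r2:1"}),
            frozenset({"r3:1", "r4:1", "r5:1"}),
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_monotone(self, seed):
        rng = np.random.default_rng(seed)
        records = [rec(f"r{i}", *rng.uniform(-90, 90, 3)) for i in range(12)]
        dendro = ward_linkage(pairwise_ead_matrix(records))
        heights = dendro.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)


def planted_records(rng, centers, per_cluster, spread):
    records, labels = [], []
    for c, center in enumerate(centers):
        for i in range(per_cluster):
            a = np.asarray(center) + rng.normal(0, spread, 3)
            records.append(rec(f"c{c}s{i}", *a, tcr_type=f"t{c}"))
            labels.append(c)
    return records, np.array(labels)


class TestBootstrapSupport:
    def test_two_separated_clusters_fully_supported(self):
        rng = np.random.default_rng(2)
        records, _ = planted_records(rng, [(0, 0, 0), (30, 0, 0)], 6, 0.5)
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=1000, seed=1)
        members = dendro.node_members()
        for j, s in enumerate(members):
            if len(s) == 6:  # the two true clusters
                assert support.au[j] >= 0.99

    def test_homogeneous_cloud_has_no_supported_structure(self):
        rng = np.random.default_rng(3)
        records = [rec(f"r{i}", *rng.normal(0, 1.0, 3)) for i in range(14)]
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=2000, seed=5)
        sizes = np.array([len(s) for s in dendro.node_members()])
        internal = (sizes > 2) & (sizes < len(records))
        assert not np.any(support.au[internal] >= 0.95)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        records, _ = planted_records(rng, [(0, 0, 0), (25, 5, 0)], 5, 1.0)
        s1 = bootstrap_support(records, n_replicas=500, seed=9)
        s2 = bootstrap_support(records, n_replicas=500, seed=9)
        np.testing.assert_array_equal(s1.au, s2.au)
        np.testing.assert_array_equal(s1.bp, s2.bp)

    def test_too_few_replicas_rejected(self):
        records = [rec("a", 0, 0, 0), rec("b", 1, 0, 0)]
        with pytest.raises(ValueError, match="100"):
            bootstrap_support(records, n_replicas=10)

    def test_component_resampling_mode_runs(self):
        rng = np.random.default_rng(6)
        records, _ = planted_records(rng, [(0, 0, 0), (30, 30, 30)], 5, 0.5)
        support = bootstrap_support(records, n_replicas=500, seed=2,
                                    resample="components")
        assert np.all((support.au >= 0) & (support.au <= 1))


class TestSignificantClusters:
    def test_threshold_domain_checked(self):
        rng = np.random.default_rng(7)
        records, _ = planted_records(rng, [(0, 0, 0), (30, 0, 0)], 4, 0.5)
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=500, seed=1)
        with pytest.raises(ValueError):
            cut_significant_clusters(dendro, support, au_threshold=1.5)

    def test_two_cluster_toy(self):
        rng = np.random.default_rng(8)
        records, labels = planted_records(rng, [(0, 0, 0), (30, 0, 0)], 6, 0.5)
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=1000, seed=3)
        clusters = cut_significant_clusters(dendro, support)
        assert clusters.n_clusters == 2
        got = clusters.labels_for([r.label for r in records])
        assert adjusted_rand_score(labels, got) == 1.0

    def test_three_cluster_recovery(self):
        rng = np.random.default_rng(9)
        records, labels = planted_records(
            rng, [(0, 0, 0), (30, 0, 0), (0, 30, 0)], 6, 0.5
        )
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=1500, seed=4)
        clusters = cut_significant_clusters(dendro, support)
        got = clusters.labels_for([r.label for r in records])
        assert adjusted_rand_score(labels, got) == 1.0

    def test_partition_covers_all_labels(self):
        rng = np.random.default_rng(10)
        records = [rec(f"r{i}", *rng.normal(0, 3, 3)) for i in range(10)]
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=500, seed=1)
        clusters = cut_significant_clusters(dendro, support)
        assert set(clusters.assignment) == {r.label for r in records}


class TestExportsAndEstimator:
    def test_newick_is_parseable_with_supports(self):
        import dendropy

        rng = np.random.default_rng(11)
        records, _ = planted_records(rng, [(0, 0, 0), (25, 0, 0)], 4, 0.5)
        dendro = ward_linkage(pairwise_ead_matrix(records))
        support = bootstrap_support(records, dendro, n_replicas=500, seed=1)
        text = to_newick(dendro, support)
        tree = dendropy.Tree.get(data=text, schema="newick")
        assert len(tree.leaf_nodes()) == 8
        assert "au" in text and "bp" in text

    def test_estimator_label_order_invariance(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal((0, 0, 0), 0.5, (6, 3)),
                       rng.normal((30, 0, 0), 0.5, (6, 3))])
        est = BootstrapWardClusterer(n_replicas=800, random_state=1)
        labels1 = est.fit(X).labels_
        perm = rng.permutation(len(X))
        labels2 = BootstrapWardClusterer(n_replicas=800, random_state=1).fit(X[perm]).labels_
        assert adjusted_rand_score(labels1[perm], labels2) == 1.0
        assert est.n_clusters_ == 2
        assert est.au_.shape == (len(X) - 1,)
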