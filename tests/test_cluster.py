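import numpy as np
import pytest
import scipy.cluster.hierarchy as sch

import costvar as cv
from conftest import make_standardized
from oracles import brute_agglomerate


def one_d(points):
    return np.asarray(points, dtype=float).reshape(-1, 1)


class TestAgglomerate:
    def test_single_linkage_toy(self):
        D = cv.euclidean_distances(one_d([0, 1, 10]))
        tree = cv.agglomerate(D, "single")
        assert tree.heights == pytest.approx([1.0, 9.0])

    def test_average_linkage_toy(self):
        D = cv.euclidean_distances(one_d([0, 1, 10]))
        tree = cv.agglomerate(D, "average")
        assert tree.heights == pytest.approx([1.0, 9.5])

    def test_two_objects_merge_at_their_distance(self):
        D = cv.euclidean_distances(one_d([2, 7]))
        tree = cv.agglomerate(D, "complete")
        assert tree.steps.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(5.0)

    def test_centroid_and_ward_require_data(self):
        D = cv.euclidean_distances(one_d([0, 1, 10]))
        with pytest.raises(ValueError, match="requires the data matrix"):
            cv.agglomerate(D, "centroid")

    def test_centroid_with_noneuclidean_metric_warns(self):
        X = np.array([[0.0, 0], [1, 1], [5, 9]])
        D = cv.cityblock_distances(X)
        with pytest.warns(UserWarning, match="heuristic"):
            cv.agglomerate(D, "centroid", X=X)

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            cv.euclidean_distances(np.zeros((1, 2)))

    @pytest.mark.parametrize("linkage", cv.LINKAGES)
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle(self, linkage, seed):
        """Exact heights and topology vs exhaustive set-formula oracle, m <= 6."""
        rng = np.random.default_rng(seed)
        m = rng.integers(3, 7)
        X = rng.normal(size=(m, 3))
        D = cv.euclidean_distances(X)
        tree = cv.agglomerate(D, linkage, X=X)
        expected = brute_agglomerate(D.values, linkage, X=X)
        for step, (l, r, h, size) in enumerate(expected):
            got = tree.steps[step]
            assert {int(got[0]), int(got[1])} == {l, r}
            assert got[2] == pytest.approx(h, rel=1e-9)
            assert int(got[3]) == size

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_matches_scipy_on_euclidean(self, linkage):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(9, 4))
        D = cv.euclidean_distances(X)
        tree = cv.agglomerate(D, linkage, X=X)
        Z = sch.linkage(sch.distance.pdist(X), linkage)
        assert np.allclose(np.sort(tree.heights), np.sort(Z[:, 2]), rtol=1e-9)
        for k in range(2, 9):
            ours = cv.cut(tree, k)
            theirs = sch.fcluster(Z, k, "maxclust")
            # same partition up to relabelling
            assert len({(a, b) for a, b in zip(ours, theirs)}) == k

    def test_centroid_heights_match_scipy(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(9, 4))
        tree = cv.agglomerate(cv.euclidean_distances(X), "centroid", X=X)
        Z = sch.linkage(sch.distance.pdist(X), "centroid")
        assert np.allclose(np.sort(tree.heights), np.sort(Z[:, 2]), rtol=1e-9)

    def test_ward_topology_matches_scipy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        D = cv.euclidean_distances(X)
        tree = cv.agglomerate(D, "ward", X=X)
        Z = sch.linkage(sch.distance.pdist(X), "ward")
        for k in range(2, 10):
            ours = cv.cut(tree, k)
            theirs = sch.fcluster(Z, k, "maxclust")
            assert len({(a, b) for a, b in zip(ours, theirs)}) == k

    @pytest.mark.parametrize("seed", range(5))
    def test_single_linkage_bounds_other_heights(self, seed):
        """Sorted single-linkage heights bound average and complete from
        below (average vs complete are not comparable once their trees
        diverge, so only the single-linkage bound is asserted)."""
        rng = np.random.default_rng(seed + 100)
        X = rng.normal(size=(8, 3))
        D = cv.euclidean_distances(X)
        hs = {
            link: np.sort(cv.agglomerate(D, link).heights)
            for link in ("single", "average", "complete")
        }
        assert (hs["single"] <= hs["average"] + 1e-12).all()
        assert (hs["single"] <= hs["complete"] + 1e-12).all()

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_graph_linkages_are_monotone(self, linkage):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        tree = cv.agglomerate(cv.euclidean_distances(X), linkage)
        assert tree.is_monotone

    def test_centroid_inversions_are_flagged(self):
        # a classic inversion: three near-equidistant points
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.8]])
        tree = cv.agglomerate(cv.euclidean_distances(X), "centroid", X=X)
        assert tree.inversions() == [1]
        assert not tree.is_monotone


class TestCophenetic:
    def test_two_objects(self):
        tree = cv.agglomerate(cv.euclidean_distances(one_d([0, 4])), "single")
        assert cv.cophenetic_distances(tree) == pytest.approx([4.0])

    def test_read_off_single_linkage_merges(self):
        tree = cv.agglomerate(cv.euclidean_distances(one_d([0, 1, 10])), "single")
        assert cv.cophenetic_distances(tree) == pytest.approx([1.0, 9.0, 9.0])

    def test_equal_height_tree_gives_constant_z(self):
        X = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])  # equilateral
        tree = cv.agglomerate(cv.euclidean_distances(X), "complete")
        Z = cv.cophenetic_distances(tree)
        assert Z.max() - Z.min() < 1e-9

    def test_matches_scipy_cophenet(self, sarcoma_X):
        D = cv.euclidean_distances(sarcoma_X)
        tree = cv.agglomerate(D, "average")
        Z_ours = cv.cophenetic_distances(tree)
        c_scipy, Z_scipy = sch.cophenet(
            sch.linkage(D.condensed(), "average"), D.condensed()
        )
        assert np.allclose(np.sort(Z_ours), np.sort(Z_scipy), rtol=1e-9)
        c_ours = cv.cophenetic_coefficient(D.condensed(), Z_ours)
        assert c_ours == pytest.approx(c_scipy, rel=1e-9)

    def test_perfect_preservation_gives_one(self):
        Y = np.array([1.0, 2.0, 3.0])
        assert cv.cophenetic_coefficient(Y, Y.copy()) == pytest.approx(1.0)

    def test_formula_arithmetic(self):
        # by hand: y=20/3, z=19/3, num=45.3333, den=sqrt(48.6667*42.6667)
        c = cv.cophenetic_coefficient(np.array([1.0, 10.0, 9.0]), np.array([1.0, 9.0, 9.0]))
        assert c == pytest.approx(0.994850, abs=1e-5)

    def test_constant_vectors_are_degenerate(self):
        with pytest.raises(cv.DegenerateInputError):
            cv.cophenetic_coefficient(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_ultrametric_for_monotone_linkages(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 3))
        tree = cv.agglomerate(cv.euclidean_distances(X), "average")
        from scipy.spatial.distance import squareform

        Z = squareform(cv.cophenetic_distances(tree))
        m = Z.shape[0]
        for i in range(m):
            for j in range(m):
                for k in range(m):
                    assert Z[i, j] <= max(Z[i, k], Z[k, j]) + 1e-9


class TestScan:
    def test_table_covers_all_15_combinations(self, sarcoma_scan):
        assert len(sarcoma_scan.table) == 15
        assert set(sarcoma_scan.table["metric"]) == set(cv.METRICS)
        assert set(sarcoma_scan.table["linkage"]) == set(cv.LINKAGES)

    def test_best_pair_attains_table_maximum(self, sarcoma_scan):
        table = sarcoma_scan.table
        assert sarcoma_scan.best_coefficient == pytest.approx(
            table["coefficient"].max()
        )

    def test_toy_scan_matches_per_combination_calls(self):
        X = make_standardized([[0.0, 1], [1, 0], [4, 5], [5, 4], [9, 9]])
        scan = cv.scan_combinations(X)
        for row in scan.table.itertuples():
            D = cv.compute_distances(X, row.metric)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tree = cv.agglomerate(D, row.linkage, X=X)
            c = cv.cophenetic_coefficient(D.condensed(), cv.cophenetic_distances(tree))
            assert row.coefficient == pytest.approx(c, rel=1e-12)

    def test_two_object_scan_is_fully_degenerate(self):
        X = make_standardized([[0.0, 0.0], [2.0, 2.0]])
        with pytest.raises(cv.DegenerateInputError):
            cv.scan_combinations(X)


class TestCut:
    def test_extremes(self, sarcoma_scan):
        tree = sarcoma_scan.best_tree
        assert set(cv.cut(tree, 1)) == {1}
        assert sorted(cv.cut(tree, 12)) == list(range(1, 13))

    def test_out_of_range_rejected(self, sarcoma_scan):
        with pytest.raises(ValueError):
            cv.cut(sarcoma_scan.best_tree, 0)
        with pytest.raises(ValueError):
            cv.cut(sarcoma_scan.best_tree, 13)

    @pytest.mark.parametrize("seed", range(4))
    def test_refining_k_splits_exactly_one_cluster(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 3))
        tree = cv.agglomerate(cv.euclidean_distances(X), "average")
        for k in range(1, 10):
            a = cv.cut(tree, k)
            b = cv.cut(tree, k + 1)
            assert len(set(a)) == k and len(set(b)) == k + 1
            # each coarse cluster is a union of fine clusters; exactly one splits
            split = sum(
                len({b[i] for i in np.where(a == lab)[0]}) > 1 for lab in set(a)
            )
            assert split == 1

    def test_node_numbering_is_paper_style(self, sarcoma_scan):
        tree = sarcoma_scan.best_tree
        numbers = tree.node_numbers()
        assert numbers[0] == 1
        assert numbers[11] == 12
        assert numbers[12] == 13  # first merge
        assert numbers[22] == 23  # root


class TestExports:
    def test_newick_roundtrip_through_dendropy_lengths(self, sarcoma_scan):
        nwk = sarcoma_scan.best_tree.to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == 11

    def test_tree_dict_is_json_ready(self, sarcoma_scan):
        import json

        d = sarcoma_scan.best_tree.to_dict()
        assert len(d["steps"]) == 11
        json.dumps(d)
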